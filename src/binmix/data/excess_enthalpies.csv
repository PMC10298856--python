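T_K,x2,HE_J_mol
288.15,0.000,0
288.15,0.050,65
288.15,0.102,146
288.15,0.206,291
288.15,0.303,396
288.15,0.409,474
288.15,0.510,517
288.15,0.606,518
288.15,0.703,483
288.15,0.804,401
288.15,0.897,245
288.15,0.952,124
288.15,1.000,0
298.15,0.000,0
298.15,0.050,71
298.15,0.102,160
298.15,0.206,325
298.15,0.303,448
298.15,0.409,542
298.15,0.510,599
298.15,0.606,602
298.15,0.703,558
298.15,0.804,461
298.15,0.897,283
298.15,0.952,143
298.15,1.000,0
308.15,0.000,0
308.15,0.050,77
308.15,0.102,175
308.15,0.206,360
308.15,0.303,495
308.15,0.409,609
308.15,0.510,663
308.15,0.606,683
308.15,0.703,644
308.15,0.804,530
308.15,0.897,334
308.15,0.952,172
308.15,1.000,0
318.15,0.000,0
318.15,0.050,88
318.15,0.102,196
318.15,0.206,401
318.15,0.303,554
318.15,0.409,676
318.15,0.510,749
318.15,0.606,762
318.15,0.703,719
318.15,0.804,593
318.15,0.897,368
318.15,0.952,195
318.15,1.000,0
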