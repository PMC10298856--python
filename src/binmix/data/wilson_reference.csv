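T_K,Lambda12,Lambda21,s_Pa,lam12_minus_lam11,lam12_minus_lam11_trend,lam12_minus_lam22,lam12_minus_lam22_trend
278.15,0.4255,0.5511,12,3783,3815,-429,-460
283.15,0.4341,0.5548,12,3803,3800,-452,-452
288.15,0.4434,0.5589,11,3818,3784,-476,-443
293.15,0.4633,0.5504,19,3776,3768,-445,-434
298.15,0.4815,0.5434,16,3743,3752,-420,-425
303.15,0.4942,0.5417,20,3739,3737,-417,-416
308.15,0.5082,0.5390,21,3725,3721,-408,-407
313.15,0.5227,0.5371,28,3710,3705,-402,-399
318.15,0.5401,0.5320,33,3682,3689,-383,-390
323.15,0.5543,0.5301,34,3666,3674,-375,-381
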