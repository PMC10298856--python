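T_K,x2,rho_kg_m3
288.15,0.0000,789.34
288.15,0.1084,821.21
288.15,0.2025,842.65
288.15,0.2938,859.68
288.15,0.3996,875.90
288.15,0.5011,888.92
288.15,0.6004,899.70
288.15,0.6980,908.60
288.15,0.7953,916.30
288.15,0.9029,923.59
288.15,1.0000,928.96
298.15,0.0000,780.99
298.15,0.1084,812.72
298.15,0.2025,834.07
298.15,0.2938,851.02
298.15,0.3996,867.22
298.15,0.5011,880.21
298.15,0.6004,890.97
298.15,0.6980,899.88
298.15,0.7953,907.60
298.15,0.9029,914.91
298.15,1.0000,920.34
308.15,0.0000,772.37
308.15,0.1084,803.98
308.15,0.2025,825.27
308.15,0.2938,842.19
308.15,0.3996,858.36
308.15,0.5011,871.35
308.15,0.6004,882.13
308.15,0.6980,891.06
308.15,0.7953,898.81
308.15,0.9029,906.19
308.15,1.0000,911.73
318.15,0.0000,763.40
318.15,0.1084,794.93
318.15,0.2025,816.20
318.15,0.2938,833.12
318.15,0.3996,849.56
318.15,0.5011,862.32
318.15,0.6004,873.15
318.15,0.6980,882.14
318.15,0.7953,889.96
318.15,0.9029,897.44
318.15,1.0000,903.13
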