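T_K,V0_m3mol_x1e6_c1,P0_Pa_c1,P0_lit_Pa_c1,V0_m3mol_x1e6_c2,P0_Pa_c2
278.15,75.35,1521,1514,164.6,71
283.15,75.70,2164,2162,165.3,93
288.15,76.12,3069,3044,166.1,130
293.15,76.52,4212,4228,166.9,178
298.15,76.93,5781,5797,167.7,253
303.15,77.35,7851,7852,168.5,346
308.15,77.78,10515,10511,169.2,477
313.15,78.23,13934,13913,170.0,627
318.15,78.66,18242,18220,170.9,828
323.15,79.15,23623,23618,171.7,1101
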