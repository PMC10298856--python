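# Chen-Kreglewski universal dispersion constants D_ij for the square-well
# segment dispersion double series a_disp/RT = m * sum_ij D_ij (u/kT)^i (eta/tau)^j,
# as used in the original (Huang-Radosz-form) SAFT equation of state.
# Source: Chen, S. S.; Kreglewski, A. Ber. Bunsenges. Phys. Chem. 1977, 81, 1048;
# tabulated in Huang, S. H.; Radosz, M. Ind. Eng. Chem. Res. 1990, 29, 2284.
i,j,D
1,1,-8.8043
1,2,4.1646270
1,3,-48.203555
1,4,140.43620
1,5,-195.23339
1,6,113.51500
2,1,2.9396
2,2,-6.0865383
2,3,40.137956
2,4,-76.230797
2,5,-133.70055
2,6,860.25349
2,7,-1535.3224
2,8,1221.4261
2,9,-409.10539
3,1,-2.8225
3,2,4.7600148
3,3,11.257177
3,4,-66.382743
3,5,69.248785
4,1,0.34
4,2,-3.1875014
4,3,12.231796
4,4,-12.110681
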