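parameter,units,3nop,3nop-no2,no3,no3-no2
k_nox_ab,h^-1,,,0.30,0.30
k_3nop_ab,h^-1,0.30,0.30,,
k_no3_nh3,mol^-1 g^-1 h^-1,,,6.99,
k_no3_no2,mol^-1 g^-1 h^-1,,,,1.5
k_no2_nh3,mol^-1 g^-1 h^-1,,,,0.113
k_3nop_no3,g^-1 h^-1,,1.55,,
k_3nop_no2,g^-1 h^-1,,0.44,,
j_no2,M,,,,1.17e-3
j_mcr,M,1.93e-5,2.10e-5,,
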