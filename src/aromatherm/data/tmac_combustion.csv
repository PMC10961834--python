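m_sample_g,m_oil_g,m_cotton_g,m_crucible_g,T_i_K,T_f_K,dT_corr_K,eps_cont_i_kJK,eps_cont_f_kJK,dU_ign_kJ,dU_HNO3_kJ,dU_corr_kJ
0.98431,0.15349,0.00178,11.51597,295.3007,297.5356,0.0432,0.0174,0.0184,0.0042,-0.0013,0.0209
0.99150,0.18881,0.00170,11.52378,295.2940,297.7015,0.0430,0.0175,0.0186,0.0042,-0.0013,0.0217
0.99156,0.17461,0.00166,11.51775,295.2910,297.6321,0.0406,0.0175,0.0185,0.0042,-0.0013,0.0214
0.99292,0.19230,0.00164,11.51940,295.3190,297.7554,0.0546,0.0175,0.0186,0.0042,-0.0015,0.0218
0.96352,0.15120,0.00168,11.52056,295.2876,297.4814,0.0427,0.0174,0.0184,0.0042,-0.0010,0.0204
0.98969,0.15585,0.00179,11.52631,295.2946,297.5493,0.0426,0.0174,0.0184,0.0042,-0.0013,0.0211
0.98211,0.17298,0.00182,11.52174,295.2943,297.6154,0.0423,0.0175,0.0185,0.0042,-0.0011,0.0212
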