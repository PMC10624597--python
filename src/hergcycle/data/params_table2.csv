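name,HEK-hERG1,PANC-1,HCT116,units,floating
k_c,0.402,1.43,1.5,s^-1,True
k_g,0.0524,0.139,0.205,s^-1,True
k_tg,0.00304,0.00206,0.00154,s^-1,True
k_e,3.55e-5,0.000227,0.000352,(#/cell)^-1 s^-1,True
k_te,0.0608,0.0218,0.0292,s^-1,True
k_de,0.105,0.18,0.253,s^-1,True
k_off,107,346,234,s^-1,True
k_on,4.24e-5,0.000113,8.82e-5,(#/cell)^-1 s^-1,True
k_minus_f,8.05e-6,8.37e-5,8.79e-5,s^-1,True
k_a,4.91e-8,1.18e-7,1.92e-7,(#/cell)^-1 s^-1,True
k_a_minus,0.000258,0.000873,0.000486,(#/cell)^-2 s^-1,True
k_i,1.23e-9,1.17e-9,1.73e-9,(#/cell)^-1 s^-1,True
k_ie,65.2,79.2,71.8,(#/cell)^-1 s^-1,True
k_n,163,100,86.4,(#/cell)^-1 s^-1,True
k_n_plus,0.000776,0.000898,0.00109,s^-1,True
k_minus_n,0.0134,0.01,0.0116,s^-1,True
k_c_plus,0.00804,0.0286,0.03,(#/cell)^-1 s^-1,True
k_g_plus,0.000698,0.00185,0.00274,(#/cell)^-1 s^-1,True
k_tg_plus,0.000108,7.32e-5,5.46e-5,(#/cell)^-1 s^-1,True
k_dm,0.105,0.18,0.253,s^-1,True
kf0,1.75e-5,6.29e-6,8.42e-6,(#/cell)^-1 s^-1,True
k_ie_plus,0.132,0.225,0.317,s^-1,True
k_o_minus,8,8,8,s^-1,False
k_o,0.15,0.15,0.15,s^-1,False
B0,1.709e7,1.709e7,1.709e7,#molecules,False
A0,1.5e3,1.5e3,1.5e3,#molecules,False
I0,1.5e3,1.5e3,1.5e3,#molecules,False
E0,1e3,1e3,1e3,#molecules,False
F0,2.4e5,2.4e5,2.4e5,#molecules,False
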