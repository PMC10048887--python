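site,stereopath,enantiomer,multiplicity,d_r_e,de_act,d_r_h,dh_act,d_r_g,dg_act,d_r_g_cor,dg_act_cor,hyd_d_r_g_cor
delta,cis,R,2,-4.11,17.4,-6.13,12.8,-3.82,17.6,-7.05,12.4,-47.4
delta,trans,S,2,-4.64,15.4,-5.56,10.9,-5.10,15.4,-8.30,10.8,-48.4
delta,cis,R,4,-0.183,18.7,-1.59,13.8,-0.548,18.8,-2.64,13.6,-45.6
delta,trans,S,4,-1.03,16.5,-1.16,13.0,-3.67,13.4,-5.08,9.87,-47.3
delta,cis,R,6,-6.52,19.6,-7.19,15.9,-13.3,15.8,-9.18,12.8,-54.0
delta,trans,S,6,-7.36,17.3,-7.35,14.4,-15.1,12.5,-11.5,10.1,-54.2
alpha,none,none,2,17.4,21.5,15.4,16.8,18.9,22.2,17.4,15.3,-50.0
alpha,none,none,4,13.0,18.8,13.6,15.3,14.3,18.5,10.8,12.8,-43.4
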