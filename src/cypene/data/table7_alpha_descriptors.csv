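site,stereopath,enantiomer,multiplicity,d_r_e,de_act,d_r_h,dh_act,d_r_g,dg_act,d_r_g_cor,dg_act_cor,hyd_d_r_g_cor
epsilon,cis,S,2,-13.6,15.9,-12.9,12.9,-13.4,12.5,-15.0,9.00,-50.2
epsilon,trans,R,2,-14.8,14.6,-14.8,11.0,-10.5,16.6,-13.8,12.2,-48.9
epsilon,cis,S,4,-0.1,18.0,-0.215,14.1,-0.981,16.4,-3.06,12.3,-36.8
epsilon,trans,R,4,0.814,16.7,0.413,12.7,-1.10,15.0,-1.87,11.2,-37.9
epsilon,cis,S,6,-16.0,18.7,-15.8,14.7,-18.6,15.5,-18.7,12.7,-53.9
epsilon,trans,R,6,-15.7,17.5,-16.8,13.0,-14.1,17.3,-15.2,13.2,-53.9
alpha,none,none,2,18.4,22.8,18.0,18.7,18.3,21.4,14.8,15.9,-50.2
alpha,none,none,4,16.7,24.9,15.9,20.6,15.7,23.1,13.5,18.1,-37.1
gamma,none,none,2,-3.18,16.1,-4.05,12.5,-0.516,16.9,-5.73,12.6,-41.9
gamma,none,none,4,1.09,18.0,0.612,14.0,0.437,15.8,-1.80,14.2,-30.8
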