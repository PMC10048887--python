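site,stereopath,multiplicity,g_hartree,printed_mole_fraction,printed_percent,printed_drg,printed_dgact,suspect
alpha,none,2,-1976.018408,0,0,14.8,17.6,false
alpha,none,4,-1976.021248,0,0,13.5,18.1,false
epsilon,trans,2,-1976.064967,0.864,86.4,-13.8,12.2,false
epsilon,cis,2,-1976.063223,0.136,13.6,-15.0,8.99,false
epsilon,trans,4,-1976.043787,0,0,-1.87,11.2,false
epsilon,cis,4,-1976.046371,0,0,-3.06,12.3,false
epsilon,trans,6,-1976.048297,0,0,-15.2,13.2,false
epsilon,cis,6,-1976.051903,0,0,-18.7,12.7,false
gamma,none,2,-1976.052329,0,0,-5.73,12.6,false
gamma,none,4,-1976.044266,0,0,-1.80,14.2,false
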