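site,stereopath,multiplicity,g_hartree,printed_mole_fraction,printed_percent,printed_drg,printed_dgact,suspect
alpha,none,2,-1976.041937,0.0871,8.71,14.8,17.6,false
alpha,none,4,-1976.024096,0.209,20.9,13.5,18.1,true
epsilon,trans,2,-1976.042897,0.241,24.1,-13.8,12.2,false
epsilon,cis,2,-1976.039343,0.00557,0.557,-15.0,8.99,false
epsilon,trans,4,-1976.040800,0.0261,2.61,-1.87,11.2,false
epsilon,cis,4,-1976.041490,0.0542,5.42,-3.06,12.3,false
epsilon,trans,6,-1976.024055,0,0,-15.2,13.2,false
epsilon,cis,6,-1976.022164,0,0,-18.7,12.7,false
gamma,none,2,-1976.043191,0.329,32.9,-5.73,12.6,false
gamma,none,4,-1976.041393,0.0489,4.89,-1.80,14.2,false
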