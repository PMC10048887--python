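site,stereopath,multiplicity,g_hartree,printed_mole_fraction,printed_percent,printed_drg,printed_dgact,suspect
alpha,none,2,-1976.037587,0.49,48.77,28.1,15.3,false
alpha,none,4,-1976.030510,0,0.03,10.8,12.8,false
delta,trans,2,-1976.035861,0.08,7.83,-8.3,10.8,false
delta,cis,2,-1976.036419,0.14,14.14,-7.05,12.4,false
delta,cis,4,-1976.037104,0.29,29.23,-2.64,13.6,false
delta,trans,4,-1976.014863,0,0,-5.08,9.87,false
delta,cis,6,-1976.015837,0,0,-9.18,12.8,false
delta,trans,6,-1976.014863,0,0,-11.5,10.1,false
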