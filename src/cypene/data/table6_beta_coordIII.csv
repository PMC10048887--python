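site,stereopath,multiplicity,g_hartree,printed_mole_fraction,printed_percent,printed_drg,printed_dgact,suspect
alpha,none,2,-1975.973971,0,0,28.1,15.3,false
alpha,none,4,-1975.973075,0,0,10.8,12.8,false
delta,trans,2,-1976.009716,0.534,53.4,-8.3,10.8,false
delta,cis,2,-1976.009578,0.461,46.1,-7.05,12.4,false
delta,cis,4,-1976.004151,0.00147,0.147,-2.64,13.6,false
delta,trans,4,-1976.004891,0.00321,0.321,-5.08,9.87,false
delta,cis,6,-1976.000132,0,0,-9.18,12.8,false
delta,trans,6,-1976.001255,0,0,-11.5,10.1,false
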