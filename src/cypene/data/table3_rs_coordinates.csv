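site,stereopath,enantiomer,multiplicity,coordinate,g_ref_kcal
epsilon,cis,S,2,1,2.41
epsilon,cis,S,2,2,11.4
epsilon,cis,S,2,3,-12.6
epsilon,cis,R,2,1,2.40
epsilon,cis,R,2,2,11.4
epsilon,cis,R,2,3,-12.6
epsilon,trans,S,2,1,0.184
epsilon,trans,S,2,2,12.4
epsilon,trans,S,2,3,-13.7
epsilon,trans,R,2,1,0.184
epsilon,trans,R,2,2,12.4
epsilon,trans,R,2,3,-13.7
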