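kind,site,stereopath,g_hartree,printed_kcal
radical,alpha,none,-389.788789,21.7
radical,gamma,none,-389.819706,2.27
radical,delta,none,-389.777607,28.7
radical,epsilon,none,-389.823321,0
radical,zeta,none,-389.790994,20.3
radical,theta,none,-389.794206,18.3
radical,iota,none,-389.795916,17.2
radical,kappa,none,-389.796285,17
hydroxylated,alpha,none,-465.658506,1.4
hydroxylated,gamma,none,-465.645667,9.45
hydroxylated,delta,none,-465.660286,0.28
hydroxylated,epsilon,cis,-465.651306,5.91
hydroxylated,epsilon,trans,-465.652273,5.31
hydroxylated,zeta,none,-465.660730,0.00
hydroxylated,theta,none,-465.654240,4.07
hydroxylated,iota,none,-465.646394,9
hydroxylated,kappa,none,-465.646120,9.17
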