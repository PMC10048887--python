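kind,site,stereopath,g_hartree,printed_kcal
radical,alpha,none,-389.784833,21.9
radical,gamma,none,-389.770224,31.1
radical,delta,none,-389.819707,0
radical,epsilon,none,-389.797584,13.9
radical,zeta,none,-389.786313,20.9
radical,theta,none,-389.788711,19.4
radical,iota,none,-389.789920,18.7
radical,kappa,none,-389.790510,18.3
hydroxylated,alpha,none,-465.653831,0.57
hydroxylated,gamma,none,-465.649621,3.21
hydroxylated,delta,cis,-465.645132,6.03
hydroxylated,delta,trans,-465.644727,6.28
hydroxylated,epsilon,cis,-465.6451796,6.00
hydroxylated,epsilon,trans,-465.6473512,4.63
hydroxylated,zeta,none,-465.6547380,0
hydroxylated,theta,none,-465.6488230,3.71
hydroxylated,iota,none,-465.6375598,10.78
hydroxylated,kappa,none,-465.6399752,9.26
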