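receptor,variant,ligand,pEC50_neg_log10_M,pEC50_sd,EmaxPrime_fold_over_basal,EmaxPrime_sd,EmaxPrime_flag,tau,tau_sd,tau_flag,pKA_neg_log10_M,pKA_sd,pKA_flag,RAi,RAi_sd,RAi_flag,system_Emax_fold_over_basal,system_Emax_sd
M2,cotransfected,carbachol,5.59,0.12,4.62,0.37,,0.88,0.17,,5.52,0.17,dagger,1,0.03,,5.8,0.4
M2,cotransfected,oxotremorine,6.53,0.13,4.46,0.33,,0.85,0.15,,6.26,0.10,dagger,5.41,0.05,dagger,5.8,0.4
M2,fused,carbachol,6.99,0.06,18,0.4,,1.41,0.03,,6.6,0.06,,1,0.01,,30.7,0.603
M2,fused,oxotremorine,8.22,0.08,22.4,0.6,*,2.8,0.08,*,7.64,0.08,,21.4,0.4,,30.7,0.603
M2,wt,carbachol,6.01,0.04,1.91,0.07,,0.2,0.1,,5.9,0.1,,1,0.01,,5.5,0.4
M2,wt,oxotremorine,6.68,0.05,1.60,0.05,,0.2,0.1,,6.6,0.1,,3.08,0.28,,5.5,0.4
M5,cotransfected,carbachol,6.61,0.08,11.7,0.4,,0.814,0.03,,6.35,0.08,dagger,1,0.02,,21,
M5,cotransfected,iperoxo,8.95,0.14,11.4,0.8,,0.785,0.057,,8.7,0.14,dagger,213,9,dagger,21,
M5,fused,carbachol,7.03,0.02,15.3,0.2,,1.126,0.015,,6.7,0.02,,1,0.01,,29,3
M5,fused,iperoxo,8.72,0.14,11.3,0.4,*,0.825,0.031,*,8.46,0.14,,35,1,,29,3
M5,wt,carbachol,6.09,0.16,10.1,1.1,,0.68,0.077,,5.86,0.16,,1,0.06,,22,2
M5,wt,iperoxo,8.93,0.16,13,1.1,*,1.08,0.09,*,8.61,0.16,,912,45,dagger,22,2
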