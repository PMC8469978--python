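receptor,ligand,tau,tau_sd,pKA_neg_log10_M,pKA_sd,RAi,RAi_sd,RAi_flag,system_Emax_fold_over_basal,system_Emax_sd
M1,arecoline,0.594,0.057,6.68,0.01,0.45,0.025,,27.1,0.5
M1,carbachol,0.887,0.017,6.8,0.06,1,0.01,,27.1,0.5
M1,furmethide,0.655,0.005,6.3,0.03,0.234,0.001,,27.1,0.5
M1,iperoxo,1.577,0.055,8.24,0.03,45.9,0.9,,27.1,0.5
M1,McN-A-343,0.472,0.02,6.53,0.1,0.248,0.006,,27.1,0.5
M1,NDMC,0.5,0.009,7.43,0.05,2.4,0.02,*,27.1,0.5
M1,oxotremorine,0.869,0.027,7.82,0.05,10.3,0.2,,27.1,0.5
M1,pilocarpine,0.668,0.04,6.29,0.02,0.234,0.008,,27.1,0.5
M1,xanomeline,0.795,0.007,8.25,0.02,25,0.1,,27.1,0.5
M1,JR6,0,,,,0,,,27.1,0.5
M1,JR7,0,,,,0,,,27.1,0.5
M2,arecoline,1.566,0.038,6.73,0.06,1.47,0.02,*,30.7,0.603
M2,carbachol,1.41,0.028,6.6,0.06,1,0.01,,30.7,0.603
M2,furmethide,1.669,0.034,6.18,0.03,0.446,0.005,*,30.7,0.603
M2,iperoxo,9.61,0.227,7.62,0.08,71.3,1,,30.7,0.603
M2,McN-A-343,1.033,0.021,6.68,0.04,0.875,0.010,*,30.7,0.603
M2,NDMC,0.951,0.016,6.7,0.02,0.846,0.008,,30.7,0.603
M2,oxotremorine,2.799,0.081,7.64,0.08,21.4,0.4,*,30.7,0.603
M2,pilocarpine,0.946,0.02,6.39,0.02,0.407,0.005,*,30.7,0.603
M2,xanomeline,1.669,0.034,8.15,0.03,41.9,0.5,*,30.7,0.603
M2,JR6,0,,,,0,,,30.7,0.603
M2,JR7,0,,,,0,,,30.7,0.603
M3,arecoline,0.541,0.004,7.1,0.01,1.05,0,,27.1,0.6
M3,carbachol,0.918,0.02,6.8,0.08,1,0.01,,27.1,0.6
M3,furmethide,0.656,0.009,5.95,0.31,0.102,0.001,,27.1,0.6
M3,iperoxo,2.926,0.876,8.56,0.1,176,30,*,27.1,0.6
M3,McN-A-343,0.307,0.046,5.81,0.13,0.028,0.002,,27.1,0.6
M3,NDMC,0.497,0.003,7.43,0.06,2.35,0.01,,27.1,0.6
M3,oxotremorine,0.834,0.027,7.84,0.05,10,0.2,,27.1,0.6
M3,pilocarpine,0.697,0.039,6.31,0.01,0.247,0.008,,27.1,0.6
M3,xanomeline,0.777,0.022,8.25,0.03,23.8,0.4,,27.1,0.6
M3,JR6,0,,,,0,,,27.1,0.6
M3,JR7,0,,,,0,,,27.1,0.6
M4,arecoline,0.804,0.071,7.19,0.04,1.11,0.06,,27.1,1.2
M4,carbachol,0.897,0.04,7.1,0.01,1,0.03,,27.1,1.2
M4,furmethide,0.865,0.084,6.64,0.01,0.33,0.018,,27.1,1.2
M4,iperoxo,1.273,0.055,7.87,0.03,8.26,0.21,,27.1,1.2
M4,McN-A-343,0.704,0.07,6.93,0.02,0.523,0.03,,27.1,1.2
M4,NDMC,0.623,0.05,6.8,0.02,0.346,0.016,,27.1,1.2
M4,oxotremorine,0.994,0.049,7.95,0.01,7.76,0.22,,27.1,1.2
M4,pilocarpine,0.557,0.054,6.47,0.01,0.144,0.008,,27.1,1.2
M4,xanomeline,0.866,0.084,8.59,0.01,29.6,1.7,,27.1,1.2
M4,JR6,0,,,,0,,,27.1,1.2
M4,JR7,0,,,,0,,,27.1,1.2
M5,arecoline,0.51,0.005,7.02,0.14,0.76,0.005,,28.9,0.4
M5,carbachol,1.126,0.015,6.7,0.02,1,0.01,,28.9,0.4
M5,furmethide,1.072,0.01,6.25,0.03,0.336,0.002,,28.9,0.4
M5,iperoxo,0.825,0.031,8.46,0.14,35,1,,28.9,0.4
M5,McN-A-343,0.358,0.009,6.96,0.11,0.452,0.006,,28.9,0.4
M5,NDMC,0.709,0.009,7.07,0.03,1.47,0.01,,28.9,0.4
M5,oxotremorine,1.555,0.016,7.72,0.03,14.5,0.1,,28.9,0.4
M5,pilocarpine,0.8,0.023,6.34,0.01,0.309,0.005,,28.9,0.4
M5,xanomeline,1.172,0.015,8.2,0.01,33,0.2,,28.9,0.4
M5,JR6,0,,,,0,,,28.9,0.4
M5,JR7,0,,,,0,,,28.9,0.4
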