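receptor,ligand,site,pKI_neg_log10_M,pKI_sd
M1,arecoline,low,5.19,0.06
M2,arecoline,low,4.68,0.03
M3,arecoline,low,5.17,0.08
M4,arecoline,low,4.68,0.01
M5,arecoline,low,5.16,0.04
M1,carbachol,low,4.87,0.01
M2,carbachol,low,4.62,0.01
M3,carbachol,low,4.77,0.02
M4,carbachol,low,4.61,0.02
M5,carbachol,low,4.72,0.01
M1,furmethide,low,5.79,0.01
M2,furmethide,low,4.69,0.04
M3,furmethide,low,5.27,0.03
M4,furmethide,low,4.71,0.01
M5,furmethide,low,5.25,0.02
M1,iperoxo,high,8.35,0.12
M1,iperoxo,low,6.20,0.08
M2,iperoxo,low,5.83,0.03
M3,iperoxo,low,6.06,0.04
M4,iperoxo,low,5.96,0.03
M5,iperoxo,low,6.99,0.02
M1,McN-A-343,low,4.24,0.04
M2,McN-A-343,low,6.54,0.04
M3,McN-A-343,low,5.14,0.02
M4,McN-A-343,low,6.41,0.02
M5,McN-A-343,low,5.34,0.06
M1,NDMC,low,7.06,0.01
M2,NDMC,low,6.51,0.04
M3,NDMC,low,6.75,0.02
M4,NDMC,low,6.40,0.01
M5,NDMC,low,6.77,0.03
M1,oxotremorine,low,6.61,0.01
M2,oxotremorine,low,5.70,0.04
M3,oxotremorine,low,6.24,0.03
M4,oxotremorine,low,5.86,0.02
M5,oxotremorine,low,6.16,0.03
M1,pilocarpine,low,5.26,0.02
M2,pilocarpine,low,4.52,0.01
M3,pilocarpine,low,4.92,0.02
M4,pilocarpine,low,4.54,0.03
M5,pilocarpine,low,4.88,0.04
M1,xanomeline,low,7.29,0.01
M2,xanomeline,low,6.82,0.02
M3,xanomeline,low,7.19,0.04
M4,xanomeline,low,7.04,0.03
M5,xanomeline,low,7.06,0.02
M4,JR6,high,6.73,0.28
M1,JR6,low,4.97,0.07
M2,JR6,low,5.74,0.10
M3,JR6,low,5.07,0.04
M4,JR6,low,5.29,0.21
M5,JR6,low,5.44,0.05
M1,JR7,low,4.34,0.05
M2,JR7,low,5.17,0.07
M3,JR7,low,4.22,0.06
M4,JR7,low,4.82,0.03
M5,JR7,low,4.46,0.04
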