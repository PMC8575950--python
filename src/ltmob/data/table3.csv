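element_id,accession,category,mechanism,organism,freq_lo,freq_hi,titre_tru_per_ml,accessory_orfs,total_orfs,source,printed_frequency_lo,printed_frequency_hi,printed_cargo_rate,printed_mobility_lo,printed_mobility_hi,flags,note
pSLT,CP001362,plasmid,conjugation,salmonella,4.20e-6,2.90e-4,,54,102,ref 50,4.20e-6,2.90e-4,0.53,2.22e-6,1.54e-4,,
pS3,,plasmid,conjugation,salmonella,1.30e-7,,,52,82,ref 51,1.30e-7,,0.63,8.24e-8,,,count-only record (no accession)
pOU1114,DQ115387,plasmid,conjugation,salmonella,4.30e-2,,,27,47,ref 52,4.30e-2,,0.57,2.47e-2,,,
pESI,,plasmid,conjugation,salmonella,4.00e-6,,,,,ref 53,4.00e-6,,,,,,"cargo ND, no accession"
pWW012,CP022169,plasmid,conjugation,salmonella,1.20e-6,,,,,ref 54,1.20e-6,,,,,,cargo ND
P22,,phage,lysogenisation,salmonella,,,1.57e8,5,70,this work,1.57,,0.07,1.12e-1,,,titre is the replicate mean (companion strain table); cargo is sieAB and gtrABC
ICESb1,FN298494.1,ICE,conjugation,salmonella,1.10e-6,,,81,105,ref 55,1.10e-6,,0.77,8.49e-7,,,
SGI3,,ICE,conjugation,salmonella,1.20e-7,1.30e-4,,57,86,ref 56,1.20e-7,1.30e-4,0.66,7.95e-8,8.62e-5,,
tetA_HF1_GT,AE006468.2,chromosomal_marker,GT,salmonella,1.52e-4,,,41,41,ref 17,1.52e-4,,1.00,1.52e-4,,,P22-mediated GT; HF1 estimated as if packaging ends where LT HF1 does
tetA_HF2_GT,AE006468.2,chromosomal_marker,GT,salmonella,1.64e-4,,,33.5,33.5,ref 17,1.64e-4,,1.00,1.64e-4,,,P22-mediated GT
tetA_HF3_GT,AE006468.2,chromosomal_marker,GT,salmonella,3.07e-4,,,44,44,ref 17,3.07e-4,,1.00,3.07e-4,,,P22-mediated GT
tetA_HF4_GT,AE006468.2,chromosomal_marker,GT,salmonella,3.00e-4,,,37,37,ref 17,3.00e-4,,1.00,3.00e-4,,,P22-mediated GT
tetA_HF5_GT,AE006468.2,chromosomal_marker,GT,salmonella,3.13e-5,,,42,42,ref 17,3.13e-5,,1.00,3.13e-5,,,P22-mediated GT
tetA_HF6_GT,AE006468.2,chromosomal_marker,GT,salmonella,2.00e-5,,,43,43,ref 17,2.00e-5,,1.00,2.00e-5,,,P22-mediated GT
tetA_HF7_GT,AE006468.2,chromosomal_marker,GT,salmonella,1.93e-5,,,43,43,ref 17,1.93e-5,,1.00,1.93e-5,,,P22-mediated GT
tetA_HF1_LT,AE006468.2,chromosomal_marker,LT,salmonella,2.33e-3,,,21.5,42.5,ref 17,2.33e-3,,0.51,1.18e-3,,,P22-mediated LT; part of HF1 is phage DNA
tetA_HF2_LT,AE006468.2,chromosomal_marker,LT,salmonella,9.27e-3,,,33.5,33.5,ref 17,9.27e-3,,1.00,9.27e-3,,,P22-mediated LT
tetA_HF3_LT,AE006468.2,chromosomal_marker,LT,salmonella,6.83e-4,,,44,44,ref 17,6.83e-4,,1.00,6.83e-4,,,P22-mediated LT
tetA_HF4_LT,AE006468.2,chromosomal_marker,LT,salmonella,2.40e-3,,,37,37,ref 17,2.40e-3,,1.00,2.40e-3,,,P22-mediated LT
tetA_HF5_LT,AE006468.2,chromosomal_marker,LT,salmonella,1.33e-3,,,42,42,ref 17,1.33e-3,,1.00,1.33e-3,,,P22-mediated LT
tetA_HF6_LT,AE006468.2,chromosomal_marker,LT,salmonella,4.97e-4,,,43,43,ref 17,4.97e-4,,1.00,4.97e-4,,,P22-mediated LT
tetA_HF7_LT,AE006468.2,chromosomal_marker,LT,salmonella,9.87e-5,,,43,43,ref 17,9.87e-5,,1.00,9.87e-5,,,P22-mediated LT
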