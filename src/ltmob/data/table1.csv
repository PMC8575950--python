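element_id,accession,category,mechanism,organism,freq_lo,freq_hi,titre_tru_per_ml,accessory_orfs,total_orfs,source,printed_frequency_lo,printed_frequency_hi,printed_cargo_rate,printed_mobility_lo,printed_mobility_hi,flags,note
pGO1,NC_012547,plasmid,conjugation,s_aureus,1.4e-7,6.0e-5,,28,55,refs 42;43,1.4e-7,6.0e-5,0.51,7.13e-8,3.05e-5,,
pAM387,,plasmid,conjugation,s_aureus,1.1e-6,,,,,ref 44,1.1e-6,,,,,,"cargo ND, no accession"
pWBG749e,,plasmid,conjugation,s_aureus,2.8e-5,6.25e-4,,23,52,ref 45,2.8e-5,6.25e-4,0.44,1.24e-5,2.76e-4,,count-only record (no accession)
pC223,NC_005243,plasmid,mobilisation,s_aureus,4.5e-6,,,1,5,refs 42;46,4.5e-6,,0.20,9.00e-7,,,mobilised via pGO1
phiSLT,AB045978.2,phage,lysogenisation,s_aureus,7.69e-3,,,3,60,ref 47,7.69e-3,,0.05,3.85e-4,,,
80alpha,NC_009526,phage,lysogenisation,s_aureus,,,1.10e6,3,73,this work,1.69e-2,,0.04,6.95e-4,,,titre is the replicate mean (companion strain table)
phi11,AF424781,phage,lysogenisation,s_aureus,,,3.00e7,3,53,this work,4.62e-1,,0.06,2.62e-2,,,titre is the replicate mean (companion strain table)
SaPI1,U93688.2,PICI,PICI_transfer,s_aureus,2.46,,,4,26,ref 26,2.46,,0.15,3.78e-1,,,
SaPIbov1,AF217235.1,PICI,PICI_transfer,s_aureus,6.31e-1,,,3,21,ref 26,6.31e-1,,0.14,9.01e-2,,,
SaPI2,EF010993,PICI,PICI_transfer,s_aureus,2.20e-1,,,2,24,ref 26,2.20e-1,,0.04,2.20e-2,,cargo_rate;mobility,printed rate 0.04 and mobility 2.20e-2 inconsistent with printed counts 2/24 and frequency 2.20e-1 (which give 0.08 and 1.83e-2); stored as printed with no silent correction
ICE6013,PRJNA360134,ICE,conjugation,s_aureus,1.16e-7,,,7,16,ref 48,1.16e-7,,0.44,5.08e-8,,,strain DAR6247
Tn916,U09422,ICE,conjugation,s_aureus,6.0e-9,3.4e-8,,2,24,ref 49,6.0e-9,3.4e-8,0.08,5.00e-10,6.25e-11,mobility_hi,printed upper mobility 6.25e-11 inconsistent with 3.4e-8 x 2/24 = 2.83e-9; lower endpoint 5.00e-10 reproduces from 6.0e-9 x 2/24
CadR_HF1_GT,NC_007795.1,chromosomal_marker,GT,s_aureus,5.58e-6,,,47,47,ref 16,5.58e-6,,1.00,5.58e-6,,,80alpha-mediated GT; HF1 estimated as if packaging ends where LT HF1 does
CadR_HF3_GT,NC_007795.1,chromosomal_marker,GT,s_aureus,5.69e-6,,,39,39,ref 16,5.69e-6,,1.00,5.69e-6,,,80alpha-mediated GT
CadR_HF5_GT,NC_007795.1,chromosomal_marker,GT,s_aureus,6.31e-6,,,40,40,ref 16,6.31e-6,,1.00,6.31e-6,,,80alpha-mediated GT
CadR_HF7_GT,NC_007795.1,chromosomal_marker,GT,s_aureus,5.12e-6,,,41.5,41.5,ref 16,5.12e-6,,1.00,5.12e-6,,,80alpha-mediated GT; half-ORF at the headful boundary
CadR_HF1_LT,NC_007795.1,chromosomal_marker,LT,s_aureus,5.18e-2,,,17.5,51,ref 16,5.18e-2,,0.34,1.78e-2,,,80alpha-mediated LT; part of HF1 is phage DNA
CadR_HF3_LT,NC_007795.1,chromosomal_marker,LT,s_aureus,8.00e-3,,,39,39,ref 16,8.00e-3,,1.00,8.00e-3,,,80alpha-mediated LT
CadR_HF5_LT,NC_007795.1,chromosomal_marker,LT,s_aureus,4.51e-3,,,40,40,ref 16,4.51e-3,,1.00,4.51e-3,,,80alpha-mediated LT
CadR_HF7_LT,NC_007795.1,chromosomal_marker,LT,s_aureus,1.45e-3,,,41.5,41.5,ref 16,1.45e-3,,1.00,1.45e-3,,,80alpha-mediated LT
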