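strain,phage,organism,phage_pfu_mean,phage_pfu_sd,lysogeny_tru_mean,lysogeny_tru_sd,lt_tru_mean,lt_tru_sd,gt_tru_mean,gt_tru_sd,printed_lysogeny_te,printed_lt_te,printed_gt_te,n_replicates,flags,note
JP20844,phi11,s_aureus,6.00e8,1.83e8,3.00e7,2.31e7,5.00e5,1.15e4,2.00e5,1.15e5,4.62e-1,7.69e-3,3.08e-3,4,,GT column is plasmid pJP2511 transfer
JP20846,80alpha,s_aureus,1.15e9,7.23e8,1.10e6,6.16e5,3.25e5,2.63e5,5.50e4,5.77e3,1.69e-2,5.00e-3,8.46e-4,4,,GT column is plasmid pJP2511 transfer
JP22210,P22,salmonella,2.03e8,1.10e8,1.57e8,8.33e7,,,,,1.567,,,3,lysogeny_te,printed 1.567 inconsistent with rounded mean titre 1.57e8 / 1.0e8 = 1.57 (companion comparative table prints 1.57); likely derived from unrounded replicate means
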