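organism,od_landmark,donor_cfu_per_ml,note
s_aureus,0.15,6.5e7,lysogens induced at OD540 0.15
salmonella,0.20,1.0e8,lysogens induced at OD600 0.20
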