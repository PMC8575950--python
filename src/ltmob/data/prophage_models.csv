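phage_id,organism,headful_size_bp,max_headfuls,note
80alpha,s_aureus,45000,7,capsid ~45-46 kb; LT packaging demonstrated over at least 7 processive headfuls
phi11,s_aureus,45000,7,staphylococcal pac phage with 80alpha-like headful size
P22,salmonella,43000,12,capsid ~43-44 kb; LT packaging demonstrated over 12 processive headfuls
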