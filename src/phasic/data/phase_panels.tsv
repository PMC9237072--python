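panel	gene
G1S	Ccne1
G1S	Cdc6
G1S	Cdc25a
G1S	Chaf1b
G1S	E2f1
G1S	Mcm5
G1S	Mcm6
G1S	Pcna
G1S	Slbp
G2M	Aurka
G2M	Birc5
G2M	Ccna2
G2M	Ccnb1
G2M	Ccnf
G2M	Cdc20
G2M	Cdk1
G2M	Cenpa
G2M	Cenpe
G2M	Cenpf
G2M	Cks2
G2M	Plk1
G2M	Racgap1
G2M	Top2a
G2M	Ube2c
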