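# canonical	synonyms (comma separated, matched case-insensitively, "MT-" prefix tolerated)
ND1	ND1,NAD1,NADH1,NADH-1,NU1M,MTND1
ND2	ND2,NAD2,NADH2,NADH-2,NU2M,MTND2
ND3	ND3,NAD3,NADH3,NADH-3,NU3M,MTND3
ND4	ND4,NAD4,NADH4,NADH-4,NU4M,MTND4
ND4L	ND4L,NAD4L,NADH4L,NU4LM,MTND4L
ND5	ND5,NAD5,NADH5,NADH-5,NU5M,MTND5
ND6	ND6,NAD6,NADH6,NADH-6,NU6M,MTND6
CYTB	CYTB,CYB,COB,CB,MTCYB
CO1	CO1,COX1,COI,COXI,COX-1,MTCO1
CO2	CO2,COX2,COII,COXII,COX-2,MTCO2
CO3	CO3,COX3,COIII,COXIII,COX-3,MTCO3
ATP6	ATP6,ATPASE6,ATPASE-6,ATP-6,MTATP6
ATP8	ATP8,ATPASE8,ATPASE-8,ATP-8,MTATP8
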