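gene	transcript	direction	species
INS	NM_000207	beta_up	human
INS	NM_001185097	beta_up	human
HADH	NM_005327	beta_up	human
PFKFB2	NM_006212	beta_up	human
G6PC2	NM_001081686	beta_up	human
RPL3	NM_000967	beta_up	human
EIF4A2	NM_001967	beta_up	human
RRAGD	NM_021244	beta_up	human
HNRNPC	NM_004500	beta_up	human
IAPP	NM_000415	beta_up	human
CANX	NM_001024649	beta_up	human
FAM162A	NM_014367	beta_up	human
ACAT1	NM_000019	beta_up	human
TVP23B	NM_001316920	beta_up	human
SERINC1	NM_020755	beta_up	human
ATP6V1A	NM_001690	beta_up	human
CCNI	NM_006835	beta_up	human
NDUFA9	NM_005002	beta_up	human
SLC30A8	NM_173851	beta_up	human
NACA	NM_001113202	beta_up	human
TMEM60	NM_032936	beta_up	human
TMEM33	NM_018126	beta_up	human
SDHB	NM_003000	beta_up	human
COMMD3	NM_012071	beta_up	human
METTL5	NM_001293187	beta_up	human
SDCBP	NM_005625	beta_up	human
SDCBP	NM_001007069	beta_up	human
IRF2BP2	NM_182972	beta_up	human
SLC39A9	NM_001252151	beta_up	human
IRF2BP2	NM_001077397	beta_up	human
SLC39A9	NM_001252152	beta_up	human
HSPA8	NM_006597	beta_up	human
TMED2	NM_006815	beta_up	human
SCGN	NM_006998	beta_up	human
HSP90AB1	NM_007355	beta_up	human
JKAMP	NM_016475	beta_up	human
SLC30A8	NM_001172814	beta_up	human
RAB1A	NM_004161	beta_up	human
PSMD7	NM_002811	beta_up	human
CSDE1	NM_007158	beta_up	human
TXLNA	NM_175852	beta_up	human
ARF6	NM_001663	beta_up	human
ANAPC13	NM_015391	beta_up	human
EIF3M	NM_006360	beta_up	human
PEBP1	NM_002567	beta_up	human
ANXA2	NM_004039	beta_up	human
MRPS33	NM_053035	beta_up	human
CACUL1	NM_153810	beta_up	human
NDUFB5	NM_002492	beta_up	human
MAPRE1	NM_012325	beta_up	human
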