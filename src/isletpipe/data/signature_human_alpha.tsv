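gene	transcript	direction	species
GCG	NM_002054	alpha_up	human
TTR	NM_000371	alpha_up	human
GC	NM_001204307	alpha_up	human
TMEM176B	NM_001101312	alpha_up	human
HIGD1A	NM_014056	alpha_up	human
GPX3	NM_002084	alpha_up	human
TM4SF4	NM_004617	alpha_up	human
FABP5	NM_001444	alpha_up	human
LDHA	NM_005566	alpha_up	human
NAA20	NM_016100	alpha_up	human
CRYBA2	NM_057094	alpha_up	human
SERPINA1	NM_000295	alpha_up	human
PDK4	NM_002612	alpha_up	human
HLA-E	NM_005516	alpha_up	human
PALLD	NM_001166110	alpha_up	human
C10orf10	NM_007021	alpha_up	human
ITGB1	NM_133376	alpha_up	human
SSR4	NM_006280	alpha_up	human
PRDX4	NM_006406	alpha_up	human
FKBP2	NM_004470	alpha_up	human
TUBA1B	NM_006082	alpha_up	human
TAPBP	NM_172209	alpha_up	human
PEMT	NM_148173	alpha_up	human
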