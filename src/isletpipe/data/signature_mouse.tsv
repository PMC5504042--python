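gene	transcript	direction	species
GCG		alpha_up	mouse
TTR		alpha_up	mouse
HIGD1A		alpha_up	mouse
GPX3		alpha_up	mouse
PDK4		alpha_up	mouse
INS		beta_up	mouse
HADH		beta_up	mouse
G6PC2		beta_up	mouse
RRAGD		beta_up	mouse
IAPP		beta_up	mouse
FAM46A		beta_up	mouse
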