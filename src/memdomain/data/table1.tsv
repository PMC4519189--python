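species	count_inner	count_outer
CHOL	245	245
PC_16:0/18:2	25	63
PC_16:0/18:1	20	52
SM_16:0/16:0	0	140
PS_18:0/20:4	90	0
PE_16:0/18:1	30	0
PE_18:0/20:4	30	0
PE_16:0/20:4	20	0
PEpl_16:0/20:4	28	0
PEpl_18:0/20:4	12	0
W	10000	0
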