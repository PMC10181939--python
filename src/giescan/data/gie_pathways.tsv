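gene	pathway	mechanism	coding_len	pathway_name
HLA-A	1	loss	1098	HLA-I
HLA-B	1	loss	1089	HLA-I
HLA-C	1	loss	1101	HLA-I
B2M	2	loss	360	antigen_presentation
CALR	2	loss	1254	antigen_presentation
TAP1	2	loss	2427	antigen_presentation
TAP2	2	loss	2121	antigen_presentation
TAPBP	2	loss	1407	antigen_presentation
NLRC5	2	loss	5691	antigen_presentation
CIITA	2	loss	3397	antigen_presentation
RFX5	2	loss	1851	antigen_presentation
JAK1	3	loss	3399	ifn_gamma
JAK2	3	loss	3399	ifn_gamma
IRF2	3	loss	1050	ifn_gamma
IFNGR1	3	loss	1470	ifn_gamma
IFNGR2	3	loss	1014	ifn_gamma
APLNR	3	loss	1143	ifn_gamma
STAT1	3	loss	2253	ifn_gamma
CD274	4	gain	873	pd_l1
CD58	5	loss	753	cd58
SETDB1	6	gain	3867	setdb1
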