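chr6	29910247	29913661	HLA-A	0	+
chr6	31321649	31324989	HLA-B	0	-
chr6	31236526	31239913	HLA-C	0	-
chr15	45003675	45011075	B2M	0	+
chr19	13049413	13055304	CALR	0	+
chr6	32812986	32821755	TAP1	0	-
chr6	32789610	32806557	TAP2	0	-
chr6	33267472	33282164	TAPBP	0	-
chr16	57023467	57116542	NLRC5	0	+
chr16	10971055	11002744	CIITA	0	+
chr1	151313116	151319769	RFX5	0	-
chr1	65298912	65432187	JAK1	0	-
chr9	4985245	5128183	JAK2	0	+
chr4	185308867	185395680	IRF2	0	-
chr6	137518620	137540609	IFNGR1	0	-
chr21	34775202	34809829	IFNGR2	0	-
chr11	57103453	57107212	APLNR	0	-
chr2	191829084	191885686	STAT1	0	-
chr9	5450503	5470567	CD274	0	+
chr1	117057157	117113661	CD58	0	-
chr1	150898814	150937220	SETDB1	0	+
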