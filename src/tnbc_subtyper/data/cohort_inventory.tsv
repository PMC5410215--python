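group	accession	country	bc_cases	tnbc_cases
non_asian	GSE12276	Netherlands	204	67
non_asian	GSE14017	USA	29	13
non_asian	GSE17907	France	51	1
non_asian	GSE18864	Denmark	84	53
non_asian	GSE19615	USA	115	35
non_asian	GSE19697	USA	24	24
non_asian	GSE20711	Canada	88	24
non_asian	GSE21653	France	266	91
non_asian	GSE31448	France	353	131
non_asian	GSE42568	Ireland	104	32
non_asian	GSE43502	USA	25	19
non_asian	GSE58812	France	107	96
non_asian	TOTAL	.	1450	494
taiwanese	GSE20685	Taiwan	327	57
taiwanese	GSE48390	Taiwan	81	16
taiwanese	GSE95700	Taiwan	57	50
taiwanese	TOTAL	.	465	123
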