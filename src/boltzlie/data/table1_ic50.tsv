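ligand_id	substituent	ic50_uM	ic50_sigma_uM	dg_exp	dg_err
L1	Ethyl	87	21	-23.32	0.69
L2	1-Propyl	42	14	-25.14	1.01
L3	cyclo-Hexyl	34	15	-25.66	1.45
L4	Phenyl	57	17	-24.37	0.88
L5	p-Methylphenyl	17	6.0	-27.39	1.09
L6	p-Methoxyphenyl	21	8.7	-26.86	1.34
L7	p-Chlorophenyl	3.5	1.2	-31.33	1.05
L8	Methylphenyl	7.0	1.2	-29.61	0.47
L9	Methyl-(p-methoxy)phenyl	4.1	1.4	-30.94	1.04
L10	Ethylphenyl	0.60	0.13	-35.73	0.61
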