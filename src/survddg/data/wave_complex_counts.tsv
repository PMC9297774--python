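gene	het_control	het_ko	homo_control	homo_ko
Abi1	14389	7343	15682	1018
Abi2	8173	7189	8031	9719
Abi3	146	271	343	195
Nckap1	36435	34964	40591	38802
Wasf1	88	66	85	118
Wasf2	8563	10349	13894	11087
Wasf3	261	151	95	221
Brk1	10240	9103	11091	9920
Cyfip1	23448	22528	31708	23030
Cyfip2	521	1289	1633	580
Rac1	25732	22621	27209	24431
Ndel1	10923	10842	15082	13030
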