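partition	NR	A1	A2	A3	A4	S	Pr
intersection	2	F_T = 1	SP_IN = 1	VEH_TY = 1	DR_INFR = 5	0.1033%	68.8%
intersection	3	WE_CO = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.23%	59.5%
intersection	4	RO_SU = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.2166%	58.03%
intersection	5	MAN = 1	PAV = 0	SP_IN = 1	ACT_TY = 2	0.1466%	57.89%
intersection	6	RO_SU = 1	ACT_TY = 5	DR_INFR = 5	MAN = 1	0.1166%	57.38%
intersection	7	DR_INFR = 5	SP_IN = 1	ACT_TY = 2		0.2432%	57.03%
intersection	8	I_L = 1	DR_INFR = 5	SP_IN = 1	ACT_TY = 2	0.2266%	56.66%
intersection	9	LUM = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.1733%	56.52%
intersection	10	I_T = 2	DR_INFR = 1	MAN = 8	O_L = 1	0.1033%	56.36%
intersection	11	SP_IN = 1	DR_INFR = 5	ACT_TY = 2	RES_VIS = 1	0.2%	55.55%
intersection	12	MAN = 8	SP_IN = 1	DR_INFR = 1		0.166%	50.5%
intersection	13	ACT_TY = 2	DR_INFR = 1	SP_IN = 1	SEX = 1	0.17%	46.79%
intersection	14	AG_FR = 2	PAV = 0	SP_IN = 1	ACT_TY = 2	0.16%	46.6%
intersection	15	VEH_TY = 1	ACT_TY = 2	MAN = 1	SP_IN = 1	0.2%	44.03%
intersection	16	LUM = 1	PAV = 0	SP_IN = 1	ACT_TY = 2	0.33%	38.17%
intersection	17	AN = 1	PAV = 0	SP_IN = 1	ACT_TY = 2	0.45%	37.6%
intersection	18	WE_CO = 1	PAV = 0	SP_IN = 1	ACT_TY = 2	0.423%	37.02%
intersection	19	F_T = 3	PAV = 0	ACT_TY = 2	SP_IN = 1	0.1766%	36.8%
intersection	20	RES_VIS = 1	PAV = 0	ACT_TY = 2	SP_IN = 1	0.397%	34.9%
intersection	21	AG_FR = 3	PAV = 0	SP_IN = 1	ACT_TY = 2	0.1866%	32.75%
intersection	22	AG_FR = 2	ACT_TY = 2	SP_IN = 1	I_T = 2	0.11%	31.73%
intersection	23	SEX = 1	DR_INFR = 1	ACT_TY = 1	PR = 1	0.213%	17.2%
intersection	24	RO_SU = 1	ACT_TY = 1	DR_INFR = 1	PR = 1	0.29%	16.86%
intersection	25	PR = 1	DR_INFR = 1	LUM = 1		0.24%	16.78%
intersection	26	WE_CO = 1	ACT_TY = 1	DR_INFR = 1	PR = 1	0.29%	16.6%
intersection	27	AN = 1	ACT_TY = 1	DR_INFR = 1	PR = 1	0.296%	16.45%
intersection	28	ACT_TY = 1	DR_INFR = 1	PR = 1		0.296%	16.42%
intersection	29	PAV = 0	DR_INFR = 1	ACT_TY = 1	PR = 1	0.296%	16.42%
intersection	30	S_W = 3	ACT_TY = 1	DR_INFR = 1	PR = 1	0.11%	14.86%
intersection	31	RES_VIS = 1	ACT_TY = 1	DR_INFR = 1	PR = 1	0.246%	14.77%
intersection	32	LUM = 1	ACT_TY = 1	DR_INFR = 1	PR = 1	0.183%	14.66%
non_intersection	1	SP_IN = 1	ACT_TY = 2	DR_INFR = 5	MAN = 8	0.117%	71.11%
non_intersection	2	S_W = 3	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.314%	64.18%
non_intersection	3	F_T = 4	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.245%	62.03%
non_intersection	4	TR_N_INT = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.574%	59.25%
non_intersection	5	LUM = 3	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.179%	59.03%
non_intersection	6	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	RO_SU = 1	0.56%	58.85%
non_intersection	7	MAN = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.38%	58.76%
non_intersection	8	SEX = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.46%	58.6%
non_intersection	9	AN = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.59%	58.06%
non_intersection	10	DR_INFR = 5	ACT_TY = 2	SP_IN = 1	O_L = 1	0.49%	58%
non_intersection	11	LUM = 1	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.377%	57.54%
non_intersection	12	I_L = 1	DR_INFR = 5	ACT_TY = 2	SP_IN = 1	0.56%	57.52%
non_intersection	13	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	RES_VIS = 1	0.5%	56.61%
non_intersection	14	VEH_TY = 2	ACT_TY = 2	DR_INFR = 5	SP_IN = 1	0.465%	55.95%
non_intersection	15	ACT_TY = 2	SP_IN = 1	DR_INFR = 1	PAV = 0	0.135%	54.41%
non_intersection	16	VEH_TY = 1	SP_IN = 1	DR_INFR = 5	F_T = 1	0.113%	53.45%
non_intersection	17	S_W = 1	ACT_TY = 2	SP_IN = 1	PAV = 0	0.143%	43.82%
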