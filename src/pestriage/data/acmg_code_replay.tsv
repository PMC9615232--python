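case_id	gene	variant_index	codes	expected_class	origin	inheritance
4	NFIA	1	PVS1, PS2, PM2	P	De novo	AD
19	NFIA	1	PS2, PM1, PM2, PP3	LP	De novo	AD
7	EZH2	1	PS2, PS3_PM, PS4_PP, PM2, PM5, PP3	P	De novo	AD
108	EZH2	1	PS2_PM, PM1_PP, PM2, PP3	LP	De novo	AD
12	PPP2R1A	1	PS2, PM2, PP3	LP	De novo	AD
30	PPP2R1A	1	PM1, PM2, PS3_PP, PS2_PVS	P	De novo	AD
21	ADNP	1	PVS1_PS, PS2_PM, PM2	LP	De novo	AD
46	ADNP	1	PVS1_PS, PS2, PM2	P	De novo	AD
18	ARV1	1	PVS1, PM2, PM3	P	Pat	AR
18	ARV1	2	PVS1, PM2_PP, PM3	P	Mat	AR
31	ZMYM2	1	PVS1, PS2_PP, PM2	P	De novo	AD
38	KCNK9	1	PS2_PVS, PS3_PP, PM2	P	De novo	AD
40	CRYAA	1	PS4, PM2, PP1_PS, PP3	P	Pat(affected)	AD
65	MAPK1	1	PS2, PM2, PP3, PP2	LP	De novo	AD
102	GDF5	1	PS2_PM, PM1_PP, PM2, PP3	P	De novo	AD
107	SCN4A	1	PVS1, PM2	LP	Mat	AR
107	SCN4A	2	PM2, PM3_PP, PM5, PP3	LP	De novo	AR
110	PUF60	1	PVS1_PM, PS2_PM, PM2	LP	De novo	AD
114	ZC4H2	1	PVS1_PS, PS2	P	De novo	XL
116	SMAD4	1	PS2, PS4, PM2_PP, PM5, PP3	P	De novo	AD
118	TPM2	1	PS3_PP, PS4_PM, PM2, PP3	LP	Mat (affected)	AD
159	BRPF1	1	PS2, PM2, PVS1_PS	P	De novo	AD
163	KAT6A	1	PVS1, PS2, PM2	P	De novo	AD
169	KMT2C	1	PVS1, PS2, PM2	P	De novo	AD
170	KCNT1	1	PM2, PP3, PS2_PVS	P	De novo	AD
172	NFIB	1	PM1, PP3, PS3_PP, PS2_PP, PM2	LP	De novo	AD
189	UBA1	1	PM1, PM2, PP3, PP4	LP	Mat	XR
206	PLOD3	1	PVS1, PM2	LP	Mat	AR
206	PLOD3	2	PVS1, PM2	LP	Pat	AR
218	MTOR	1	PS2, PM2, PP3, PP2	P	De novo	AD
219	KMT2A	1	PM2, PVS1, PS2_PM	P	De novo	AD
221	ARID1A	1	PS2, PM2, PVS1_PS	P	De novo	AD
225	CSNK2A1	1	PVS1_PS, PM1, PM2	LP	De novo	AD
229	CLCN5	1	PVS1_PS, PM1, PM2	LP	Mat	XR
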