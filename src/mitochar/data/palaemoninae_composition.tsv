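species	accession	region	size_bp	pct_a	pct_g	pct_t	pct_c	pct_at	at_skew	gc_skew
Palaemonetes_sinensis	MH880828	whole	15955	36.2	12.1	30.5	21.3	66.7	0.085	-0.275
Palaemon_serenus	KM978916.1	whole	15967	29.2	16.9	29.8	24.1	59.0	-0.010	-0.176
Palaemon_gravieri	KT935323.1	whole	15735	35.3	12.1	32.1	20.4	67.4	0.047	-0.255
Palaemon_gravieri	KU899135.1	whole	15740	35.3	12.1	32.1	20.5	67.4	0.047	-0.258
Palaemon_capensis	MF797833.1	whole	15925	36.2	11.5	32.9	19.4	69.1	0.048	-0.256
Exopalaemon_annandalei	MG787410.1	whole	15718	34.8	12.7	29.3	23.2	64.1	0.086	-0.292
Exopalaemon_modestus	MF687349.1	whole	15736	32.1	20.4	35.4	12.1	67.5	-0.049	0.255
Exopalaemon_carinicauda	EF560650.1	whole	15730	33.6	13.4	30.0	23.0	63.6	0.057	-0.264
Macrobrachium_bullatum	KM978918.1	whole	15774	37.3	11.7	27.2	23.7	64.5	0.157	-0.339
Macrobrachium_lanchesteri	FJ797435.1	whole	15694	36.9	12.1	30.2	20.8	67.1	0.100	-0.264
Macrobrachium_nipponense	HQ830201.1	whole	15806	37.2	12.5	28.9	21.5	66.1	0.126	-0.265
Macrobrachium_rosenbergii	AY659990.1	whole	15772	35.8	13.4	26.4	24.3	62.2	0.151	-0.289
Palaemonetes_sinensis	MH880828	PCG	11166	34.8	12.9	28.9	23.4	63.7	0.093	-0.289
Palaemon_serenus	KM978916.1	PCG	11076	21.7	21.3	34.3	22.7	56.0	-0.225	-0.032
Palaemon_capensis	MF797833.1	PCG	11128	27.8	16.4	39.0	16.8	66.8	-0.168	-0.012
Palaemon_gravieri	KT935323.1	PCG	11125	27.1	17.0	38.1	17.8	65.2	-0.169	-0.023
Palaemon_gravieri	KU899135.1	PCG	11128	27.2	17.0	38.0	17.8	65.2	-0.166	-0.023
Exopalaemon_annandalei	MG787410.1	PCG	11126	25.3	18.3	36.2	20.2	61.5	-0.177	-0.049
Exopalaemon_modestus	MF687349.1	PCG	11136	27.2	16.9	37.9	18.0	65.1	-0.164	-0.032
Exopalaemon_carinicauda	EF560650.1	PCG	11122	25.0	18.8	35.6	20.7	60.6	-0.175	-0.048
Macrobrachium_bullatum	KM978918.1	PCG	11126	26.7	17.6	35.4	20.3	62.1	-0.140	-0.071
Macrobrachium_lanchesteri	FJ797435.1	PCG	11125	27.7	16.5	37.5	18.3	65.2	-0.150	-0.052
Macrobrachium_nipponense	HQ830201.1	PCG	11128	27.6	16.8	36.7	18.9	64.3	-0.142	-0.059
Macrobrachium_rosenbergii	AY659990.1	PCG	11126	25.9	18.3	34.2	21.5	60.1	-0.138	-0.080
Palaemonetes_sinensis	MH880828	tRNA	1438	34.4	15.2	30.4	20.0	64.8	0.062	-0.136
Palaemon_serenus	KM978916.1	tRNA	1449	31.3	17.6	30.5	20.6	61.8	0.013	-0.079
Palaemon_capensis	MF797833.1	tRNA	1438	35.4	12.9	34.8	16.9	70.2	0.009	-0.134
Palaemon_gravieri	KT935323.1	tRNA	1444	35.1	14.6	32.1	18.2	67.2	0.045	-0.110
Palaemon_gravieri	KU899135.1	tRNA	1444	35.2	14.6	32.0	18.2	67.2	0.048	-0.110
Exopalaemon_annandalei	MG787410.1	tRNA	1450	33.7	15.9	30.3	20.1	64.0	0.053	-0.117
Exopalaemon_modestus	MF687349.1	tRNA	1443	32.4	18.5	34.6	14.5	67.0	-0.033	0.121
Exopalaemon_carinicauda	EF560650.1	tRNA	1445	33.6	15.2	32.2	19.0	65.8	0.021	-0.111
Macrobrachium_bullatum	KM978918.1	tRNA	1443	35.6	14.3	29.8	20.3	65.4	0.089	-0.173
Macrobrachium_lanchesteri	FJ797435.1	tRNA	1449	34.9	14.4	31.5	19.3	66.4	0.051	-0.145
Macrobrachium_nipponense	HQ830201.1	tRNA	1450	35.0	14.8	30.7	19.4	65.7	0.065	-0.135
Macrobrachium_rosenbergii	AY659990.1	tRNA	1449	34.6	15.1	30.1	20.2	64.7	0.070	-0.144
Palaemonetes_sinensis	MH880828	rRNA	2088	38.9	9.1	34.6	17.4	73.5	0.059	-0.313
Palaemon_serenus	KM978916.1	rRNA	2176	32.4	14.5	33.5	19.5	65.9	-0.017	-0.147
Palaemon_capensis	MF797833.1	rRNA	2112	37.7	9.3	36.5	16.5	74.2	0.016	-0.279
Palaemon_gravieri	KT935323.1	rRNA	2092	38.5	9.6	34.4	17.5	72.9	0.056	-0.292
Palaemon_gravieri	KU899135.1	rRNA	2091	38.5	9.5	34.5	17.5	73.0	0.055	-0.296
Exopalaemon_annandalei	MG787410.1	rRNA	2088	38.2	10.0	32.7	19.2	70.9	0.078	-0.315
Exopalaemon_modestus	MF687349.1	rRNA	2128	34.8	16.9	38.3	10.0	73.1	-0.048	0.257
Exopalaemon_carinicauda	EF560650.1	rRNA	2142	38.0	10.6	33.6	17.7	71.6	0.061	-0.251
Macrobrachium_bullatum	KM978918.1	rRNA	2169	39.1	9.9	29.8	21.3	68.9	0.135	-0.365
Macrobrachium_lanchesteri	FJ797435.1	rRNA	2154	39.4	9.7	31.7	19.3	71.1	0.108	-0.331
Macrobrachium_nipponense	HQ830201.1	rRNA	2157	38.9	10.4	29.9	20.7	68.8	0.131	-0.331
Macrobrachium_rosenbergii	AY659990.1	rRNA	2157	38.3	11.1	27.7	22.9	66.0	0.161	-0.347
Palaemonetes_sinensis	MH880828	CR	1159	46.7	6.5	38.1	8.7	84.8	0.101	-0.145
Palaemon_serenus	KM978916.1	CR	1150	37.5	12.5	35.5	14.5	73.0	0.027	-0.074
Palaemon_capensis	MF797833.1	CR	1085	42.3	9.4	38.1	10.2	80.4	0.052	-0.041
Palaemon_gravieri	KT935323.1	CR	948	42.1	8.0	39.7	10.2	81.8	0.029	-0.121
Palaemon_gravieri	KU899135.1	CR	947	42.0	8.1	39.6	10.2	81.6	0.029	-0.115
Exopalaemon_annandalei	MG787410.1	CR	934	43.0	7.7	37.2	12.1	80.2	0.072	-0.222
Exopalaemon_modestus	MF687349.1	CR	952	38.3	10.1	43.7	7.9	82.0	-0.066	0.122
Exopalaemon_carinicauda	EF560650.1	CR	886	41.0	9.3	38.7	11.1	79.7	0.029	-0.088
Macrobrachium_bullatum	KM978918.1	CR	1002	42.8	7.3	39.1	10.8	81.9	0.045	-0.193
Macrobrachium_lanchesteri	FJ797435.1	CR	861	41.7	7.3	41.0	10.0	82.7	0.008	-0.156
Macrobrachium_nipponense	HQ830201.1	CR	950	42.4	9.2	37.5	10.9	79.9	0.061	-0.085
Macrobrachium_rosenbergii	AY659990.1	CR	931	39.5	9.6	36.2	14.7	75.7	0.044	-0.210
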