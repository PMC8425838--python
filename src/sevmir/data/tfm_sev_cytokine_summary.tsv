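analyte	control_n	control_mean	control_sd	tfm_n	tfm_mean	tfm_sd	difference	p	p_adj
IL-1β	6	39.0	13.0	8	25.0	14.0	-15.0	0.06	0.38
IL-2	6	76.0	54.0	8	37.0	36.0	-40.0	0.16	0.38
MIP-1a	6	70.0	47.0	8	38.0	24.0	-32.0	0.17	0.38
TNFα	6	63113.0	22374.0	8	44931.0	25191.0	-18182.0	0.18	0.38
IL-5	6	13808.0	4924.0	8	9853.0	5524.0	-3954.0	0.18	0.38
IL-17	6	489.0	174.0	8	349.0	196.0	-140.0	0.18	0.38
KC	6	1134.0	404.0	8	809.0	454.0	-325.0	0.18	0.38
MCP-1	6	9539.0	3402.0	8	6807.0	3817.0	-2732.0	0.18	0.38
IL-3	6	1090.0	576.0	8	696.0	465.0	-395.0	0.2	0.38
GM-CSF	6	406.0	197.0	8	280.0	142.0	-126.0	0.22	0.38
IL-12p40	6	1826.0	1585.0	8	899.0	675.0	-927.0	0.22	0.38
IL-4	6	196.0	133.0	8	116.0	89.0	-81.0	0.24	0.38
Eotaxin	6	1451.0	704.0	8	1023.0	559.0	-428.0	0.25	0.38
IL-9	6	1343.0	761.0	8	896.0	540.0	-446.0	0.25	0.38
IL-13	6	36765.0	47127.0	8	12128.0	8241.0	-24637.0	0.26	0.38
G-CSF	6	2282.0	1714.0	8	1340.0	975.0	-942.0	0.26	0.38
IFNγ	6	80672.0	43806.0	8	56155.0	36511.0	-24516.0	0.29	0.4
MIP-1β	6	2743.0	2317.0	8	1561.0	1557.0	-1183.0	0.31	0.4
IL-1α	6	54.0	64.0	8	25.0	47.0	-29.0	0.37	0.44
IL-10	6	3634.0	1492.0	8	2824.0	1956.0	-810.0	0.4	0.44
IL-12p70	6	2725.0	3173.0	8	1328.0	2548.0	-1397.0	0.4	0.44
IL-6	6	274.0	197.0	8	204.0	252.0	-70.0	0.57	0.6
RANTES	6	170.0	226.0	8	113.0	222.0	-57.03	0.65	0.65
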