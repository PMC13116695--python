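variant_id	freq_PA03	freq_TD01	freq_TP02	freq_TH04	freq_TH04.1	gq_PA03	gq_TD01	gq_TP02	gq_TH04	gq_TH04.1	specific
CM037083.1_8482984	1	0	1	1	1	127	127	127	127	117	TD01
CM037083.1_8483193	0	0	0	1	1	127	127	127	127	127	TH04
CM037083.1_8534743	0	0	0.004	1	1	127	127	127	127	127	TH04
CM037085.1_14072991	0.05	0.016	1	0	0	33	127	102	127	104	TP02
CM037087.1_13816	0	0.959	0.953	1	1	24	127	127	38	15	PA03
CM037087.1_13892	1	0.005	0.977	1	1	84	127	127	63	30	TD01
CM037087.1_3202	0.93	0.914	0	1	0.984	70	37	127	127	127	TP02
CM037087.1_3220	0	0.972	1	1	1	127	70	127	127	127	PA03
CM037087.1_8678	0.965	0	0.021	0	0	127	127	126	127	127	PA03
CM037087.1_8773	0.009	0.041	0.991	0	0	127	127	127	127	127	TP02
CM037087.1_8956	0	0.974	1	1	1	127	127	127	127	65	PA03
CM037087.1_9160	0.026	0	1	0	0	127	127	127	127	127	TP02
JAJGXB010002921.1_86	0.012	0	1	0	0	127	127	127	127	127	TP02
JAJGXB010011211.1_115	1	0	0.996	1	1	127	127	127	127	127	TD01
JAJGXB010011928.1_660	1	0	0.995	1	1	73	53	52	89	80	TD01
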