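variant_id	freq_PA03	freq_TD01	freq_TP02	freq_TH04	freq_TH04.1	gq_PA03	gq_TD01	gq_TP02	gq_TH04	gq_TH04.1	low	high
CM037083.1_8483200	1	0	0	1	0.987	127	127	127	127	127	TD01 x TP02	PA03 x TH04
CM037083.1_8483224	0	0.996	0	1	1	127	127	127	127	127	PA03 x TP02	TD01 x TH04
CM037085.1_14072988	0	0	1	1	1	121	127	112	127	76	PA03 x TD01	TP02 x TH04
CM037087.1_15154	0.991	0.992	0	0	0	127	127	127	127	127	TP02 x TH04	PA03 x TD01
CM037087.1_3238	0.994	1	0	0	0	127	127	127	127	127	TP02 x TH04	PA03 x TD01
CM037087.1_3241	0.006	1	0	1	1	127	127	127	127	127	PA03 x TP02	TD01 x TH04
CM037087.1_8968	0	1	1	0	0	127	127	127	127	76	PA03 x TH04	TD01 x TP02
CM037087.1_9106	1	0	1	0	0	127	127	127	127	127	TD01 x TH04	PA03 x TP02
CM037087.1_9133	0.005	0	1	1	1	127	127	127	127	127	PA03 x TD01	TP02 x TH04
JAJGXB010000273.1_8514	0	1	1	0	0	127	127	127	127	127	PA03 x TH04	TD01 x TP02
JAJGXB010011211.1_107	1	0	0	1	1	127	127	127	127	127	TD01 x TP02	PA03 x TH04
JAJGXB010012658.1_191	1	0	1	0	0	127	127	127	127	100	TD01 x TH04	PA03 x TP02
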