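subject	ear	hearing	pta_db	lf_db	hf_db	stapedial_reflex	oae	gap_detection_ms	wave_i_ms	wave_iii_ms	wave_v_ms	ip_i_iii_ms	ip_iii_v_ms
1	R	normal	10	10	10	+	+	5.4	1.55	4.13	6.18	2.58	2.05
1	L	normal	10	10	15	+	+	5.4	1.52	4.47	6.63	2.95	2.16
2	R	normal	10	10	20	+	+	3.8	1.57	4.01	5.81	2.44	1.80
2	L	normal	11	11	13	+	+	3.8	1.67	4.04	5.30	2.37	1.26
3	R	normal	11	13	10	+	+	0.7	1.49	4.17	5.54	2.68	1.37
3	L	normal	15	16	10	+	+	0.7	1.53	4.01	5.33	2.48	1.32
4	R	normal	11	10	13	+	+	6.0	1.49	3.58	5.53	2.09	1.95
4	L	normal	11	11	22	+	+	6.0	1.50	3.54	5.45	2.04	1.91
5	R	mild	29	26	43	+	ABS	5.0	ABS	4.67	6.27	-	1.60
5	L	mild	34	25	60	+	ABS	5.0	ABS	4.37	6.08	-	1.71
6	R	mild	20	16	32	+	+	3.4	1.65	4.23	5.47	2.58	1.24
6	L	mild	25	15	58	+	+	3.4	2.02	4.34	6.26	2.32	1.92
7	R	mild	33	23	55	ABS	+	11.0	ABS	ABS	7.08	-	-
7	L	mild	31	23	53	ABS	ABS	11.0	ABS	ABS	ABS	-	-
8	R	mild	31	24	53	+	+	5.6	ABS	ABS	ABS	-	-
8	L	mild	34	26	52	+	+	5.6	ABS	ABS	7.03	-	-
9	R	mild	30	23	53	+	+	7.0	ABS	ABS	ABS	-	-
9	L	normal	10	10	17	+	+	7.0	ABS	ABS	ABS	-	-
10	R	mild	21	18	38	+	+	6.0	ABS	ABS	ABS	-	-
10	L	mild	21	15	42	+	+	6.0	ABS	ABS	ABS	-	-
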