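feature	regulation	norm_metastatic	norm_non_metastatic	printed_fold	shift_note
miR-7-1*	down	2.76	24.54	-8.88
miR-15b	down	489.84	2660.69	-5.43
miR-16	down	999.03	17741.34	-17.76
miR-24	down	1046.96	8903.54	-8.50
miR-24-2*	down	5.07	22.50	-4.44	one_base_shift
miR-26b	down	1964.89	8991.18	-4.58
miR-28-5p	down	184.78	1264.17	-6.84
miR-29a	down	446.06	13028.23	-29.21
miR-29c	down	299.99	1643.68	-5.48
miR-33b	down	22.12	62.81	-2.84
miR-34a	down	76.03	194.87	-2.56
miR-95	down	57.60	1128.90	-19.60
miR-101*	down	4.61	105.76	-22.95	one_base_shift
miR-106b	down	906.41	6545.23	-7.22
miR-126*	down	1099.03	3798.06	-3.46
miR-145	down	103.68	297.71	-2.87
miR-146b-5p	down	1335.88	2765.57	-2.07
miR-185	down	84.79	448.76	-5.29
miR-186	down	1666.28	5838.21	-3.50
miR-188-5p	down	0.92	9.64	-10.46
miR-191	down	1822.50	12911.66	-7.08
miR-193a-3p	down	35.94	196.91	-5.48
miR-195	down	116.58	560.65	-4.81
miR-196a	down	33.64	70.99	-2.11
miR-200b*	down	146.54	499.30	-3.41
miR-200c*	down	12.44	54.34	-4.37
miR-203	down	147.92	434.73	-2.94
miR-203	down	224.41	334.81	-1.49	one_base_shift
miR-205	down	0.00	31.26	N/A
miR-324-5p	down	27.19	61.94	-2.28
miR-331-3p	down	2.76	14.32	-5.18
miR-335	down	22.58	54.63	-2.42
miR-339-5p	down	35.94	189.03	-5.26
miR-342-3p	down	61.75	247.46	-4.01
miR-361-5p	down	103.68	259.73	-2.51
miR-363	down	1298.10	8476.40	-6.53
miR-424	down	22.12	76.25	-3.45
miR-425	down	1869.04	10985.75	-5.88
miR-454	down	10.60	32.72	-3.09
miR-497	down	164.05	373.67	-2.28
miR-503	down	0.00	7.30	N/A
miR-542-5p	down	0.92	12.27	-13.31
miR-556-5p	down	1.84	13.15	-7.13
miR-582-5p	down	49.77	203.93	-4.10
miR-590-5p	down	12.44	213.86	-17.19
miR-627	down	2.30	93.20	-40.45
miR-651	down	11.06	54.63	-4.94
miR-652	down	12.90	33.89	-2.63
miR-660	down	51.15	110.14	-2.15
miR-664	down	8.76	30.97	-3.54
miR-708	down	0.00	42.36	N/A
miR-1180	down	3.69	15.48	-4.20
miR-1269	down	11.06	42.66	-3.86
miR-1287	down	1.84	12.85	-6.97
miR-2115*	down	0.00	7.89	N/A
miR-3065-5p	down	14.75	117.74	-7.98
let-7d	up	671.86	322.84	2.08
let-7g	up	8690.38	3448.64	2.52
let-7g*	up	42.39	3.21	13.19
let-7i	up	851.11	400.55	2.12
miR-7	up	72.35	22.50	3.22
miR-9	up	20121.64	1386.00	14.52
miR-9*	up	352.98	35.64	9.90	one_base_shift
miR-17	up	12228.92	5600.39	2.18
miR-18a	up	1023.45	142.57	7.18
miR-18b	up	90.78	26.59	3.41
miR-20b*	up	89.40	7.60	11.77
miR-27a	up	1568.59	721.34	2.17
miR-27b	up	1406.39	425.38	3.31
miR-30a	up	30144.22	10956.83	2.75
miR-30a*	up	1300.40	532.90	2.44
miR-31	up	80.64	3.80	21.23
miR-34c-5p	up	2190.22	51.13	42.84
miR-99a	up	1017.92	330.43	3.08
miR-106a	up	2790.65	845.51	3.30
miR-125b	up	1699.46	287.19	5.92
miR-125b-2*	up	15.67	1.46	10.73
miR-126	up	26005.24	1799.70	14.45
miR-128	up	81.10	15.48	5.24
miR-136	up	40.55	7.89	5.14
miR-138	up	38.25	1.46	26.18
miR-140-5p	up	2458.87	723.97	3.40
miR-142-5p	up	104.60	26.00	4.02
miR-144	up	915.16	134.98	6.78
miR-144*	up	5429.24	418.37	12.98
miR-148b*	up	258.97	111.31	2.33	one_base_shift
miR-151-3p	up	4377.22	1866.89	2.34
miR-152	up	2662.55	582.56	4.57
miR-181a-2*	up	19.81	0.88	22.61
miR-200a	up	7217.64	1066.09	6.77
miR-210	up	16686.78	347.38	48.04
miR-218	up	140.55	70.12	2.00
miR-223*	up	16.13	0.29	55.20
miR-301a	up	60.83	21.62	2.81
miR-340*	up	46.08	16.36	2.82
miR-374a	up	1638.17	674.30	2.43
miR-379	up	104.14	35.94	2.90
miR-449a	up	18.43	1.17	15.77
miR-450a	up	191.24	24.83	7.70
miR-451	up	4504.40	2197.62	2.05
miR-486-3p	up	9.22	0.88	10.52
miR-486-5p	up	430.86	54.93	7.84
miR-542-3p	up	100.00	26.88	3.72
miR-744*	up	17.05	3.80	4.49
miR-1246	up	95.39	22.50	4.24	one_base_shift
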