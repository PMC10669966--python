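V1	V2	V3	V4	V5	V6	V7	V8
G01	66	67	26	52	41	67	89	77
G02	40	66	26	39	29	61	25	29
G03	41	63	88	42	47	35	45	18
G04	83	37	47	57	48	41	11	67
G05	88	43	69	46	72	49	42	63
G06	35	39	55	51	55	27	65	31
G07	70	36	41	27	33	30	60	81
G08	62	71	84	26	45	74	62	42
G09	33	44	38	33	44	42	45	62
G10	97	56	55	61	22	27	37	39
G11	55	44	45	21	47	27	50	79
G12	30	76	61	43	85	20	33	35
G13	36	33	43	45	32	34	23	18
G14	66	35	50	36	53	21	78	39
G15	34	60	62	53	74	62	44	36
G16	39	59	30	36	51	28	43	43
G17	44	55	30	27	52	48	27	48
G18	43	28	70	48	65	26	39	39
G19	31	27	35	41	53	27	107	56
G20	39	44	58	70	33	54	25	47
G21	50	42	29	24	44	55	43	17
G22	45	45	49	39	90	53	36	48
G23	58	43	44	45	48	58	119	70
G24	56	55	50	57	76	40	35	50
G25	27	62	55	35	54	61	44	39
G26	61	29	51	39	41	46	34	67
G27	67	36	23	58	26	76	38	42
G28	38	70	54	44	81	42	49	73
G29	75	38	44	27	53	88	102	38
G30	24	34	43	39	39	31	79	53
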