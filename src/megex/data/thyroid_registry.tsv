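study_id	n_case	n_control	country	study_age	organism	data_type	design
GSE35570	65	51	Poland	4	Homo sapiens	RNA expression	case_control
GSE58545	27	18	Poland	4	Homo sapiens	RNA expression	case_control
GSE58689	27	18	Poland	4	Homo sapiens	RNA expression	case_control
GSE60542	33	34	Belgium	4	Homo sapiens	RNA expression	case_control
GSE65144	12	13	USA	4	Homo sapiens	RNA expression	case_control
GSE39156	48	16	Belgium	6	Homo sapiens	RNA expression	case_control
GSE53157	24	3	Portugal	6	Homo sapiens	RNA expression	case_control
GSE29265	29	20	Belgium	7	Homo sapiens	RNA expression	case_control
GSE33630	60	45	Belgium	7	Homo sapiens	RNA expression	case_control
GSE27155	95	4	USA	8	Homo sapiens	RNA expression	case_control
GSE5364	270	58	Singapore	11	Homo sapiens	RNA expression	case_control
GSE6339	48	135	France	12	Homo sapiens	RNA expression	case_control
GSE9115	15	4	USA	12	Homo sapiens	RNA expression	case_control
GSE3678	7	7	USA	13	Homo sapiens	RNA expression	case_control
GSE6004	14	4	USA	13	Homo sapiens	RNA expression	case_control
GSE3467	9	9	USA	14	Homo sapiens	RNA expression	case_control
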