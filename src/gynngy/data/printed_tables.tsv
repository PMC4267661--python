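table	cell	numerator	denominator	printed_percent	decimals
as_by_region	human_cds_as	621	107221	0.58	2
as_by_region	human_utr_as	175	14977	1.17	2
as_by_region	human_total_as	796	122198	0.65	2
as_by_region	mouse_cds_as	845	109906	0.77	2
as_by_region	mouse_utr_as	182	14160	1.29	2
as_by_region	mouse_total_as	1027	124066	0.83	2
regulation_by_region	human_cds_strong	75	510	14.71	2
regulation_by_region	human_utr_strong	43	111	38.74	2
regulation_by_region	human_total_strong	118	621	19.00	2
regulation_by_region	mouse_cds_strong	15	652	2.30	2
regulation_by_region	mouse_utr_strong	6	86	6.98	2
regulation_by_region	mouse_total_strong	21	738	2.85	2
regulation_by_region	human_total_regulated	277	621	45	0
regulation_by_region	mouse_total_regulated	50	738	6.8	1
conservation_by_class	human_strong	26	73	35.62	2
conservation_by_class	human_medium	16	64	25.00	2
conservation_by_class	human_weak	5	38	13.16	2
conservation_by_class	human_very_weak	3	41	7.32	2
conservation_by_class	human_unregulated	43	279	15.41	2
conservation_by_class	mouse_strong	8	25	32	0
conservation_by_class	mouse_medium	14	52	26.92	2
conservation_by_class	mouse_weak	9	50	18.00	2
conservation_by_class	mouse_very_weak	9	59	15.25	2
conservation_by_class	mouse_unregulated	47	456	10.31	2
protein_change	strong_lt10	0	75	0	0
protein_change	strong_stop	54	75	72	0
protein_change	other_lt10	5	144	3.5	1
protein_change	other_stop	107	144	74	0
protein_change	unregulated_lt10	7	291	2.4	1
protein_change	unregulated_stop	216	291	74	0
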