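# Per-lineage PSMC-derived demographic statistics for 14 Catharus/Hylocichla
# thrush lineages (8 Nearctic-Neotropic seasonal migrants, 6 Neotropical
# residents), transcribed from published PSMC analyses of this clade.
# Ne columns are in units of 1e4 individuals; deltaT in years; rate per year.
taxon_id	group	mean_Ne_e4	sd_Ne_e4	cv	degree	rate_per_yr	deltaT_yr
H_mustelina	migrant	35.63	20.11	0.56	0.86	2.92e-07	2946862
C_fuscescens	migrant	95.59	50.99	0.53	0.83	1.93e-07	4284020
C_guttatus_E	migrant	75.34	65.69	0.87	0.90	4.48e-07	2021768
C_guttatus_W	migrant	39.72	24.20	0.61	0.81	3.28e-07	2477684
C_minimus	migrant	63.71	28.83	0.45	0.78	2.17e-07	3594914
C_ustulatus_swainsonii	migrant	76.61	66.61	0.87	0.79	2.12e-07	3740764
C_ustulatus_ustulatus	migrant	39.56	12.15	0.31	0.63	2.14e-07	2943763
C_bicknelli	migrant	46.90	24.12	0.51	0.78	2.79e-07	2781554
C_aurantiirostris	resident	12.38	2.83	0.23	-0.75	-1.00e-06	747451
C_fuscater	resident	11.38	1.66	0.15	0.39	6.18e-07	627449
C_frantzii	resident	24.71	8.41	0.34	0.17	2.20e-07	774024
C_gracilirostris	resident	29.98	9.28	0.31	0.58	3.52e-07	1637663
C_mexicanus	resident	37.10	16.18	0.44	0.75	3.34e-07	2250295
C_occidentalis	resident	76.40	53.14	0.70	0.91	2.11e-07	4292405
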