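spot_id	accession	protein_name	mr_pi	wt_mean	wt_sd	ko_mean	ko_sd	fold	p
1	P24549	Aldehyde dehydrogenase family 1, subfamily A1	54468/7.91	0.19	0.01	0.15	0.01	0.78	0.0025
2	P10649	Glutathione S-transferase, mu 1	25970/7.7	0.88	0.20	0.53	0.07	0.60	0.0158
3	P30115	Glutathione S-transferase, alpha 3	25361/8.76	0.85	0.09	0.67	0.02	0.80	0.0098
4a	P19157	Glutathione S-transferase, pi 1	23609/7.69	2.06	0.17	1.20	.50	0.58	0.0170
4b	P19157	Glutathione S-transferase, pi 1	23609/7.69	0.29	0.03	0.017	0.05	0.57	0.0040
4c	P19157	Glutathione S-transferase, pi 1	23609/7.69	0.21	0.01	0.11	0.05	0.50	0.0073
5	Q923D2	Biliverdin reductase B	22197/6.49	0.13	0.01	0.010	0.01	0.83	0.0155
6	P11588	Major urinary protein 6	20648/5.0	0.46	0.06	0.17	0.05	0.36	0.0002
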