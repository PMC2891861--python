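accession	protein_name	wt_gm	wt_lo	wt_hi	ko_gm	ko_lo	ko_hi	fold	p
P10649	Glutathione S-transferase Mu 1	1.00	0.91	1.10	0.44	0.40	0.47	0.44	0.001
P17717	UDP-glucuronosyltransferase 2B5	0.99	0.93	1.06	0.55	0.52	0.57	0.55	0.001
Q8VCC2	Liver carboxylesterase 1	1.06	0.96	1.17	0.59	0.54	0.64	0.56	0.001
Q91X77	Cytochrome P450 2C50	0.97	0.87	1.08	0.56	0.46	0.69	0.58	0.001
P19157	Glutathione S-transferase P 1	0.95	0.89	1.01	0.58	0.54	0.63	0.62	0.001
Q9D379	Epoxide hydrolase 1	0.97	0.90	1.05	0.63	0.59	0.68	0.65	0.001
Q64458	Cytochrome P450 2C29	1.08	0.90	1.29	0.75	0.62	0.90	0.69	0.001
P30115	Glutathione S-transferase A3	1.03	0.98	1.08	0.72	0.66	0.78	0.70	0.001
P24549	Retinal dehydrogenase 1	0.94	0.86	1.04	0.68	0.58	0.80	0.72	0.021
O70475	UDP-glucose 6-dehydrogenase	1.09	0.97	1.23	0.79	0.63	0.99	0.73	0.183
Q62452	UDP-glucuronosyltransferase 1-9	0.99	0.93	1.06	0.73	0.58	0.92	0.74	0.183
Q91VA0	Acyl-coenzyme A synthetase ACSM1, mitochondrial	0.97	0.91	1.04	0.79	0.74	0.84	0.81	0.001
Q64442	Sorbitol dehydrogenase	1.02	0.92	1.13	0.84	0.78	0.91	0.83	0.081
P97494	Glutamate-cysteine ligase catalytic subunit	1.15	1.06	1.25	0.95	0.89	1.02	0.83	0.021
Q8CG76	Aflatoxin B1 aldehyde reductase member 2	1.06	1.01	1.11	0.88	0.81	0.96	0.83	0.013
Q9CQX2	Cytochrome b5 type B	1.01	0.91	1.13	0.85	0.76	0.94	0.83	0.197
Q9JII6	Alcohol dehydrogenase [NADP+]	1.01	0.98	1.04	0.86	0.80	0.92	0.85	0.003
Q8VCW8	Acyl-CoA synthetase family member 2, mitochondrial	1.00	0.93	1.08	0.86	0.79	0.93	0.86	0.132
O55022	Membrane-associated progesterone receptor component 1	1.03	0.96	1.11	0.89	0.81	0.98	0.86	0.207
P47738	Aldehyde dehydrogenase, mitochondrial	1.02	0.99	1.06	0.88	0.85	0.92	0.86	0.000
Q8QZS1	3-hydroxyisobutyryl-CoA hydrolase, mitochondrial	1.07	1.00	1.13	0.94	0.89	1.00	0.89	0.084
Q9ET01	Glycogen phosphorylase, liver form	0.98	0.96	1.00	0.87	0.80	0.94	0.89	0.081
O35945	Aldehyde dehydrogenase, cytosolic 1	0.97	0.93	1.01	0.86	0.83	0.89	0.89	0.024
Q8VDJ3	Vigilin	1.10	1.05	1.15	0.99	0.94	1.04	0.90	0.069
Q9EQ20	Methylmalonate-semialdehyde dehydrogenase [acylating], mitochondrial	1.00	0.98	1.03	0.92	0.87	0.98	0.92	0.140
Q9Z2I8	Succinyl-CoA ligase [GDP-forming] subunit beta, mitochondrial	1.02	0.99	1.06	0.96	0.92	0.99	0.93	0.121
Q99P30	Peroxisomal coenzyme A diphosphatase NUDT7	0.98	0.93	1.03	1.10	1.05	1.17	1.13	0.039
Q9CW42	MOSC domain-containing protein 1, mitochondrial	0.95	0.90	1.00	1.09	1.04	1.15	1.15	0.095
Q9QXD6	Fructose-1,6-bisphosphatase 1	1.02	0.96	1.09	1.21	1.10	1.33	1.18	0.117
P31786	Acyl-CoA-binding protein	1.01	0.94	1.07	1.19	1.06	1.34	1.18	0.207
P24369	Peptidyl-prolyl cis-trans isomerase B	0.95	0.89	1.01	1.12	1.05	1.20	1.18	0.017
Q8VDM4	26 S proteasome non-ATPase regulatory subunit 2	0.90	0.80	1.02	1.08	1.00	1.17	1.20	0.183
P06151	L-lactate dehydrogenase A chain	0.97	0.89	1.05	1.16	1.06	1.28	1.20	0.086
Q61207	Sulfated glycoprotein 1	0.94	0.84	1.05	1.14	1.07	1.21	1.21	0.057
P16460	Argininosuccinate synthase	1.02	0.93	1.13	1.27	1.16	1.40	1.25	0.038
Q3THE2	Myosin regulatory light chain MRLC2	1.13	1.03	1.24	1.46	1.25	1.70	1.29	0.117
Q8VBT2	L-serine dehydratase	1.02	0.91	1.15	1.37	1.13	1.67	1.34	0.183
Q05816	Fatty acid-binding protein, epidermal	1.17	0.96	1.43	2.10	1.69	2.60	1.79	0.005
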