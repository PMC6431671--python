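# netpharm summary v1 — serum DEP candidates, NPC cases vs pooled healthy control
# consensus_fraction = 26/30 patients on the same side of 1.0 as the mean ratio
protein_acc	protein_name	mean_ratio	p_value	n_peptides	unused_score	consensus_fraction
P01009	Alpha-1-antitrypsin	2.02	0.034	22	37.04	0.8666666666666667
P01857	Ig gamma-1 chain C region	3.32	0.001	20	26.76	0.8666666666666667
P01859	Ig gamma-2 chain C region	0.51	6.26e-08	16	12.11	0.8666666666666667
P04114	Apolipoprotein B-100	1.4	0.005	10	21.8	0.8666666666666667
P02763	Alpha-1-acid glycoprotein 1	2.32	3.68e-04	6	10.2	0.8666666666666667
Q14624	Inter-alpha-trypsin inhibitor heavy chain H4	1.4	1.75e-04	3	7.42	0.8666666666666667
P19823	Inter-alpha-trypsin inhibitor heavy chain H2	0.76	7.00e-03	3	7.55	0.8666666666666667
P01008	Antithrombin III	3.34	2.59e-04	3	6.58	0.8666666666666667
P05155	Plasma protease C1 inhibitor	1.54	1.62e-04	3	7.01	0.8666666666666667
P01023	Alpha-2-macroglobulin	0.53	7.73e-10	27	53.11	0.8666666666666667
P00738	Haptoglobin	1.39	1.20e-02	12	21.41	0.8666666666666667
P02647	Apolipoprotein A-I	0.57	2.17e-08	14	25.64	0.8666666666666667
P04196	Histidine-rich glycoprotein	0.74	7.97e-07	3	6.52	0.8666666666666667
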