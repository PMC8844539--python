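gene_name	log2_fold_change	p_value
Plxnb2	3.408307894	0.00244823
Tnfsf11	3.200035166	0.018665401
Emb	3.075917964	0.007876617
Nt5e	3.024345063	0.005280796
Cd200	2.775011745	3.28E-05
Slc7a5	2.73475518	0.000811395
Tmem2	2.476666371	0.010418948
Entpd1	2.451121422	2.31E-05
Icam1	2.39946905	0.001301713
Cd36	2.36357507	0.000360733
Alcam	2.349663889	0.001106104
Slc3a2	2.312643859	0.000110602
Cd80	2.26982976	0.001791933
Cd69	2.265710589	0.005099445
Ly6e	2.187298039	0.000319921
Itgb3	2.174073587	0.007612442
Cd48	2.138949606	0.000380995
Bsg	2.042021555	0.001567574
Pecam1	1.938435284	0.011336039
Slamf1	1.89767313	0.014593304
Thy1	1.882500884	0.000949947
Icos	1.864047709	0.006299044
Ncstn	1.832939578	0.003987165
Cd5	1.775109343	0.000259476
Atp1b3	1.764153318	0.000248229
Atp1b1	1.76026351	0.000101095
Trac;Tcra	1.701583438	5.86E-05
Cd44	1.691378866	0.000167253
St14	1.681174874	0.00233923
Slc4a7	1.678065082	0.003163946
Itgb7	1.630313414	0.000741549
Amica1	1.609105761	0.002620728
Tlr2	1.602045805	0.005176914
Itgal	1.506602363	5.91E-05
Adgre5;Cd97	1.484718926	0.000147198
Itgb6	1.45152913	0.000181207
Itgb2	1.438960296	0.000402497
Prnp	1.419583945	0.004513303
Ptprc	1.414131506	0.000199609
Spn	1.408694655	0.004129782
Itgb5	1.406146072	0.000999951
Il18r1	1.386062293	0.000560288
Itgae	1.346952587	8.27E-05
Pdcd1	1.335366065	0.019382887
Cr1l	1.294204529	0.004629208
Itgb1	1.266107792	0.00026695
Cd274	1.205180756	0.003790173
H2-D1;H2-L	1.202468601	0.001008074
Il2ra	1.195019215	0.000200364
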