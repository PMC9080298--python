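class	no	rt	name	mz	p_flag	auc	fc	trend	pathway
rna_interference	1	39.952	Ribonic acid	167.0589	<0.001	0.520	1.562	up	
rna_interference	2	12.269	Deoxyadenosine	274.1097	<0.001	0.875	1.646	up	Purine metabolism
rna_interference	3	12.759	5-Thymidylic acid	340.2486	<0.01	0.843	6.795	up	Pyrimidine metabolism
rna_interference	4	40.002	Neryl glucoside	345.0645	<0.01	0.807	0.004	down	
rna_interference	5	16.917	Uracil	113.0375	<0.01	0.521	1.011	up	Pyrimidine metabolism
rna_interference	6	0.675	Hypoxanthine	136.9216	<0.001	0.821	2.487	up	Pyrimidine metabolism
rna_interference	7	12.983	Isoleucine	131.9327	<0.001	0.912	3.769	up	Valine, leucine and isoleucine biosynthesis
rna_interference	8	19.790	Aspartic acid	134.0478	<0.001	0.615	0.411	down	Alanine, aspartate and glutamate metabolism
rna_interference	9	19.792	Dehydroalanine	88.0386	<0.001	0.812	1.856	up	Methylation metabolism
rna_interference	10	11.429	Dimethylglycine	104.0691	<0.01	0.512	0.136	down	Methylation metabolism
rna_interference	11	15.802	N-Methyl-d-aspartic acid	148.0639	<0.01	0.735	0.021	down	
rna_interference	12	1.795	N-Acetyl-d-glucosamine 6-phosphate	319.0641	<0.001	0.631	0.106	down	Amino sugar and nucleotide sugar metabolism
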