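class	no	rt	name	mz	p_flag	auc	fc	trend	pathway
antimetabolite	1	12.260	d-Glucuronic acid 1-phosphate	275.0116	<0.001	0.696	4.932	up	Amino sugar and nucleotide sugar metabolism
antimetabolite	2	16.821	Uracil	113.0351	<0.01	0.783	1.808	up	Pyrimidine metabolism
antimetabolite	3	0.661	Hypoxanthine	136.9225	<0.001	0.652	4.736	up	Pyrimidine metabolism
antimetabolite	4	40.628	Nicotinic acid adenine dinucleotide	666.1287	<0.05	0.722	3.708	up	Act as second messenger
antimetabolite	5	33.008	Glucosamine 6-phosphate	282.2731	<0.05	0.643	4.980	up	Alanine, aspartate and glutamate metabolism
antimetabolite	6	39.893	Linoleic acid	303.3405	<0.05	0.522	0.166	down	Lipid metabolism
antimetabolite	7	13.055	Isoleucine	131.9333	<0.001	0.678	0.013	down	Valine, leucine and isoleucine biosynthesis
antimetabolite	8	36.194	5-Hydroxymethyluracil	143.0419	<0.001	0.650	3.027	up	
antimetabolite	9	11.862	Lactic acid	91.0408	<0.001	0.543	3.800	up	Glycolysis or gluconeogenesis
antimetabolite	10	1.879	d-Erythrose 4-phosphate	218.0164	<0.001	0.609	0.019	down	Pentose phosphate pathway
antimetabolite	11	33.832	Xanthosine	307.0836	<0.05	0.543	0.169	down	Purine metabolism
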