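class	no	rt	name	mz	p_flag	auc	fc	trend	pathway
microtubule	1	35.704	DG(15:0/22:1(13Z)/0:0)	654.5905	<0.01	0.674	1.298	up	Glycerolipids metabolism
microtubule	2	39.784	Myo-inositol 1-phosphate	261.0414	<0.05	0.805	3.469	up	Inositol phosphate metabolism
microtubule	3	24.220	Cinnavalininate	301.0518	<0.05	0.678	0.816	down	Tryptophan catabolism
microtubule	4	39.799	LysoPC (10:0)	413.3280	<0.05	0.819	3.592	up	Phospholipid metabolism
microtubule	5	21.039	4-Aminobutyraldehyde	88.0743	<0.05	0.546	1.628	up	Arginine catabolism
microtubule	6	11.865	Dimethylglycine	104.0729	<0.05	0.561	0.620	down	Glycine metabolism
microtubule	7	15.049	l-Proline	116.0712	<0.05	0.582	0.314	down	Arginine and proline metabolism
microtubule	8	15.609	Homocysteine	136.0404	<0.01	0.655	1.632	up	Cysteine and methionine metabolism
microtubule	9	15.405	Dopamine	154.0883	<0.05	0.606	1.440	up	Tyrosine catabolism
microtubule	10	13.764	l-Phenylalanine	165.9617	<0.05	0.621	1.724	up	Phenylalanine metabolism
microtubule	11	12.077	L-Tryptophan	205.0541	<0.05	0.547	2.195	up	Tryptophan metabolite
microtubule	12	17.052	d-Erythrose 4-phosphate	223.0174	<0.01	0.501	0.644	down	Pentose phosphate metabolism
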