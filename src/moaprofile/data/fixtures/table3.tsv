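class	no	rt	name	mz	p_flag	auc	fc	trend	pathway
dna_acting	1	24.322	Cinnavalininate	301.2291	<0.05	0.712	0.756	down	Tryptophan catabolism
dna_acting	2	35.764	DG(15:0/22:1(13Z)/0:0)	654.5937	<0.01	0.704	1.274	up	Glycerolipids metabolism
dna_acting	3	39.875	TG(16:0/16:1(9Z)/16:1(9Z))[iso3]	820.7550	<0.05	0.762	1.564	up	Glycerolipids metabolism
dna_acting	4	39.780	Myo-inositol 1-phosphate	261.0370	<0.05	0.804	4.177	up	Inositol phosphate metabolism
dna_acting	5	40.722	DG(18:1(11Z)/18:1(11Z)/0:0)	638.5786	<0.05	0.645	1.041	up	Glycerolipids metabolism
dna_acting	6	20.912	4-Aminobutyraldehyde	88.0744	<0.05	0.616	1.149	up	Arginine catabolism
dna_acting	7	15.647	l-Alanine	90.0564	<0.05	0.539	0.285	down	Alanine metabolism
dna_acting	8	10.820	Cytosine	112.0494	<0.05	0.524	1.224	up	Pyrimidine metabolism
dna_acting	9	15.047	l-Proline	116.0708	<0.05	0.671	1.372	up	Arginine and proline metabolism
dna_acting	10	11.907	l-Threonine	120.0678	<0.05	0.654	0.661	down	l-Threonine metabolism
dna_acting	11	11.690	Thymine	127.0493	<0.05	0.522	1.959	up	Pyrimidine metabolism
dna_acting	12	20.908	Dihydrothymine	129.0671	<0.01	0.558	0.965	down	Pyrimidine metabolism
dna_acting	13	16.862	N-Acetylputrescine	131.1208	<0.05	0.651	0.968	down	Arginine catabolism
dna_acting	14	15.421	Dopamine	154.0849	<0.05	0.575	1.166	up	Tyrosine catabolism
dna_acting	15	15.584	l-Tyrosine	181.9096	<0.05	0.609	2.705	up	Tyrosine metabolism
dna_acting	16	12.031	L-Tryptophan	205.0562	<0.05	0.533	1.603	up	Tryptophan metabolite
dna_acting	17	15.068	Cytidine	244.0982	<0.01	0.597	1.835	up	Pyrimidine metabolism
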