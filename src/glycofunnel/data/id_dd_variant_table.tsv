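gene_symbol	protein_accession	hgvs_p	clinical_significance	polyphen_humvar	condition
PUM1	PUM1	S802F	Uncertain significance	0.921	Spinocerebellar ataxia 47
TUBB2B	TUBB2B	S172P	Pathogenic	.	Cortical dysplasia, complex, with other brain malformations
TUBB2B	TUBB2B	S172L	Likely pathogenic	.	Cortical dysplasia, complex, with other brain malformations
DOCK7	DOCK7	S190N	Uncertain significance	0.995	Epileptic encephalopathy, early infantile, 23
DOCK7	DOCK7	S190G	Uncertain significance	0.989	Epileptic encephalopathy, early infantile, 23
ATRX	ATRX	S594C	Uncertain significance	0.993	Alpha thalassemia-X-linked intellectual disability
HCF1	HCF1	T556M	Uncertain significance	0.959	Mental retardation 3, X-linked
KMT2A	KMT2A	S1858I	Uncertain significance	0.855	Wiedemann-Steiner syndrome
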