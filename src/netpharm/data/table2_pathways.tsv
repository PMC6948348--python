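set_id	name	degree
hsa05200	Pathways in cancer	28
hsa04151	PI3K-AKT signaling pathway	18
hsa05206	MicroRNAs in cancer	13
hsa04915	Estrogen signaling pathway	11
hsa05205	Proteoglycans in cancer	11
hsa04015	Rap1 signaling pathway	11
hsa05166	HTLV-I infection	11
hsa05215	Prostate cancer	10
hsa05142	Chagas disease (American trypanosomiasis)	10
hsa04062	Chemokine signaling pathway	10
hsa05203	Viral carcinogenesis	10
hsa04976	Bile secretion	9
hsa04668	TNF signaling pathway	9
hsa05160	Hepatitis C	9
hsa05161	Hepatitis B	9
hsa04010	MAPK signaling pathway	9
hsa05222	Small-cell lung cancer	8
hsa04914	Progesterone-mediated oocyte maturation	8
hsa04726	Serotonergic synapse	8
hsa04071	Sphingolipid signaling pathway	8
hsa04611	Platelet activation	8
hsa05162	Measles	8
hsa05152	Tuberculosis	8
hsa04024	cAMP signaling pathway	8
hsa04810	Regulation of actin cytoskeleton	8
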