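mirna_id	mirna_direction	gene_id	gene_direction	sources	validation
hsa-miR-542-3p	up	BIRC5	down	targetscan,mirtarbase	V
hsa-miR-532-3p	up	BORA	down	microt_cds,targetscan	-
hsa-miR-503-5p	up	CDC25A	down	mirtarbase,mirecords	V
hsa-miR-424-5p	up	CHEK1	down	mirdb,mirtarbase	V
hsa-miR-18a-5p	down	CTGF	up	mirdb,mirtarbase	V
hsa-miR-200b-3p	down	DUSP1	up	microt_cds,mirdb	-
hsa-miR-200c-3p	down	DUSP1	up	microt_cds,mirdb	V (literature)
hsa-miR-139-5p	up	EIF4G2	down	microt_cds,mirdb	V (literature)
hsa-miR-146a-5p	up	EIF4G2	down	microt_cds,mirdb	-
hsa-miR-146b-5p	up	EIF4G2	down	microt_cds,mirdb	-
hsa-miR-3127-5p	up	EIF4G2	down	microt_cds,mirdb	-
hsa-miR-379-5p	up	EIF4G2	down	microt_cds,mirdb	V (literature)
hsa-miR-222-3p	down	ETS1	up	microt_cds,mirtarbase	V
hsa-miR-532-3p	up	HMGA2	down	mirdb,targetscan	-
hsa-miR-200b-3p	down	JUN	up	microt_cds,mirdb	V (literature)
hsa-miR-200c-3p	down	JUN	up	microt_cds,mirdb	V (literature)
hsa-miR-381-3p	up	KIF11	down	microt_cds,mirdb	-
hsa-miR-424-5p	up	KIF23	down	mirdb,targetscan,mirtarbase	V
hsa-miR-135b-5p	down	LZTS1	up	microt_cds,mirdb,mirtarbase	V (literature)
hsa-miR-335-3p	down	PRKAA2	up	microt_cds,mirdb	-
hsa-miR-19a-3p	down	RHOB	up	microt_cds,mirdb,targetscan	V (literature)
hsa-miR-542-3p	up	UBE2E1	down	microt_cds,mirdb	-
hsa-miR-381-3p	up	WEE1	down	microt_cds,mirtarbase	V
hsa-miR-424-5p	up	WEE1	down	microt_cds,mirdb,targetscan,mirtarbase	V
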