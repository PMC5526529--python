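# mitoaudit gene-name synonym map, version 1
# canonical	synonym (case-insensitive)
ND1	ND1
ND1	NADH1
ND1	NADH DEHYDROGENASE SUBUNIT 1
ND1	NAD1
ND1	MT-ND1
ND2	ND2
ND2	NADH2
ND2	NADH DEHYDROGENASE SUBUNIT 2
ND2	NAD2
ND2	MT-ND2
ND3	ND3
ND3	NADH3
ND3	NADH DEHYDROGENASE SUBUNIT 3
ND3	NAD3
ND3	MT-ND3
ND4	ND4
ND4	NADH4
ND4	NADH DEHYDROGENASE SUBUNIT 4
ND4	NAD4
ND4	MT-ND4
ND4L	ND4L
ND4L	NADH4L
ND4L	NADH DEHYDROGENASE SUBUNIT 4L
ND4L	NAD4L
ND4L	MT-ND4L
ND5	ND5
ND5	NADH5
ND5	NADH DEHYDROGENASE SUBUNIT 5
ND5	NAD5
ND5	MT-ND5
ND6	ND6
ND6	NADH6
ND6	NADH DEHYDROGENASE SUBUNIT 6
ND6	NAD6
ND6	MT-ND6
COX1	COX1
COX1	COI
COX1	COXI
COX1	CO1
COX1	CYTOCHROME C OXIDASE SUBUNIT 1
COX1	CYTOCHROME C OXIDASE SUBUNIT I
COX1	MT-CO1
COX2	COX2
COX2	COII
COX2	COXII
COX2	CO2
COX2	CYTOCHROME C OXIDASE SUBUNIT 2
COX2	CYTOCHROME C OXIDASE SUBUNIT II
COX2	MT-CO2
COX3	COX3
COX3	COIII
COX3	COXIII
COX3	CO3
COX3	CYTOCHROME C OXIDASE SUBUNIT 3
COX3	CYTOCHROME C OXIDASE SUBUNIT III
COX3	MT-CO3
ATP6	ATP6
ATP6	ATPASE6
ATP6	ATPASE 6
ATP6	ATP SYNTHASE F0 SUBUNIT 6
ATP6	MT-ATP6
ATP8	ATP8
ATP8	ATPASE8
ATP8	ATPASE 8
ATP8	ATP SYNTHASE F0 SUBUNIT 8
ATP8	MT-ATP8
CYTB	CYTB
CYTB	CYT B
CYTB	COB
CYTB	CYTOCHROME B
CYTB	MT-CYB
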