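mirna_id	gene_id
hsa-let-7b	ASPA
hsa-miR-130a	ABAT
hsa-miR-130b	ESR1
hsa-miR-136	CXCL14
hsa-miR-148a	FAM134B
hsa-miR-148b	SORD
hsa-miR-152	ABAT
hsa-miR-181c	ESR1
hsa-miR-181d	FAM134B
hsa-miR-182	SORD
hsa-miR-18a	ABAT
hsa-miR-18b	ESR1
hsa-miR-19a	FAM134B
hsa-miR-206	IGF1
hsa-miR-22	SORD
hsa-miR-221	ABAT
hsa-miR-222	ESR1
hsa-miR-26b	PBLD
hsa-miR-29a	PCK1
hsa-miR-29c	ASPA
hsa-miR-302a	FAM134B
hsa-miR-302b	CXCL14
hsa-miR-302c	SORD
hsa-miR-302d	ABAT
hsa-miR-31	ESR1
hsa-miR-340	IGF1
hsa-miR-372	FAM134B
hsa-miR-373	PBLD
hsa-miR-410	PCK1
hsa-miR-425	ASPA
hsa-miR-488	CXCL14
hsa-miR-495	IGF1
hsa-miR-506	SORD
hsa-miR-520b	PBLD
hsa-miR-520e	PCK1
hsa-miR-93	ABAT
hsa-miR-96	ESR1
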