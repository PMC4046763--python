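[
 {
  "name": "SMID_BREAST_CANCER_BASAL_DN",
  "deg_group": "C/N_down",
  "deg_members": [
   "ABAT",
   "ASPA",
   "CXCL14",
   "ESR1",
   "FAM134B",
   "IGF1",
   "PBLD",
   "PCK1",
   "SORD"
  ],
  "mirnas": [
   "hsa-let-7b",
   "hsa-miR-130a",
   "hsa-miR-130b",
   "hsa-miR-136",
   "hsa-miR-148a",
   "hsa-miR-148b",
   "hsa-miR-152",
   "hsa-miR-181c",
   "hsa-miR-181d",
   "hsa-miR-182",
   "hsa-miR-18a",
   "hsa-miR-18b",
   "hsa-miR-19a",
   "hsa-miR-206",
   "hsa-miR-22",
   "hsa-miR-221",
   "hsa-miR-222",
   "hsa-miR-26b",
   "hsa-miR-29a",
   "hsa-miR-29c",
   "hsa-miR-302a",
   "hsa-miR-302b",
   "hsa-miR-302c",
   "hsa-miR-302d",
   "hsa-miR-31",
   "hsa-miR-340",
   "hsa-miR-372",
   "hsa-miR-373",
   "hsa-miR-410",
   "hsa-miR-425",
   "hsa-miR-488",
   "hsa-miR-495",
   "hsa-miR-506",
   "hsa-miR-520b",
   "hsa-miR-520e",
   "hsa-miR-93",
   "hsa-miR-96"
  ]
 },
 {
  "name": "SMID_BREAST_CANCER_LUMINAL_B_UP",
  "deg_group": "C/N_down",
  "deg_members": [
   "ABAT",
   "ESR1",
   "FAM134B",
   "SORD"
  ],
  "mirnas": [
   "hsa-miR-130a",
   "hsa-miR-130b",
   "hsa-miR-148a",
   "hsa-miR-148b",
   "hsa-miR-152",
   "hsa-miR-181c",
   "hsa-miR-181d",
   "hsa-miR-182",
   "hsa-miR-18a",
   "hsa-miR-18b",
   "hsa-miR-19a",
   "hsa-miR-22",
   "hsa-miR-221",
   "hsa-miR-222",
   "hsa-miR-302a",
   "hsa-miR-302c",
   "hsa-miR-302d",
   "hsa-miR-31",
   "hsa-miR-372",
   "hsa-miR-506",
   "hsa-miR-93",
   "hsa-miR-96"
  ]
 }
]
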