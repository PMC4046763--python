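[
 {
  "name": "chr1q32",
  "deg_group": "C/N_up",
  "features": [
   "BATF3",
   "C1orf106",
   "CENPF",
   "MDM4",
   "NEK2",
   "RABIF",
   "TLR5",
   "TRAF5",
   "UBE2T"
  ],
  "profiles": [
   "C"
  ]
 },
 {
  "name": "KAUFFMANN_MELANOMA_RELAPSE_UP",
  "deg_group": "C/N_up",
  "features": [
   "CENPF",
   "CHEK1",
   "CHEK2",
   "FANCD2",
   "GINS2",
   "MCM6",
   "MSH2",
   "RAD54L",
   "RFC4",
   "RRM2",
   "SMC2",
   "TOP2A"
  ],
  "profiles": [
   "C"
  ]
 },
 {
  "name": "PETROVA_PROX1_TARGETS_UP",
  "deg_group": "C/N_up & C/P_up",
  "features": [
   "BUB1B",
   "CCNE2",
   "CDK1",
   "MCM6",
   "TOP2A"
  ],
  "profiles": [
   "C",
   "C/P"
  ]
 },
 {
  "name": "BROWNE_HCMV_INFECTION_2HR_UP",
  "deg_group": "P/N_up",
  "features": [
   "EGR1",
   "FOS",
   "NR4A2",
   "NR4A3"
  ],
  "profiles": [
   "P/N"
  ]
 },
 {
  "name": "ENK_UV_RESPONSE_EPIDERMIS_DN",
  "deg_group": "P/N_up",
  "features": [
   "AREG",
   "CH25H",
   "EGR1",
   "EGR2",
   "FJX1",
   "GSN",
   "LXN",
   "NR4A2",
   "PTGS2",
   "STK17B"
  ],
  "profiles": [
   "P/N"
  ]
 },
 {
  "name": "GSE9988_LOW_LPS_VS_CTRL_TREATED_MONOCYTE_UP",
  "deg_group": "P/N_up",
  "features": [
   "AREG",
   "EGR1",
   "IL6",
   "NR4A2",
   "NR4A3",
   "PTGS2",
   "RGS1",
   "SERPINB8"
  ],
  "profiles": [
   "P/N"
  ]
 },
 {
  "name": "MODULE_43",
  "deg_group": "C/N_down",
  "features": [
   "ACADL",
   "ACADSB",
   "CAT",
   "CYP1A1",
   "CYP26A1",
   "CYP2C8",
   "CYP3A4",
   "CYP3A7",
   "CYP4A11",
   "DAO",
   "ETFDH",
   "FMO3",
   "GYS2",
   "LEPR",
   "PPP1R1A",
   "QDPR",
   "TREH"
  ],
  "profiles": [
   "C"
  ]
 },
 {
  "name": "MODULE_99",
  "deg_group": "C/N_down",
  "features": [
   "ABAT",
   "AFM",
   "BBOX1",
   "BCHE",
   "CRHBP",
   "F11",
   "FETUB",
   "IGF1",
   "LEPR",
   "LIFR",
   "MARCO",
   "NAT2",
   "OTC",
   "PCK1",
   "SLC10A1",
   "SLC22A1",
   "UGT8"
  ],
  "profiles": [
   "C/N"
  ]
 },
 {
  "name": "PKCA_DN.V1_UP",
  "deg_group": "C/N_down",
  "features": [
   "ADRA1A",
   "BBOX1",
   "CYP2C18",
   "CYP2C8",
   "DIO1",
   "FBP1",
   "LECT2",
   "NR1I3",
   "PCK1",
   "PIPOX",
   "PRODH2",
   "RDH16",
   "RDH5",
   "SEC14L2",
   "SLC2A2",
   "TREH",
   "UPB1"
  ],
  "profiles": [
   "C"
  ]
 }
]
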