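# Sentinel lesion catalog, version 1.
# Maps fusions and hotspot mutations to the subtype vocabulary of the
# integration rule table.  Edit and re-version rather than patching code:
# subtype taxonomies evolve faster than software.
version: 1

# exact gene pairs (5' partner first; matching ignores orientation)
defining_fusion_pairs:
  "BCR::ABL1": "Ph"
  "ETV6::RUNX1": "ETV6::RUNX1"
  "TCF3::PBX1": "TCF3::PBX1"
  "TCF3::HLF": "HLF"
  "UBTF::ATXN7L3": "CDX2/UBTF"
  "PAX5::ETV6": "PAX5::ETV6"

# any fusion involving the gene implies the subtype (rearrangement classes)
defining_fusion_genes:
  KMT2A: "KMT2A"
  ZNF384: "ZNF384"
  DUX4: "DUX4"
  MEF2D: "MEF2D"
  HLF: "HLF"
  NUTM1: "NUTM1"
  BCL2: "BCL2/MYC"
  MYC: "BCL2/MYC"
  BCL6: "BCL2/MYC"

# CRLF2 rearrangements: kinase-class evidence with their own subtype logic
crlf2_genes: [CRLF2]

# kinase-activating genes whose rearrangement is Ph-like-class evidence
kinase_fusion_genes:
  [ABL1, ABL2, CSF1R, PDGFRA, PDGFRB, LYN, CRLF2, JAK2, EPOR, TSLP, TYK2,
   IL2RB, NTRK3, PTK2B, FGFR1, FLT3, DGKH, BLNK, CBL]

# hotspot mutations defining a subtype
sentinel_mutations:
  - {gene: PAX5, protein_change: P80R, subtype: "PAX5 P80R"}
  - {gene: IKZF1, protein_change: N159Y, subtype: "IKZF1 N159Y"}
  - {gene: ZEB2, protein_change: H1038R, subtype: "ZEB2/CEBP"}

# any other protein-altering variant in these genes counts toward PAX5alt
pax5alt_mutation_genes: [PAX5]
# any fusion involving PAX5 (other than PAX5::ETV6) counts toward PAX5alt
pax5alt_fusion_genes: [PAX5]

# secondary hotspot genes reported as context, never subtype-defining
reportable_hotspot_genes:
  [FLT3, IL7R, JAK1, JAK2, JAK3, KRAS, NRAS, PTPN11, NF1, IKZF3, TP53]

# lesions validated against single-gene overexpression
expression_coupled:
  "CRLF2-r": CRLF2
  "DUX4": DUX4
  "NUTM1": NUTM1
  "HLF": HLF
  "CDX2/UBTF": CDX2
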