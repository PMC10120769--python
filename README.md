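# leukotype

Integrative molecular subtyping of B-cell acute lymphoblastic leukemia
(B-ALL) from RNA-seq, for computational hematology groups and pipeline
developers. B-ALL comprises over two dozen molecular subtypes with
distinct outcomes and therapies, defined by a mix of sentinel gene
fusions (e.g. *BCR::ABL1*, *ETV6::RUNX1*, *KMT2A* rearrangements),
hotspot mutations (*PAX5* P80R, *IKZF1* N159Y, *ZEB2* H1038R), gross
aneuploidy (hyperdiploid, near haploid, low hypodiploid, iAMP21), and —
for phenocopy subtypes with no detectable driver — gene-expression
profile (GEP) alone. `leukotype` combines all of these evidence streams
from a single RNA-seq run into one definitive, auditable subtype call.

## What it does

Starting from a raw gene-level read-count matrix (plus optional
fusion-caller tables, a VCF of short variants, and a clinical
karyotype), the pipeline:

1. **Normalizes** counts with median-of-ratios size factors and a
   closed-form negative-binomial variance-stabilizing transform (VST),
   then quantile-maps each test sample onto a packaged reference cohort
   so library-prep shifts cancel.
2. **Classifies the GEP** with two independent ensemble models over the
   consensus feature genes: a linear one-vs-rest SVM and a
   PhenoGraph-style model (Jaccard-weighted shared-neighbor KNN graph +
   Louvain-family community detection, test samples voting their
   community's majority reference label). Each model votes once per
   round over an increasing schedule of top-ranked gene subsets
   (canonically 100, 200, …, 1000, 1058 genes — 11 rounds); the
   confidence score is the modal-vote fraction, and a subtype is
   reported only when it exceeds 0.5.
3. **Matches lesions** from FusionCatcher-style and CICERO-style fusion
   tables (merging duplicates, filtering read support) and from VCFs
   (dropping common SNPs with population allele frequency ≥ 1%) against
   a versioned sentinel catalog, then validates expression-coupled
   lesions (e.g. a *CRLF2* rearrangement must show *CRLF2*
   overexpression above the 95th percentile of subtype-negative
   reference samples).
4. **Infers karyotype** from per-chromosome median log2 expression
   ratios, refined by allele-fraction imbalance at heterozygous SNPs
   (mean |VAF − 0.5|) and anchored on allele-balanced chromosomes so
   genome-wide losses are not normalized away; flags iAMP21 as a
   segmental chr21 gain beyond whole-chromosome trisomy.
5. **Integrates** everything through an explicit, ordered rule table:
   genetic lesions determine primary subtypes (*BCR::ABL1* → Ph
   unconditionally), chromosome-number ranges define the aneuploid
   subtypes (≥51 hyperdiploid, 47–50 low hyperdiploid, 31–39 low
   hypodiploid, 24–30 near haploid), and GEP decides phenocopies
   (ETV6::RUNX1-like, KMT2A-like, ZNF384-like) and everything the
   lesions leave open.
6. **QCs purity** by non-negative least squares deconvolution against a
   20-cell-type blood signature; samples whose B-lineage fraction
   (pro-B1 through mature B) falls below 30% are flagged, since
   normal-cell contamination distorts classification.

A single-cell mode QC-filters a sparse cell × gene matrix (genes in ≥5
cells; cells with ≥200 genes, <10% mitochondrial reads, gene count ≤
median + 3·MAD), types every cell against the blood-cell reference,
flags pro-B–to–pre-B cells as leukemic-blast candidates, subtypes them
against the bulk reference centroids, and calls the sample from the
modal blast vote — even when blasts are under 20% of cells. A
near-uniform spread of blast subtype votes flags probable *normal* B
precursors rather than leukemia.

Every stage is testable without patient data through a synthetic-cohort
generator: negative-binomial counts with per-subtype marker shifts,
chromosome-copy scaling, subtype-consistent fusions/mutations written as
real VCF and fusion-table files (with decoy false positives), and
sparse single-cell matrices with contaminant cell types.

## Worked example

Simulate a cohort, train a reference bundle, and classify one sample
that carries a *KMT2A::AFF1* fusion:

```bash
leukotype simulate --out sim --seed 7 --scenario distinct8 \
    --samples-per-subtype 12 --n-genes 1500 --no-lesion-files
leukotype build-ref --counts sim/counts.tsv \
    --annotation sim/gene_annotation.tsv \
    --labels sim/gep_labels.tsv --out bundle --seed 1 --quick-ranking
# test_sample.tsv = one column of sim/counts.tsv (sample S0012, a KMT2A
# cohort member); its fusion table and VCF come from the lesion-file
# generator (leukotype.synthetic.generate_vcf_and_fusion_files)
leukotype classify --counts test_sample.tsv \
    --annotation sim/gene_annotation.tsv --bundle bundle \
    --fusions lesions/S0012.fusioncatcher.tsv \
    --vcf lesions/S0012.vcf --out results
cat results/S0012.report.txt
```

```
Sample: S0012
Final subtype: KMT2A
Rule fired: R2-defining-fusion
Confidence note: lesion+GEP concordant

Evidence:
  - KMT2A::AFF1 [defining fusion]

GEP models:
  SVM: KMT2A (confidence 1.000, reported)
  PhenoGraph: KMT2A (confidence 1.000, reported)

CNV: 46 chromosomes (none); iAMP21=False; inferred sex male
```

Reading the report: both GEP models voted KMT2A in every ensemble round
(confidence 1.000 > 0.5, so both are reported), the fusion table
contained the defining *KMT2A::AFF1* rearrangement, and the two agree —
the strongest evidence class (`lesion+GEP concordant`). The
chromosome-level profile is diploid (46, no aneuploid class, no
segmental chr21 amplification), so no karyotype rule interferes.
`results/calls.tsv` holds the same call in machine-readable form and
`results/S0012.evidence.tsv` the full lesion table.

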