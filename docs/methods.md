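# Methods

This note documents the models implemented in `leukotype`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the package's known limitations. It states no
empirical result that the test suite and `scripts/acceptance.py` do not
themselves compute.

## Normalization

**Size factors.** Median-of-ratios: for sample *j*,
`s_j = median_g (k_gj / geomean_g)` over genes with a positive geometric
mean across samples. Scale-equivariant by construction. If no gene is
expressed in every sample (or only one sample is given), total-count
factors scaled to geometric mean 1 are used and the transform falls back
to `log2(normalized + 1)`.

**Variance-stabilizing transform.** Per-gene dispersions are estimated
by method of moments on normalized counts, `α̂ = (var − μ)/μ²`; the
parametric trend `α(μ) = a0 + a1/μ` is fitted by Huber robust
regression; the closed form of the fitted trend is applied:

    vst(x) = log2( (1 + a1 + 2·a0·x + 2·√(a0·x·(1 + a1 + a0·x))) / (4·a0) )

which is asymptotically `log2(x)` for large counts. A degenerate fit
(`a0 ≤ 0` or `a1 ≤ 0`) triggers an automatic, logged fallback to
`log2(normalized + 1)`. Exact replication of any particular VST
implementation (dispersion shrinkage, gene-wise GLM fits) is
deliberately not attempted: downstream classification consumes ranks
and margins, not absolute values. One consequence worth knowing: the
VST intentionally compresses fold-changes at moderate counts, so
chromosome-ratio magnitudes measured on VST values undershoot
`log2(c/2)`; the copy-number thresholds below are calibrated for that
compressed scale, while exact ratio recovery holds on the plain log
scale.

**Co-normalization.** A test sample is aligned to the reference gene
space (missing reference genes imputed at the reference per-gene
median, logged, capped at 20% for the classifiers) and each sample's
values are replaced by the pooled-reference quantiles at the sample's
own plotting positions `(rank + 0.5)/n`. This removes monotone global
shifts exactly, preserves within-sample ranks, and is idempotent.
Quantile mapping was chosen over joint re-normalization or median
centering because it is invertible on ranks and robust to library-prep
differences; it can be disabled (`--no-conorm`) since the prediction
models are also meant to accept uncorrected data.

## Feature selection and reference curation

**Balanced cohorts.** Subtype cohorts are equalized at the eight
schedule sizes (10, 25, 50, 75, 100, 150, 200, 250 samples per class):
larger classes are subsampled without replacement, smaller classes are
augmented by SMOTE interpolation `x_i + u·(x_nn − x_i)`,
`u ~ Uniform(0,1)`, with `k = 5` same-class neighbors (capped at class
size − 1). A one-sample class is an error — there is nothing to
interpolate.

**Boruta.** Each iteration appends independently shuffled shadow copies
of all candidate (protein-coding) features, fits a random forest
(default 500 trees, √p features per split), and scores a "hit" for
features beating the maximum shadow importance. From iteration 5 on,
two-sided binomial tests at `α = 0.01` with Bonferroni correction over
the *initial* feature count confirm or reject features; correcting over
the shrinking active set would progressively loosen the threshold and
admit chance-correlated noise. Features still tentative at `max_iter`
(default 100) are rejected. The consensus list keeps genes confirmed in
all eight resampled runs (intersection semantics), ranked by mean
importance with ties broken by gene ID.

**Quick ranking.** For workflows that do not need the eightfold
consensus, a one-way-ANOVA F ranking is provided; it keeps only genes
at Benjamini–Hochberg FDR < 0.01, mirroring the confirmed-set role —
padding the list with non-discriminative genes would poison the larger
ensemble rounds, whose distances would then be dominated by noise.

**Reference curation.** Samples whose expression neighborhood
contradicts their lesion-derived label are dropped iteratively: each
round clusters the cohort with the PhenoGraph-style graph and embeds it
in 2-D; a sample is dropped when its community majority label *or* its
15-nearest-neighbor majority in the embedding disagrees with its label.
Clustering and embedding run on the top 500 genes by median absolute
deviation (distances over the full gene space are diluted by
uninformative genes), the graph `k` is capped at the smallest class
size (larger `k` forces small classes into mixed neighborhoods), and
the default reducer is t-SNE with a fixed seed (`perplexity =
min(30, (n−1)/3)`): a linear 2-D projection cannot keep many classes
apart and would mass-drop good samples. Any reducer with a
`fit_transform` can be injected. Classes never drop below 3 samples;
iteration stops at a fixed point or 5 rounds.

## GEP classification

Two models, each voting once per ensemble round; rounds use the top-k
ranked genes for k = step, 2·step, … then the full list (1,058 genes at
step 100 gives the canonical 11 rounds). Confidence is the modal-vote
fraction — the simplest statistic consistent with a 0.5 reporting
cutoff — and is order-free in the rounds.

**SVM.** Linear one-vs-rest (`LinearSVC`, primal, C = 1) with per-gene
standardization fitted on the reference per round. The primal problem
has a unique optimum, so refits reproduce predictions exactly; bundles
therefore store only the reference data and refit on load.

**PhenoGraph-style.** Reference and test samples are standardized and
clustered jointly per round: exact KNN graph (Euclidean), edges
weighted by the Jaccard index of shared neighbor sets, community
detection by the RB-configuration (Louvain-family) objective at
resolution 1.0 with a fixed seed. Each test sample votes the majority
reference label of its community; a community with no reference
members, or with a tied majority, votes "unassigned" — never a coin
flip. `k = 30`, capped at n/3 *and at the smallest reference class
size*.

**Unification.** Both models reported and equal → concordant; both
reported but different → discordant, with the SVM label carried forward
(it resolves closely related subtypes better) but both surfaced to the
rule engine; one reported → that label, flagged single-model; neither →
unclassified. The GEP class vocabulary merges Ph with Ph-like and never
contains the non-distinct classes (near haploid, low hyperdiploid,
CRLF2 without Ph-like expression) — those exist only in the rule
engine's output vocabulary.

## Lesion evidence

Fusion tables are parsed by header-detected dialect, merged across
orientations and callers (max read support, dual-caller flagged), and
filtered by `--min-reads` (default 2) — a machine substitute for manual
curation of caller output, which is dominated by false positives. VCF
variants annotated with population allele frequency ≥ 1% are removed
(inclusive boundary; annotations are rounded to printed precision
because float32 round-trips would otherwise break the boundary).
Matching runs exact fusion pairs first (e.g. *BCR::ABL1*,
*ETV6::RUNX1*), then single-gene rearrangement classes (*KMT2A*,
*DUX4*, *ZNF384*, …), then *CRLF2* and the kinase-gene list (Ph-like
class evidence), then *PAX5* alterations; unmatched lesions are kept as
"other". "Other *PAX5* mutations" counted toward PAX5alt are any
protein-altering *PAX5* variants surviving filters. The catalog ships
as versioned, editable YAML.

Expression-coupled lesions (*CRLF2*-r → *CRLF2*, *DUX4*-r, *NUTM1*-r,
*HLF*-r, *UBTF::ATXN7L3* → *CDX2*) are validated against the reference:
consistent iff the sample's expression of the coupled gene exceeds the
95th percentile of reference samples outside the lesion's GEP class — a
scale-free criterion. Inconsistent lesions never fire a rule; they
appear in the evidence trail as down-weighted.

## Chromosome-level copy number

Per gene, the sample's (co-normalized) expression minus the reference
median; per chromosome, the median of those differences, centered on
the autosome median. Median-centering silently assumes the modal copy
state is diploid, which fails for genome-wide losses; when variant
allele fractions are available, autosomes with balanced heterozygous
sites (imbalance score < 0.08, heterozygous fraction ≥ 0.5 of
depth-bearing variants) re-anchor the baseline at copy 2, which
recovers near-haploid and low-hypodiploid genomes correctly. The
allele-imbalance score is the mean |VAF − 0.5| over variants with VAF
in (0.1, 0.9), requiring ≥ 10 informative sites per chromosome; a
trisomy's 1/3–2/3 mixture scores ≈ 0.167.

Integer copies come from ratio thresholds chosen to separate the
VST-compressed `log2(c/2)` levels: within ±0.2 → 2, [0.2, 0.75) → 3,
≥ 0.75 → 4, ≤ −0.2 → 1 (X/Y use plain rounding on a sex-inferred
baseline; sex comes from Y-gene expression). The modal chromosome
number is the sum of per-chromosome copies; karyotype classes follow
the integration table's ranges (24–30 near haploid, 31–39 low
hypodiploid, 47–50 low hyperdiploid, ≥ 51 hyperdiploid). More than 6
unreliable chromosomes (< 30 usable genes each) make the class
"unreliable". This is a deliberately simplified chromosome-level
caller — the rule engine needs only the modal number and the iAMP21
flag — and all thresholds are exposed as parameters.

**iAMP21.** chr21 genes are split into ≤ 10 positional bins; the flag
is raised iff ≥ 3 consecutive bins have a median ratio ≥ 2·log2(2.5/2)
*and* stand ≥ 0.3 above the chromosome's own median bin level, and not
all bins qualify. The second condition makes the gain segmental: a
whole-chromosome trisomy, or the global normalization shift of a
near-haploid genome, cannot raise the flag.

## Rule integration

Rules are evaluated in a fixed order; the engine is a pure function and
every non-unclassified call cites its evidence:

1. *BCR::ABL1* → Ph, unconditionally (no added evidence may turn a
   *BCR::ABL1*-positive sample into a non-Ph call).
2. Defining fusion → its canonical subtype (GEP concordance recorded in
   the confidence note; expression-inconsistent fusions skipped).
3. Sentinel hotspot mutation → its subtype (*ZEB2* H1038R additionally
   requires a concordant GEP and is marked provisional, since that
   subtype sits outside the established table).
4. Ph/Ph-like GEP + non-*BCR::ABL1* kinase lesion → Ph-like.
5. *CRLF2*-r with a GEP that is not Ph/Ph-like → CRLF2(non-Ph-like).
6. Karyotype class → aneuploid subtype. A clinical karyotype always
   fires; an RNA-derived one fires only when the GEP is unreported or
   in the Hyperdiploid/Low-hypodiploid classes — the only GEP classes
   the table pairs with chromosome-number ranges (near haploid
   notoriously mimics hyperdiploid expression), and a noisy
   single-chromosome call must not override a confident unrelated GEP.
7. PAX5alt GEP + *PAX5* fusion/mutation/intragenic-amplification flag
   (not deletion) → PAX5alt. Intragenic amplification is not derivable
   from these inputs and is accepted as a user-supplied flag.
8. iAMP21 flag + iAMP21 GEP → iAMP21.
9. Canonical GEP without its defining lesion → phenocopy (-like).
10. Any remaining reported GEP → that subtype, noted GEP-only;
    otherwise unclassified.

Confidence notes: `lesion+GEP concordant`, `lesion-over-GEP` (only on
an actual conflict), `lesion-only` (lesion fired with no reported GEP),
`GEP-only`, `insufficient`.

## Deconvolution and purity

Non-negative least squares of the linear-scale (CPM-like) bulk sample
on a 20-cell-type signature over its marker genes, coefficients
renormalized to the simplex; mixtures are additive in linear space,
which is why deconvolution does not run on VST values. The blast
fraction sums pro-B1 through mature B (the bulk window; the single-cell
blast window is pro-B1 through pre-B2 — both are parameters). Samples
below 30% are flagged, never suppressed. The shipped signature is
synthetic, matched to the generator's cell models, and intended for
testing; a real signature is user-suppliable as TSV.

## Single-cell annotation

QC order: genes in ≥ 5 cells; cells with ≥ 200 expressed genes (on the
filtered gene set), < 10% mitochondrial reads (genes matched by
configurable prefix, default `MT-`), gene count ≤ median + 3·MAD (plain
MAD, computed on the cells surviving the first two cell rules). Cell
typing is single-pass Spearman correlation of log-CPM with each cell
type's signature profile over the signature markers. Cells typed
pro-B1…pre-B2 are blast candidates and are scored against the bulk
reference's per-class centroids on the union of each class's top
pairwise marker genes, using a nearest-centroid linear score: log-CPM,
background-centered on the non-blast cells' mean (which estimates each
gene's dataset-level baseline), dotted with the centroid deviations.
Rank correlation was evaluated for this step and found unstable on
sparse per-cell profiles, whose rank information lives entirely in the
few discriminative genes. The sample call is the modal blast subtype
with its vote fraction (≥ 20 blasts required, configurable); a
normalized vote entropy above 0.85 flags probable normal blasts.

## Synthetic-data generator

The generator defines the conditions every contract is tested under.
Bulk counts are negative-binomial with log-normal per-gene baselines
(median 30 counts; marker and driver genes floored at the median so
configured effects are recoverable), per-sample library factors
uniform in [0.7, 1.5], and dispersion `0.15 + 1.5/μ` — an asymptotic
patient-cohort dispersion of 0.15 with the usual low-count excess,
which is also what makes the VST trend fit well-posed. Subtype specs
carry marker genes with log2 effects (scaled 1.0/0.8/0.5/0 by the
distinctness class), a 24-chromosome copy profile scaling gene means by
c/2, optional sentinel fusion/mutation, an optional segmental chr21
amplification (central 40% of genes at copy 5), and lesion-coupled
driver overexpression (+4 to +5 log2 for *CRLF2*, *DUX4*, *NUTM1*,
*HLF*, *CDX2*) attached to the corresponding fusions. The shipped
catalog covers every rule-table subtype plus ZEB2/CEBP; phenocopies
share their canonical class's markers. Lesion files are written as real
VCF 4.2 (sentinel variant with gene/protein-change/population-AF
annotation and allele depths; decoy common SNPs at AF ≥ 1% on every
chromosome with allele fractions following the truth copy profile —
copy-1 chromosomes show loss of heterozygosity) and as both fusion
dialects with decoy false-positive rows.

Single-cell matrices draw ~8,000 UMIs per cell (typical droplet
depth — at a few thousand UMIs the per-cell marker information is too
thin for any scorer), with blasts carrying a random B-precursor stage
signature plus the subtype markers, contaminants carrying their
cell-type signature, and a mitochondrial background around 4–6%. The
cell gene universe includes the full marker vocabulary of both shipped
spec catalogs so bulk-trained references cross-apply.

What the generator does **not** emulate: isoform structure, read-level
artifacts, batch effects between library preparations, clonal
heterogeneity, doublets, ambient RNA, correlated gene modules, and
realistic gene-density differences between chromosomes. Passing tests
therefore demonstrate the pipeline's internal correctness and its
behavior under controlled effect sizes — not clinical performance on
patient data, for which a real curated reference cohort is required.

## Numerical and policy choices

- Modal-vote ties break lexicographically; graph-vote ties break to
  "unassigned"; ranking ties break by gene ID — everything is
  deterministic under a fixed seed.
- Problem sizes in the test suite (8 classes × 30 reference samples,
  1,500–3,600-gene universes, 200 aneuploid genomes, 20 Boruta seeds,
  1,000-cell single-cell samples) are deliberately scaled-down study
  conditions that still exercise every contract.
- The chromosome-ratio recovery checks use a low-dispersion
  measurement-accuracy fixture (dispersion 0.05) and plain log space,
  because at patient-level dispersion a single sample's chromosome
  median carries irreducible noise of the same order as the tolerance.
- The reference-bundle format is plain TSV + a JSON manifest with a
  content hash; classifiers are refit on load rather than pickled.

## Known limitations

- The chromosome-level caller is not a substitute for a dedicated CNV
  method: no sub-chromosomal events outside chr21, no focal deletions
  (e.g. *PAX5* deletions, which is also why PAX5alt's "not deletion"
  clause relies on the user), no subclonal copy states.
- Without a VCF, karyotype calls rest on expression ratios alone and
  single-chromosome calls can be noisy; the rule engine compensates by
  not letting RNA-derived karyotypes override unrelated confident GEPs.
- The shipped deconvolution signature is synthetic; purity flags on
  real data need a real signature.
- FLT3-ITD detection, fusion calling itself, and batch correction of
  historical cohorts are out of scope; the package consumes caller
  output and count matrices.
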