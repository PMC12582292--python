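# Methods

## The measurement model

Each picked protoplast is lysed in a well; the lysate is split in half, one
half analyzed by targeted UPLC-MS and the other by plate-based scRNA-seq. The
well ID is therefore the cell identity in both modalities, and integration is
an exact join — no computational alignment, mapping or label transfer is ever
applied.

### Absolute quantification

For each analyte a linear response `area = slope · c + intercept` is fitted by
ordinary least squares to the mean of triplicate peak areas across a standard
dilution ladder. The limit of quantification (LOQ) is the lowest standard
whose back-calculated mean accuracy is within ±20 % of nominal and whose
replicate CV is ≤ 20 % — the common bioanalytical acceptance rule; the rule's
tolerances are configurable (`loq_accuracy_tol`, `loq_cv_tol`). If no standard
qualifies the analyte is unquantifiable (LOQ = +∞).

A peak area from a cell well is converted as

    c_analysis = (area − intercept) / slope            [µM in the aliquot]
    amount     = split_factor · c_analysis · V_aliquot  [doubled for the split]
    c_cell     = amount / V_cell,  V_cell = (π/6)·d³    [sphere, d in µm]

with `split_factor = 2` (half the lysate measured) and `V_aliquot = 4 µL`
(the injection aliquot; the exact dilution chain is absorbed into this single
constant). Negative analysis concentrations are clamped to zero; anything
below the analyte's LOQ is censored to 0 µM and flagged, and no result ever
reports a nonzero concentration below LOQ. Unit chain: µM = pmol/µL, so
`amount_fmol = 1000 · c_analysis · V_aliquot` and `c_cell[µM] =
amount_fmol / V_cell[nL]`. Doublet and empty wells are never quantified;
empty wells instead feed a background report (count and median back-calculated
concentration of above-LOQ signals per analyte).

### Expression processing

* QC keeps picked single cells with strictly more than `min_genes` (default
  1,000) and strictly fewer than `max_genes` (10,000) detected genes, where
  detection means raw count > 0 (the minimal reading; no posterior or
  threshold-based detection). The reported retention percentage is truncated
  to an integer; co-annotation percentages are rounded half-up — both match
  the conventions of the experimental report this pipeline emulates.
* TPM: `1e6 · (count/len_kb) / Σ(count/len_kb)` with transcript lengths from
  the sidecar table; effective-length corrections are out of scope.
* Log-normalization: `ln(1 + 10⁴ · count / total)`, natural log, pseudocount 1.
* Variable genes: a local linear regression (tricube weights, span 0.3) of
  log10 variance on log10 mean predicts each gene's expected sd; raw counts
  standardized by it are clipped at √n_cells, and genes are ranked by the
  variance of the clipped z-scores. Ties break lexically by gene ID, making
  the selection fully deterministic.

### Integration, annotation, cross-tabulation

Metabolite concentrations are transformed `log10(1 + c µM)` (bounded at 0 for
absent analytes, monotone) and z-scored per analyte within each collection
batch using the sample sd (n−1); constant analyte-within-batch slices and
single-cell batches get z = 0. Embeddings take a feature × cell matrix
(scaled variable genes for RNA; the 12-analyte batch-z matrix for
metabolites); UMAP (n_neighbors 15, min_dist 0.1, fixed seed) is available,
but PCA is the default because its coordinates are exactly reproducible
across library versions — UMAP output is deterministic only for a fixed seed
*and* version.

Annotation applies ordered rules, first match wins. RNA priority is
idioblast > IPAP > epidermis, because the idioblast markers are the most
cell-type-exclusive; conflicts are logged. Metabolite presence means
"above LOQ" (flag false and c > 0) — detection alone is not trusted below the
quantifiable range. The epidermis splits into secologanin-only and
secologanin + mauritianin subtypes on the metabolite side only.

### Correlation and networks

Spearman ρ uses average ranks (midranks) and is computed between every
gene's TPM and every analyte's concentration over all jointly profiled cells,
with below-LOQ entries kept at 0 µM: the presence/absence pattern of a
cell-type-restricted metabolite is the dominant, intended signal. A
`detected_only` option restricts each analyte's correlation to cells where it
is nonzero; the default (all cells) is reported alongside any use of the
option. Constant vectors give NA, excluded from per-analyte rankings.

Trends of expression vs concentration use local linear regression with
tricube weights (span 0.75, degree 1) with pointwise 95 % CI
(fit ± 1.96·SE, residual variance estimated from the fit at the observed
points). Because concentrations span decades, the fit runs on the
log10(1 + c) axis by default and is evaluated on an even grid over the
observed range.

Transporter networks connect, per analyte, the top 15 most positive and
bottom 15 most negative transporter correlations (NA excluded; ties at the
cutoff break lexically and are logged; if the transporter pool is smaller
than top+bottom, a transporter is linked at most once). Exports: SIF
(`transporter <pos|neg> analyte`) and GraphML with ρ edge attributes and
per-transporter degree.

Differential expression between metabolic subclusters uses the two-sided
Wilcoxon rank-sum test: exact enumeration over all group assignments
(midranks, so ties are handled) when both groups have ≤ 10 cells, otherwise
the tie-corrected normal approximation (with continuity correction, as in
scipy). P-values are BH-adjusted across genes; log2 fold changes use
de-logged group means with pseudocount 1.

## The synthetic-data generator

The generator emulates the plate design the pipeline targets: four 96-well
plates collected on two days (two plates per day), ~24 % empty wells, ~3 %
doublets, diameters uniform in 30–50 µm. Cell types and proportions:
epidermis_A 0.30, epidermis_B 0.22, idioblast 0.09, IPAP 0.03 (rare by
design, < 4 %), parenchyma 0.36. Twelve analytes span µM–mM pools:

* nine *in-situ* analytes stored in the type that expresses their
  biosynthesis genes (a secologanin analog in both epidermal subtypes, a
  mauritianin analog in subtype B only, six alkaloids in idioblasts);
* two *transported* analytes decoupled from their genes — a catharanthine
  analog synthesized in the epidermis but pooled in idioblasts (with a low
  ubiquitous background pool, as transported metabolites are detected
  broadly), and a loganic-acid analog whose genes sit in the rare IPAP type
  while its ~40 mM pools sit in parenchyma;
* one ubiquitous low-level analyte.

Within a cell, pools share a latent factor (weight 0.7) so alkaloids stored
in the same cell co-occur. Counts are negative binomial (shared dispersion 2)
with log-normal library sizes (mean 10,000 counts, log-sd 0.7) over 2,000
genes whose relative levels come from a fixed "organism profile" seed —
separate simulations share gene-level biology, so an independently simulated
bulk profile is a valid pseudobulk comparator. Marker genes are exclusive to
their type; biosynthesis genes of in-situ analytes follow the unimodal link
`g(c) = a·log10(1 + c/c0)·exp(−c/c1)` (c0 = 100 µM, c1 = 5·10⁵ µM, peak
≈ 75 mM): expression rises with concentration and declines slightly past
~100 mM. Transported-analyte pathway genes keep a 15 % leaky baseline outside
their source type. Each type additionally over-expresses a 60-gene program
(3×) of otherwise generic genes, as real cell types do, so unsupervised
structure does not hinge on a handful of markers. Doublets are element-wise
sums of two independent component cells; empty wells are all-zero.

The calibration forward model is exactly the inverse of the quantification
stage: half the cell's analyte amount diluted into a 4 µL aliquot, linear
response with 5 % multiplicative CV (per-analyte slopes ~10⁵ area/µM), an
instrument floor at 3·10⁻⁷ µM below which the area is zero, and a 5-point
ladder from 10⁻⁶ to 10⁻⁴ µM. The ladder spans two decades because an
unweighted OLS fit across many decades lets the top standard's noise dominate
the intercept, destroying back-calculated accuracy at the low standards; two
decades around the sample range keep the LOQ at the bottom of the ladder,
where a dilution series reaching 0.001 nM places it. Empty wells
get occasional trace areas (rate 5 %) for the two most abundant analytes.

All generator draws are deterministic: one RNG stream per operation, sub-seeded
from `(seed, operation-id)`; identical configurations give bit-identical
outputs.

### What the generator does not emulate

No chromatography, spectra or sequencing reads; no ambient RNA, doublet
detection difficulty (doublet status is known from picking images, as in the
real workflow), mitochondrial content, or batch effects beyond the batch
label; cell-type expression programs are clean blocks rather than continuous
gradients. Tests passing on this generator therefore demonstrate the
correctness of the *analysis* — unit arithmetic, censoring, rule logic,
statistical calibration, recovery of designed structure — not robustness to
every artifact of real plates.

## Numerical and design choices

* Percent reporting: retention truncates; co-annotation rounds half-up.
* Spearman on tied data uses midranks; NA for constant vectors.
* LOESS standard errors use the equivalent-kernel norm with residual dof
  approximated by n − Σ‖l(xᵢ)‖²; degenerate local designs fall back to the
  weighted mean.
* The trend-peak recovery checks assert the fitted argmax within ±0.25 on the
  log10-concentration axis (a factor ≈ 1.8), on samples of 150 cells drawn
  ±1.2 decades around the true peak with 10 % noise — a range comparable to
  the concentration span over which such trends are observable per analyte.
* Problem sizes in the test suite and acceptance script (4 × 96 wells, 2,000
  genes, 12 analytes, 10–20 replicate seeds) are the package's default
  plate-design scale; they keep every recovery property measurable while the
  whole pipeline runs in seconds.
* The acceptance script's co-annotation and retention examples take the
  experiment's printed counts (8/9, 29/38, 193/289) as inputs and recompute
  the percentages through the package's reporting path.

## Known limitations

* Pure external calibration: no internal-standard normalization.
* Unweighted OLS calibration is sensitive to ladder design (see above);
  weighted (1/x²) regression would extend usable ladders but is not the
  fitted model here.
* The LOQ rule needs ≥ 2 replicates per standard for a CV; single-replicate
  points pass the CV check trivially.
* `wilcoxon_de`'s exact path enumerates C(n, n_a) assignments and is
  intentionally limited to groups of ≤ 10.
* RNA annotation leaves non-marker types "unassigned" rather than guessing a
  parenchyma label by exclusion.
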