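# Methods

## Model

Each gene is modelled as a first-order chain: transcription produces
unspliced RNA at rate α, splicing converts it at rate β, and spliced RNA
degrades at rate γ. At steady state the expected unspliced and spliced
abundances are u = α/β and s = α/γ, so the unspliced share of total RNA is

    u / (u + s) = γ / (β + γ),

independent of α. This identity drives the package's mechanism verdict:

* **XCU** (transcriptional upregulation) multiplies α on X-linked genes —
  the X:A dosage ratio rises, the unspliced fraction does not move.
* **TURNOVER** (transcript stabilization) divides γ — dosage rises *and*
  the unspliced fraction falls, because spliced RNA accumulates relative
  to nascent RNA.

`discriminate_mechanism` tests (1) ChrX-S:A elevation in a stratum against
a reference stratum (one-sided greater Wilcoxon rank-sum, default α =
0.05) and (2) an X unspliced-fraction deficit against autosomes within the
stratum (one-sided less paired Wilcoxon signed-rank, default α = 0.05).
Elevated + deficit → TURNOVER; elevated only → XCU; not elevated → NONE;
elevated but too few paired cells for the second test → AMBIGUOUS. The
default reference stratum is same-sex zygotene: the pachytene dosage claim
is relative to the neighbouring earlier stage, which avoids both the
pre-meiotic population (different cell biology) and diplotene (potentially
carrying the same effect). One-sided tests are used inside the verdict
because the hypotheses fix the directions; every user-facing comparison
function defaults to two-sided.

Note an asymmetry inherent in the rule: under a true XCU world the deficit
test is an exact null at level α, so the verdict misfires to TURNOVER in
about 5% of replicates by construction. Tightening α_turnover would trade
those errors against sensitivity to weak stability effects; the defaults
keep both tests at the conventional 0.05.

## Dosage and turnover statistics

* Gene classes: ChrX-E = X-linked genes with escape-flavour categories
  (PAR, E, mostly E, mostly VE, VE; matching is case/underscore
  insensitive), ChrX-S = all other X-linked genes, Chr7 = a designated
  autosomal control (still part of the autosome denominator), AUTOSOME =
  remaining chr1–22, CHRY and EXCLUDED (MT, scaffolds) never enter any
  denominator.
* `class_means`: per cell, arithmetic mean TPM over each class divided by
  the autosome-universe mean. The universe is first filtered to genes
  detected (TPM > 0) in ≥ `detect_frac` of cells (default 0.05; 0
  reproduces "all genes"). Zeros are included after the filter — the
  filter stabilizes means without conditioning on per-cell detection.
  Cells with a zero autosome mean are flagged invalid.
* `unspliced_fractions`: pooled per-cell, per-class fraction
  Σu/(Σu+Σs) by default; a `per_gene_mean` variant averages per-gene
  fractions over genes with nonzero totals. The pooled form is robust to
  zero-total genes and is what the verdict uses.
* Stage contrasts are two-sided Wilcoxon rank-sum on per-cell ratios;
  within-cell class contrasts are paired two-sided Wilcoxon signed-rank
  with zero differences dropped (p = 1 when all differences are zero).

## Exact-test policy

All Wilcoxon tests share one dispatch: tie-aware exact enumeration of the
permutation/sign-flip null for combined n ≤ 8 (inclusive tails; two-sided
p = min(1, 2·min(tails))); scipy's exact method for tie-free samples with
combined n ≤ 25; the normal approximation with tie and continuity
corrections otherwise. Welch's t uses scipy with the convention t = 0,
p = 1 when both groups are constant and equal. BH adjustment goes through
statsmodels and, for cluster DEGs, is applied within each cluster's gene
list (matching the convention of one-vs-rest marker callers).

## DEG calling

`find_degs` runs one-vs-rest two-sided rank-sum per gene per cluster,
BH-adjusts within cluster, computes the natural-log fold change
ln((mean_in+1)/(mean_out+1)) on TPM group means (pseudocount 1), and
retains records with p_adj < 0.05 and pct_1 > 0.6, both strict. Clusters
with fewer than 3 cells are skipped. `sex_degs` applies the stricter
p_adj < 0.01 with |ln FC| > 1.5 on the shared gene universe and splits
records by the sign of the fold change.

## Synthetic data: the stated world

`simulate` emits 2 sexes × 5 stages × `cells_per_stage` cells over a
500-gene genome (chr1: 100, chr2: 100, chr3: 80, chr7: 60, X: 140 with 25%
escapees, Y: 20) with TPM plus matched spliced/unspliced counts.

* **Kinetics.** β = 2 and γ = 1 are global constants; per-gene α is
  log-normal (ln-mean ln 10, ln-sd 0.8, a ~30-fold 5–95% dynamic range)
  drawn by stratified quantile sampling within each chromosome class, and
  each class's α vector is rescaled to the population mean. This makes
  classes exchangeable *by construction*: under NULL every class:A rate
  ratio is 1, so deviations in the measured ratios reflect the observation
  model, not the gene-sampling lottery. Constant β, γ also make the pooled
  class fraction exactly γ/(β+γ), which is what gives the XCU scenario its
  clean "dosage up, fraction unchanged" signature; with per-gene β, γ the
  class-level fraction would pick up rate-pairing noise and the verdict's
  identifiability would degrade. Per-gene kinetic heterogeneity in β and γ
  is therefore deliberately absent from the stated world.
* **Scenarios.** MSCI: α × 0.1 on X in male pachytene (and diplotene by
  default); XCU: α × 1.5 on X in female pachytene; TURNOVER: γ ÷ 2 on X in
  female pachytene. Effects are surgical: at a fixed seed, non-targeted
  strata are bit-identical across scenarios because random streams are
  split per (purpose, sex, stage, cell) from the master seed — adding
  cells never perturbs existing draws.
* **Markers.** 8 markers per stage, drawn from the plain autosomes, with
  baseline α pinned at the population mean; a marker's α is multiplied by
  4.5 in its own stage and damped to 0.125 elsewhere. The multipliers
  satisfy k_on + (S−1)·k_off = S (S = 5 stages), so total marker output is
  identical in every stage and the marker program cannot distort the
  autosome mean of any stratum. The 36-fold on/off contrast yields ≥ 95%
  stage-call accuracy at default noise; panel size and boost were set for
  that design target.
* **Observation model.** Negative binomial with dispersion size 2 around
  the (library-scaled) steady-state means, log-normal library factors with
  CV 0.3, and gene-level Bernoulli dropout at rate 0.1 hitting a gene's
  spliced and unspliced counts together (detection failure in full-length
  protocols is gene-level). TPM is the per-cell total (u+s) rescaled to
  10^6. Dropout and library-size values are typical of Smart-Seq2 quality
  cells; neither is critical to any acceptance property.
* **What the generator does not emulate:** donor/batch effects, doublets,
  ambient RNA, gene-length bias in TPM, per-gene kinetic variability in
  β/γ, correlated gene programs beyond the stage markers, or empty/failed
  cells. A green test on synthetic data therefore establishes that the
  statistics recover planted kinetic effects under clean Smart-Seq2-like
  noise — not that they are robust to batch structure or annotation error.

## QC presets

`female_fetal`: total transcripts in [100,000, 1,500,000] (inclusive —
"between" read inclusively; the boundary convention at exactly 100,000 /
1,500,000 is this package's choice) and genes detected strictly above
2000. `male_adult`: total strictly above 10,000 and genes strictly above
2000. Totals are column sums of the TPM matrix as deposited.

## Numerical choices and degenerate inputs

* Stage scoring z-scores log1p TPM per gene (population SD; constant
  genes get z = 0); a cell is `unassigned` when its top two stage scores
  tie within 1e-9 or no score is positive.
* k-means clustering uses full-SVD PCA and `n_init=10` with a fixed seed;
  labels are deterministic per seed but arbitrary in numbering.
* Spearman cluster correlations are symmetrized and the diagonal pinned to
  1 before complete-linkage on 1 − ρ.
* Pearson p-values use the t transform of r (|r| = 1 → p = 0).
* Percentages in composition tables are exact rational counts rendered at
  one decimal.
* Duplicate gene ids in annotations: first occurrence wins, the rest are
  logged. Escape categories on non-X genes are ignored with a warning.

## Known limitations

* The mechanism verdict assumes steady state within a stage; bursts or
  stage transitions captured mid-flight bias the unspliced fraction.
* Cluster counts, DEG counts and correlation structure on real data
  depend on upstream clustering parameters the package deliberately does
  not fix; only the filter semantics are pinned.
* Allele-specific (SNP-based) X activity is out of scope, as is read
  alignment and spliced/unspliced counting — the pipeline consumes matrix
  outputs of tools like STARsolo/velocyto.
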