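# Methods

This note documents the models and procedures implemented in `isoratio`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Absolute quantification from composite MS1–MS2 data

MS2-level isobaric multiplexing (TMT) reports relative channel intensities
per spectrum, while ratios *between different proteins* require abundances
on a common scale. The estimator used here reconstructs absolute-scale
abundances by treating each PSM's MS1 precursor intensity as the total
signal of that peptide across all pooled samples and apportioning it by
the MS2 reporter fractions:

    x_ic = Σ_{PSM j of protein i} ms1_j · r_jc / Σ_c' r_jc ,
    abundance_ic = x_ic / N_i

where `N_i` is the number of theoretically observable tryptic peptides of
protein i (fully tryptic, zero missed cleavages, length 7–30, no cleavage
C-terminal to K/R when followed by proline; digestion via pyteomics). This
is the iBAQ idea adapted to multiplexed data. Apportionment conserves MS1
intensity exactly, and scaling all MS1 intensities by a constant scales
the whole matrix by the same constant.

Choices:

* **Estimator family.** An iBAQ-style estimator (sum ÷ theoretical peptide
  count) rather than top-N averaging. iBAQ is the simplest estimator whose
  denominator is a property of the sequence alone, which keeps the
  pipeline independent of peptide detectability models.
* **Peptide uniqueness.** Only PSMs whose peptide maps to exactly one
  accession contribute. Within isoform groups of ~90% identity, shared
  peptides cannot be attributed and would homogenize exactly the ratios
  under test; the default razor rule therefore *excludes* shared peptides
  everywhere.
* **Missing ≠ zero.** A protein with no unique quantifiable PSM is absent
  from the matrix, never zero-filled. A pair enters a contrast only when
  both members are quantified in every sample (complete-case default; a
  ≥k-per-group rule is available via `complete_case=False` pre-filtering).
* **Order of operations.** Apportion per PSM → sum per protein → normalize.
  Apportioning first lets high-intensity PSMs dominate naturally, in place
  of peptide-level averaging.

## Normalization and the generalized log

Full variance-stabilizing normalization estimates per-sample affine
calibrations by maximum likelihood. `isoratio` uses a transparent two-step
surrogate with the same intent and a testable closed form: (1) per-sample
multiplicative median scaling on proteins quantified in all samples,
toward the geometric mean of sample medians; (2) glog2 with a per-sample
soft-zero constant c set to the 5th percentile of that sample's positive
scaled intensities. The transform is strictly monotone, finite at zero
(log2(c/2)), and within 0.02 of log2(v) once v ≥ 100·c. Exact equivalence
to ML-calibrated VSN is not claimed.

Because the ratio statistic is a per-sample *difference* of glog values,
any additive per-sample offset — global loading differences, residual
normalization error — cancels row-wise. This self-normalization is
asserted exactly in the tests.

## The ratio statistic and moderated testing

For pair (a, b), r_s = glog2(a_s) − glog2(b_s) per sample s. Pairs are
canonically oriented (accession_a lexicographically smaller), making signs
deterministic; swapping orientation negates logFC and t and leaves p and
MIF unchanged.

Each ratio row (or protein row, for single-protein differential
expression) is fit by OLS against a main-effects design matrix built from
an R-style formula (`~ condition`, `~ treatment + age + block`), treatment
coding with the first-appearing level as reference. Rows with missing
entries are fit per missingness pattern on their complete samples; rows
whose reduced design loses full rank or residual df are flagged untestable.

Variance moderation follows the standard empirical-Bayes moment approach:
assuming σ²_g ~ scaled-inv-χ²(d₀, s₀²), the observed s²_g are scaled F,
and with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),

    ψ′(d₀/2) = var(e) − mean ψ′(d/2),   s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)),

with the trigamma inverted by monotone Newton iteration (start 1/x,
tolerance 1e-8, ≤50 iterations; non-convergence → d₀ = ∞). Posterior
variances (d₀s₀² + d·s²)/(d₀ + d) yield moderated t on d₀ + d df (normal
reference when d₀ = ∞). With d₀ forced to 0 the pipeline reduces exactly
to ordinary row-wise t-tests — asserted to 1e-10 — and the full pipeline
matches limma 3.58.1 `lmFit`/`eBayes` to 1e-10 on a frozen reference
matrix (tests/data/limma_ebayes_reference.tsv, synthetic input). Fewer
than 20 rows with positive variance triggers an unmoderated fallback with
a warning. Robust prior estimation (outlier-variance down-weighting) is
not implemented.

Multiple testing uses Benjamini–Hochberg step-up adjustment. Ratios
sharing a protein (A/B and A/C) are not independent; as in the source
workflow this is handled by the stricter 1% FDR for primary contrasts
rather than a dependence-adjusted procedure. All p-values are two-sided;
directional screens filter on sign downstream.

**Minor isoform fraction.** MIF = mean over samples of min(a,b)/(a+b) on
raw abundances, pooled across conditions by default (a per-condition
minimum is available). Pairs with MIF < 0.05 are excluded from the
significant set: when one member is present only at trace levels, its
ratio is noise-dominated and a large logFC is not biologically meaningful.

Significance: adjusted p < 0.01 AND |logFC| ≥ 0.5 AND MIF ≥ 0.05, each
failure recorded as a reason code. Disease-reversal screens use adjusted
p ≤ 0.1 with no fold-change magnitude requirement, retaining pairs whose
disease shift is co-directional with the developmental shift; the
amplitude ratio |logFC_disease|/|logFC_development| quantifies how partial
the reversal is.

## Pairing and ancestry

Paralog pairs come from a homology table (gene pairs with reciprocal
percent identities, paralog type, last-common-ancestor taxon). The filter
keeps pairs with mean reciprocal identity ≥ 50% (inclusive) whose genes
both map to quantified accessions; groups are connected components of the
retained-pair graph, and all n(n−1)/2 within-group pairs are enumerated.
Spliceoform pairs are built from UniProt accession conventions: all
quantified isoforms of one base accession are paired. A group may mix
paralog and spliceoform relations; pair type is per pair.

Ancestry classification is taxon-label based: a last-common-ancestor
clade at or deeper than Bilateria (including Opisthokonta, Metazoa,
Eukaryota) marks the family ancient, any other known label recent,
missing labels unclassified. Both this classification and the
paralog-type column are available as 2×2 schemes for enrichment tests.

Fisher's exact test is implemented by hypergeometric enumeration with
probability-mass ordering of the two-sided tail (ties included with a
relative tolerance of 1e-7, the convention of the common exact-test
implementations); it agrees with exact integer enumeration for all tables
with total ≤ 40 to 1e-12 and with scipy's implementation on random
tables. The reported odds ratio is the sample (cross-product) estimate.
The identity-vs-usage comparison uses Welch's t-test by default
(pooled-variance optional).

## Synthetic data

The generator emulates exactly the features the estimator and test are
sensitive to:

* **Copy numbers** log-uniform such that the inner 99% of the
  distribution spans the configured orders of magnitude (default 5,
  starting at 100 copies).
* **Groups**: members split a shared group total by per-condition
  proportions (Dirichlet base with a visibility floor, default minor
  proportion ≥ 0.125); a "shift" adds ±shift_glog2 to member 1's log2
  odds in the second condition, so the true pair logFC is ±shift_glog2.
* **Sequences** are concatenations of unique synthetic tryptic peptides
  (length 7–30, terminal K/R, internal KP motifs injected at rate 0.1),
  so the theoretical peptide count equals the number of peptides emitted
  and iBAQ recovers copy numbers exactly in the noiseless limit.
* **Noise**: unit-mean lognormal factors (configurable CV, default 0.2)
  on each PSM's MS1 response and independently on each reporter channel.
* **Interference**: reporters measure a + f·m̄ where m̄ is the channel
  mean over the whole proteome and f the co-isolation fraction; this
  reproduces ratio compression toward 1:1, monotone in f.
* **Missingness** is applied MAR at the protein × sample level after
  quantification, matching the complete-case filter's assumptions.

The standard benchmark — 1500 background proteins, 200 two-member groups
(100 null, 100 shifted by 1.0 glog2 unit), 5+5 samples in one 10-plex,
CV 0.2, no interference, no missingness, seed 17 — yields sensitivity
0.93 at the default thresholds with observed FDR 0 and |logFC bias| < 0.02.

What the simulator does *not* model: chromatographic variation, isotope
envelopes and impurity matrices, peptide-specific ionization efficiency,
search-engine identification errors, batch structure across plexes, and
correlated (non-MAR) missingness tied to abundance. Passing the benchmark
therefore demonstrates the correctness of the estimator/test chain under
its own assumptions, not robustness to every artifact of real acquisitions.

## Numerical notes and limitations

* Problem sizes in the test bench (hundreds to a few thousand proteins,
  ≤10 seeds) are chosen so the whole suite runs in about a minute while
  keeping binomial error bars on rates well inside the asserted margins.
* Moderated p-values with d₀ = ∞ use the normal reference; posterior
  variances always lie between the sample and prior variances.
* glog compresses ratios of proteins whose abundance approaches the
  soft-zero constant (the bottom few percent of the intensity range); on
  the benchmark this appears as a small negative bias of high-magnitude
  logFC estimates. It is the price of finite, stable values at zero.
* Ratio compression from co-isolation is simulated but not corrected;
  measured logFCs under interference underestimate true shifts, which is
  a known property of MS2-multiplexed quantification.
* The pair canonical ordering (lexicographic) is arbitrary but total;
  biological orientation (e.g. reporting the fetal-enriched member first)
  is presentation-layer and both accessions are always carried in output.
* The 545→520-style reduction from enumerable to testable pairs depends
  on the completeness rule; complete-case is the default and the most
  conservative choice under MAR missingness.
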