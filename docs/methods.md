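# Methods

`thermosig` implements a two-stage biomarker pipeline for chronic thermal
stress in salmonid gill tissue: (1) consensus discovery of responsive
microarray probes across multi-year expression datasets, and (2) qPCR
validation statistics for a candidate panel. This note records the models,
the defaults and why, the numerical choices, and what the synthetic data
do and do not establish.

## Discovery: moderated differential expression

Each probe g in a dataset is fit with a one-way linear model on log2
intensities; the contrast of interest is warm − cool (moderate-temperature
samples are excluded from the discovery contrast by default). The fit
yields the contrast estimate (log2 fold change), its unscaled standard
error, the pooled residual variance s²_g and residual df d_g
(= n − #groups).

Variances are shrunk by empirical Bayes under the scaled inverse
chi-square prior: marginally s²_g ~ s0²·F(d_g, d0). Hyperparameters are
estimated by moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
whose mean and excess variance identify log s0² and ψ′(d0/2) through the
digamma/trigamma relations of the log scaled-F law. The trigamma equation
is inverted by Newton iteration; when the empirical spread of log s²_g
does not exceed the spread implied by finite d_g alone, d0 is declared
infinite. The degenerate input where every s²_g is identical returns
d0 = ∞ with s0² equal to that shared value.

The moderated t uses s²_post = (d0·s0² + d_g·s²_g)/(d0 + d_g) on
d0 + d_g df (normal reference when d0 = ∞). Limits: d0 = 0 reproduces
the ordinary pooled two-sample t; d0 = ∞ pins s²_post at s0². A probe
with zero posterior variance and zero contrast gets p = 1; with a
nonzero contrast it is flagged degenerate with p = 0.

**Robust estimation.** "Robust" here means robust hyperparameter
estimation, not robust regression: e_g is winsorized at the (0.05, 0.10)
tails before moment matching, with the winsorized spread rescaled by the
variance-deflation factor of a winsorized normal (computed by numerical
integration), and probes beyond the upper winsor limit receive a reduced
per-probe prior df — the largest d0 consistent with that probe's own
excess spread — so variance outliers are shrunk less aggressively and
cannot inflate the shared prior. The suite cross-checks the non-robust
estimator and moderated t/p against Bioconductor limma on a small fixture.

**FDR.** Benjamini–Hochberg q-values are computed by the literal step-up
definition (reverse cumulative minimum over sorted p), with ties broken
by a stable sort on (p, probe ID); NaN p-values propagate with a warning.
Signatures are thresholded at q < 0.01 by default, recording per-probe
fold-change direction and provenance.

## Discovery: unsupervised feature selection

* **PCA** is a plain SVD of probe-centered data, used for projection and
  separation checks.
* **Sparse PCA** uses truncated power iteration: at every step the
  loading vector is hard-thresholded to its top-k absolute entries and
  renormalised; initialisation is the leading left singular vector of the
  (deflated) residual, so the procedure is deterministic. After
  convergence the rank-1 fit is deflated. Each dimension reports exactly
  min(k, n_probes) probes (k = 100 by default, matching the discovery
  design of one hundred identifiers per dimension); if thresholding
  leaves fewer nonzero entries, the support is padded with the
  next-largest dense loadings.
* **Gene shaving** repeatedly removes the floor(α·|S|) genes (at least
  one) with the smallest |inner product| with the leading principal
  component of the current set (α = 0.10 default). Cluster quality is
  R²(S) = Var(cluster mean profile) / mean(member total variance).
  Members are oriented by the sign of their alignment with the leading
  component before the mean is formed — anti-correlated genes belong to
  the same cluster, and without orientation up- and down-regulated
  members cancel. The null curve averages B = 20 full shaving runs on
  data permuted independently within each gene row (destroying inter-gene
  correlation, preserving marginals); the selected size maximises the gap
  R² − R²_null. Subsequent clusters are found on residuals after
  regressing every gene on the selected cluster mean. A seed is
  mandatory.

In the orchestrated discovery stage, the default exploratory method is
sparse PCA with **separation-selected components**: components whose
scores separate the temperature groups at |Welch t| ≥ 2 are unioned
(falling back to the single best). This automates the study-style manual
choice of "the dimensions showing the strongest separation" and, because
deflation removes each component's support before the next is extracted,
successive components sweep up successive blocks of signal probes without
a hard cardinality ceiling on the union. Gene shaving can be selected per
dataset in the config.

## Consensus and candidate ranking

Per-dataset signatures are intersected; a probe is concordant when its
fold-change direction is identical and nonzero in every signature.
Discordant probes are retained in the intersection but flagged (a switch
drops them). Unions keep directions only where unanimous. Cross-platform
overlaps are counted in the target platform's ID space after applying the
(many-to-many) mapping table, with unmapped sources reported separately.

Candidates are ranked by sequential criteria: tier 1 = in the
intersection AND in the designated published signature AND in ≥ 2 of the
3 per-year unsupervised signatures; tier 2 = platform support; tier 3 =
cross-study robustness (both supplied as per-probe input flags — they
summarise external studies the pipeline does not recompute); sequence
availability is a final gate on selection, not on tier.

## Validation: qPCR statistics

Amplification efficiency comes from OLS of Ct on log10(relative
concentration): E = 10^(−1/slope) − 1 (identical to the dilution-axis
convention E = 10^(1/slope′) − 1 with slope′ = −slope, which the suite
asserts). Assays pass at E ∈ [0.8, 1.1]; E ∈ [0.65, 1.5] is the wider
reporting range, and both flags are exposed because published assay
tables retain some out-of-band efficiencies.

Relative expression is 2^−ΔΔCt: the reference aggregate is the
arithmetic mean Ct of the housekeeping genes per sample (the geometric
mean of linear quantities); ΔΔCt subtracts the control-group mean ΔCt per
gene, so the control group centers at ΔΔCt = 0 by construction.
"No-amplification" Ct entries are treated as missing, never imputed at a
ceiling cycle.

Group comparisons run on log2 relative expression: Bartlett homogeneity,
per-group one-sample KS against a normal with estimated parameters (plus
a Lilliefors-corrected p, since naive KS with estimated parameters is
anticonservative), one-way ANOVA from explicit sums of squares (with
scipy cross-checks), Tukey HSD for all pairs, stars at 0.05/0.01/0.001,
and a headline call at P < 0.01. Panel validation requires significance
with a consistent direction in every required stratum
(survivor/moribund) of every cohort; partial hits are reported as
survivor-only / moribund-only.

## Synthetic data: what it emulates and what it does not

The generator emulates a multi-year two-species holding design: 3 annual
datasets, 2 temperature groups of 10 samples each, 3000 probes with
150 up- and 150 down-regulated planted probes, |log2FC| ~ Uniform(1, 3)
with shared signs across years ("strong effects", concordant by
construction) and per-year magnitude multipliers (1.0, 0.75, 1.25)
reflecting year-to-year effect-size variation. Gene-wise residual
variances follow the scaled inverse chi-square law with d0 = 4,
s0² = 0.05 — exactly the prior the discovery stage assumes — and 5% of
samples have their noise sd inflated 3× to exercise the robust path.
Noise is Gaussian on the log2 scale.

The qPCR generators produce standard curves
Ct = c0 − log10(conc)/log10(1+E) with the 1/5…1/625 five-step dilution
design, Ct noise sd 0.15 by default, three unresponsive reference genes
and planted per-gene fold changes.

What passing these tests does **not** show about real data: the
generator's noise matches the model's assumptions by design, so recovery
results certify correctness of the machinery, not robustness to
normalisation artifacts, probe cross-hybridisation, dye or spatial
effects, batch structure, or non-Gaussian heavy tails beyond the
variance-inflation outlier mechanism. Matrices are assumed already
normalised on the log2 scale; no preprocessing is implemented.

## Problem sizes and numerical choices

Test and acceptance runs use these sizes, chosen as the smallest designs
at which the statistical contracts are informative: 5000 probes / 10 df
for hyperparameter recovery; 50 seeds × 800 probes for null FDR
calibration; 20 seeds of the full default study for planted-panel
recovery; 200 genes × 20 samples for the planted shaving block; shared
small-study fixtures at 400 probes elsewhere. Identifier comparison is
case-sensitive with whitespace trimming; missing values are the explicit
sentinel "NA" in files and NaN in memory, and stages that cannot handle
them refuse rather than dropping rows silently (the DE fit alone uses
per-probe listwise deletion with the effective n recorded).

## Known limitations

Single grouping factor only (no blocking/duplicate-correlation
modelling); the supervised gene-shaving variant is not implemented; the
literature/robustness support columns are inputs, not computed; GEO
series-matrix files are read but never fetched; reproduction of any
specific published probe counts additionally depends on the upstream
normalisation of the deposited data, which is outside this package's
scope.
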