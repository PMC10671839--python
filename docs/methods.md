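# Methods

## Scope and model

`prgscreen` implements a vote-counting screen for drug-resistance genes
across several independently generated sensitive/resistant expression
cohorts, followed by patient-side survival analysis, synergy-gene discovery
around an anchor gene, interaction-network core filtering, and quantitative
assay analytics (4PL dose–response, resistance index, 2^−ΔΔCt, ANOVA).

The screen's statistical core is the moderated t-statistic. Within one
cohort pair with arms of size n₁ (resistant) and n₂ (sensitive), the
gene-wise pooled variance s²_g is modelled as

    s²_g | σ²_g ~ σ²_g · χ²(d_g)/d_g,      d_g = n₁ + n₂ − 2,
    σ²_g ~ s₀² d₀ / χ²(d₀)                  (scaled inverse chi-square prior),

which implies E[log s²] = log s₀² + ψ(d_g/2) − log(d_g/2) − ψ(d₀/2) +
log(d₀/2) and Var[log s²] = ψ′(d_g/2) + ψ′(d₀/2). The prior is estimated by
inverting these two moment equations (ψ = digamma, ψ′ = trigamma; the
trigamma inverse uses Newton iteration on an asymptotic start). When the
observed spread of log s² does not exceed pure chi-square sampling noise the
variance estimate carries no gene-level information: d₀ = ∞ and every gene
shares s₀² = mean(s²). The moderated statistic is

    t_g = logFC_g / ( s̃_g · √(1/n₁ + 1/n₂) ),
    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),

with two-sided p-values from t on d₀ + d_g df (standard normal when
d₀ = ∞). Cohorts whose arms are both singletons have no within-group
variance at all; such genes fall back to the full-shrinkage limit (variance
s₀², df d₀), an approximation the user should be aware of when feeding
single-replicate series. The implementation agrees with the Bioconductor
reference empirical-Bayes implementation to ~1e-15 on shared inputs (see
`tests/test_diffexpr.py`), which is used purely as a cross-check oracle.

## Screen rules and their assumptions

A gene is a candidate when it carries an up-flag (logFC ≥ `up_lfc` = 1 and
p ≤ `up_p` = 0.05, both inclusive) in at least `min_support` = 3 cohorts and
its observed logFC stays ≥ `floor_lfc` = −0.2 in every measured cohort
without an up-flag. PRGs are candidates with support strictly greater than
`min_support`; ties in ranking break lexicographically for reproducibility.
No multiple-testing adjustment is applied inside the screen — the
cross-cohort vote plus the floor is the error control, matching the
screening convention this design follows; Benjamini–Hochberg can be applied
downstream by the user if desired.

Two behaviours deserve emphasis:

- **The floor rule is noise-sensitive.** It thresholds the *observed*
  logFC, so for a truly null cohort the violation probability is
  Φ(−0.2 / (σ√(1/n₁+1/n₂))) per cohort, where σ is the within-arm residual
  sd. At triplicate arms this is negligible for σ ≈ 0.1 (technical-replicate
  noise on isogenic pairs, the default of the panel generator) but reaches
  ~16% per cohort at σ = 0.25. On noisy biological replicates the floor
  rejects genuinely supported genes; raising `floor_lfc` toward −0.5 or
  pre-filtering by a confidence interval would be the remedy.
- **Quantile normalization needs genome scale.** Forcing every sample onto
  the mean sorted profile is near-lossless when differential genes are a
  small fraction of rows; on matrices of a few dozen genes it visibly
  compresses planted effects. The package normalizes per cohort-pair
  dataset only — never across datasets — since cross-platform joint
  normalization would contradict the per-cohort analyses.
- Genes measured on only some platforms vote over measured cohorts only and
  must be measured in at least half the cohorts to be eligible.

## Patient-side statistics

Kaplan–Meier, the two-group log-rank test, Pearson correlation and
univariate least squares are implemented directly from their defining
formulas; `lifelines`, `scipy` and `numpy.linalg` serve as independent
oracles in the tests. Conventions: patients exactly at the median anchor
expression join the *low* group; at tied times deaths are processed before
censorings (censored subjects remain at risk for a death at their own
time); the log-rank variance is the hypergeometric form summed over distinct
death times, with χ² referred to 1 df. Survival time is taken in days as
provided. No Cox model is fitted: the pipeline reports only the
nonparametric contrast.

## Synergy and network stage

The co-upregulation step reuses the moderated-t machinery with the
median-split groups playing the two arms (high-anchor = "resistant") at
thresholds logFC ≥ 0.6, p ≤ 0.05. Set operations uppercase and strip gene
symbols but perform no alias resolution; GMT files are the interchange
format. Interaction filtering requires a *direct* edge to the anchor with
score strictly greater than 0.7 (STRING's 0–1000 integer scale is
auto-detected and rescaled); multi-hop connectivity deliberately does not
count. The anchor is included in the reported core; LRG selection
(intersection with the packaged, user-editable literature list of nine
lipid-metabolism enzymes) removes it.

## Assay analytics

The 4PL viability model is parameterized with hill > 0 and decreasing
response; IC50 is the concentration at the asymptote midpoint (relative
IC50). Fitting is bounded least squares (bottom ≥ 0, top ≤ 120% of the
observed maximum, hill ∈ (0.1, 10]) multi-started from seven log-spaced
IC50 seeds; the best residual sum of squares wins. Zero-dose wells anchor
the top asymptote by remapping x = 0 to 10⁻³ × (smallest nonzero dose).
Monotone non-decreasing dose–response data are rejected rather than fitted.
At the default simulated plate design (8 doses × 3 replicates, OD noise
sd 3) the IC50 sampling error is ~6% (median), so single-plate estimates
should be read with that precision in mind. ANOVA delegates the F/p
computation to `scipy.stats.f_oneway` with explicit degenerate-input
handling (all-constant groups → F = 0, p = 1, flagged).

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their spec (single seeded numpy
`Generator`, no global state; identical seeds give identical bytes).

- **Cell-line panels** (default 7 cohort pairs × 3 replicates per arm,
  1000 genes): gene baselines ~ N(8, 2) on log2 scale, cohort batch shifts
  ~ N(0, 0.5), per-sample array offsets ~ N(0, 0.3) (what quantile
  normalization removes), within-arm noise sd 0.1, planted effects added to
  the resistant arms of chosen cohorts.
- **Patient cohorts** (default n = 368, matching a curated ovarian-cancer
  registry cut): anchor-correlated genes built as r·z_anchor + √(1−r²)·ε;
  survival exponential with hazard h₀·exp(β·z) per driver gene
  (h₀ = 1/1000 days); independent exponential censoring whose rate is
  solved numerically so the expected censored fraction hits the target
  (default 40%).
- **Interaction tables**: anchor–partner scores ~ U(0.75, 0.99), decoys
  ~ U(0.10, 0.69).
- **The reference fixture** wires these together deterministically: 19
  planted candidates (one in all 7 cohorts, two in 4, sixteen in rotating
  3-subsets; within-arm sd 0.05 so significance is certain), decoys
  exercising the floor, support and effect-size rejection rules, a patient
  cohort whose 18 planted partners track CPT1A at r = 0.9, gene sets and
  edges yielding a 19-node core, and viability curves planted at IC50s
  1574 / 299.7 nM.

Not emulated: platform-specific probe effects, RNA-seq count distributions
(negative binomial), real TCGA expression marginals, informative censoring,
or gene–gene correlation beyond the anchor structure. Passing tests
therefore demonstrate the *algorithmic* correctness and calibration of the
pipeline under its stated model, not robustness to every pathology of real
GEO/TCGA data.

## Problem sizes used in the test suite

Simulation-based tests use 1000-gene panels (100 seeds) for screen
operating characteristics, 2000 genes × 200 replicates for null
calibration, 5000 genes for variance-prior recovery, n = 368 × 200 seeds
for log-rank power, and 5000 label permutations for the log-rank reference
p-value — sizes at which the Monte-Carlo error of each check is comfortably
below the asserted tolerance.

## Known limitations

- The floor rule's noise sensitivity (above) is inherent to thresholding
  observed fold changes.
- "Support" weighs all cohorts equally regardless of replicate number or
  platform quality.
- The moderated-t model assumes equal within-group variances (no Welch
  option) and no mean–variance trend.
- The patient stage's median split discards within-group expression
  information; no optimal-cutpoint scanning is provided by design.
- Relative IC50 is reported; absolute EC50 (response = 50% of control)
  differs when bottom is far from zero.
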