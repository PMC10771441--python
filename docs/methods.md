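# Methods

`hltme` re-implements, as a tested library, a transcriptional analysis of the
classic Hodgkin lymphoma (cHL) tumor microenvironment: per-patient gene-set
enrichment of immune and stromal signatures from targeted expression panels,
signature-based cell-type deconvolution, outcome-group statistics gated on
normality, progression-free-survival (PFS) analysis, and a composite
prognostic score transferred frozen from a discovery to a validation cohort.
This note records the models, the parameters that matter, and the design
choices made where more than one defensible option existed.

## Single-sample enrichment (ssGSEA)

For one sample, expression values are replaced by average ranks
`r_1..r_n` (ties averaged). Genes are walked in decreasing-rank order and the
raw enrichment score of a set S is the summed difference of two empirical
CDFs — the weighted ECDF of the members and the unweighted ECDF of the
remaining genes:

    ES(S) = Σ_i [ P_in(i) − P_out(i) ],
    P_in(i)  = Σ_{j∈S, pos_j≤i} r_j^α / Σ_{j∈S} r_j^α,
    P_out(i) = #{j∉S : pos_j≤i} / (n − |S|).

The implementation uses the algebraically identical closed form
`ES = Σ_{j∈S} w_j t_j / W − Σ_{j∉S} t_j / (n−|S|)` with `t_j` the bottom-up
position of gene j in the decreasing-rank order, which makes the empirical
null cheap (O(R·|S|) after one sort). A literal O(n²) double-loop
implementation is retained as the independent oracle; the test suite holds
the two equal to 1e-12 over a thousand random instances.

**Normalization.** R random gene sets of the same effective size are drawn
from the panel and the normalized score is the z-score
`NES = (ES − mean_null) / sd_null`; the two-sided empirical p-value uses the
add-one rule `(1 + #{|null| ≥ |ES|}) / (R+1)`, flooring at `1/(R+1)`. A
negative NES therefore reads as weaker relative activity than a random set of
the same size, which is how enrichment directions are interpreted throughout.
A ratio-to-mean alternative (`nes_mode="ratio"`) exists for sensitivity
analysis. The null generator is seeded from `(seed, crc32(rank vector))`, so
a sample's scores depend only on its own profile: they are invariant to
cohort composition and identical for identical expression columns.

**Parameters.** `weight_exponent` α = 0.25 (the canonical single-sample
choice; α = 0 gives the unweighted Kolmogorov–Smirnov-like sum), `n_null`
R = 1000 (p-value floor ≈ 0.001), `min_set_size` = 3 (smaller sets are
skipped with a warning). Equal-size sets within a sample share one null
draw, which cuts the null cost roughly tenfold on the packaged catalog. Ties
in expression are broken by stable input gene order.

## Deconvolution

Cell-type proportions are estimated per sample by nonnegative least squares
against a genes × K signature matrix: minimize ‖S f − x‖₂ subject to f ≥ 0,
then renormalize f to the unit simplex. NNLS is convex, deterministic and
dependency-light; the solver backend is an injectable callable so a
support-vector variant can be slotted in. Diagnostics per sample: residual
RMSE, Pearson r between fitted and observed signature-gene expression, and a
degeneracy flag (an all-zero solution falls back to uniform fractions).
Renormalization makes fractions invariant to any positive scaling of the
input, so library-size differences are harmless.

Signature genes default to those whose value in some cell type is at least
2× the median of the *other* types. The leave-one-out median (rather than
the all-type median) keeps the rule meaningful at small K: with two cell
types an all-type median lies midway between the two values and no finite
fold threshold can fire. Flat genes (housekeeping, filler) carry no mixture
information and are excluded. No batch correction between mixture and
signature is attempted, and no permutation p-value for goodness of fit is
computed; the residual diagnostics serve that role.

## Outcome-group statistics

Outcome labels follow the two-year rule: favorable (F) iff PFS > 24 months,
else unfavorable (U). Every variable (gene, enrichment score, cell fraction)
is compared F vs U through a Shapiro–Wilk gate applied per group at
α = 0.05: both groups normal → unpaired Student t-test (pooled variance;
Welch via config); otherwise Kruskal–Wallis across the two groups. The gate
is per group, not pooled, because a mixture of two normals with different
means fails a pooled normality test even when both arms are normal.
Kruskal–Wallis with k = 2 is equivalent to a Mann–Whitney test up to tie
handling and is retained in that form for fidelity with the published
analysis convention. Raw p-values are reported; Benjamini–Hochberg
adjustment can be appended but never alters them. A constant group makes the
normality test undefined and routes to Kruskal–Wallis with a warning.

## Survival

PFS in months is the endpoint everywhere. Kaplan–Meier estimation and the
k-group log-rank test delegate to `lifelines`. The univariate Cox
proportional-hazards fit is implemented in-package as a Newton–Raphson
maximizer of the partial likelihood with **Breslow** tie handling by default
(Efron via flag): Breslow keeps the exact identity between the log-rank
statistic and the Cox score test at β = 0 available as a cross-check, which
the tests verify to 1e-8 on tie-free data, alongside agreement with
`lifelines.CoxPHFitter`. Convergence is declared when the score magnitude
drops below 1e-8 (max 50 iterations); a standardized |β̂| > 8 or a huge
standard error marks a monotone partial likelihood (complete separation) and
is reported as non-convergence rather than a spurious estimate.

Quantile splits (median/tertiles/quartiles) use the linear-interpolation
quantile definition with values exactly at a cutoff assigned to the lower
group — at n = 25 the group sizes genuinely depend on this convention, so it
is fixed and documented. "High vs low" figures for tertiles compare top vs
bottom group; dropping the middle tertile is an explicit flag
(`tertiles-extremes` semantics) rather than a silent default.

## Prognostic model

The composite score combines 31 enrichment variables (13 cell populations +
18 signaling pathways, all oriented adverse): each component is centered by
its cohort median, and a patient's score is the mean of the centered
components. Of the readings compatible with "median per component, mean per
patient", this is the one in which both statistics act on well-defined axes
and produce a per-patient scalar; per-patient-median-then-cohort-mean does
not. Median centering makes the score invariant to per-component constant
shifts and robust to the non-normality that motivates the gate above. No
per-variable weights are used; a descriptive importance ranking via
univariate Cox Wald statistics can be produced but is clearly a stand-in,
not part of the score.

The cutpoint between high- and low-risk is chosen on the ROC curve
(unfavorable = positive class, score > cutpoint = positive call) by
maximizing Youden's J over midpoints between adjacent sorted unique scores,
ties broken toward the lower cutpoint; accuracy maximization is available by
flag. A score exactly at the cutpoint classifies low-risk. Cross-cohort
evaluation freezes the training medians and cutpoint and applies them to the
validation cohort without refitting — scoring never sees validation labels,
so evaluation is leakage-free by construction. Re-centering within the
validation cohort is available by flag but is not the default.

## Synthetic cohorts

The generator emulates a targeted immune-profiling panel of 800 genes:
13 cell types × 10 marker genes, 40 housekeeping genes, 22 pathway blocks of
12 genes, and unstructured filler. Markers take `baseline × marker_fold`
(30 × 8 counts) in their own type and baseline elsewhere; housekeeping and
filler are flat across types with log-normal per-gene levels. Per-sample
compositions are Dirichlet draws (all-ones concentration by default);
unfavorable samples have the concentrations of the adverse populations
(M2-like macrophages, myeloid and plasmacytoid dendritic cells, MDSC,
stromal cells) multiplied by `adverse_shift` = 2, and the 18 adverse pathway
blocks multiplied by `pathway_fold` = 1.3 in expectation. Counts are
negative binomial around `signature @ fractions` with one shared dispersion
φ = 0.1 (variance μ + φμ²; φ → 0 recovers Poisson) and a log-normal library
factor (σ = 0.15). Under these defaults the planted per-variable
standardized enrichment difference between U and F averages ≈ 0.9 SD —
a deliberately moderate effect so that classifier transfer, not separability
by any single variable, is what the model evaluation demonstrates.

Survival is simulated label-first by default: group sizes are fixed by
design (discovery preset 11 F / 14 U, i.e. 56% unfavorable; scaled
discovery 44/56; validation 75 F / 28 U — the validation series' label
proportion is not published, and ~27% early-treatment-failure is a realistic
first-line cHL rate), U patients draw an exponential time with rate
`λ0·exp(β·score)` truncated to the 24-month window (event = 1), F patients
add an exponential tail beyond it, censored at a 120-month horizon. Defaults
λ0 = 0.08 events/month and β = 0.5 per SD of the planted adverse-burden
score. Label-first makes the preset group counts exact and the two-year rule
self-consistent; a hazard-first mode (times first, labels derived by the
rule) is kept behind `survival_mode`.

**What the generator does not emulate:** probe-level chemistry and QC
attrition, per-gene dispersions, correlated marker programs across cell
types, spatial structure, batch effects between cohorts, and real biological
overlap between gene sets. Passing tests therefore demonstrate correctness
and calibration of the *methods* under a controlled generative model, not
clinical performance on real cohorts.

## Numerical choices and degenerate inputs

- All randomness flows from integer seeds through `numpy` Generators with
  fixed derivation paths; equal seeds give byte-identical artifacts.
- Geometric means in housekeeping normalization add +1 to zero counts
  (logged); normalization is idempotent to 1e-9.
- Constant expression vectors, whole-panel gene sets, single-class label
  vectors, constant covariates and all-equal split variables raise errors
  rather than returning conventional values.
- Duplicate gene rows on input collapse by per-sample max, with a warning.
- Fraction columns are validated to the simplex within 1e-6; enrichment
  p-values to [1/(R+1), 1].

## Problem sizes

The shipped verification suite uses panels up to 200 genes and sets up to
30 genes for oracle comparisons (1,000 instances), 2,000 replicates at
R = 1000 for p-value calibration, 500 replicates for noisy-mixture recovery,
200 replicates of n = 500 for Cox recovery, and the 100/103-sample
discovery/validation pair for model transfer. These sizes hold Monte-Carlo
error comfortably below the tolerances asserted while keeping a full run in
the tens of seconds on one core.

## Known limitations

- The packaged 89-entry cell-population catalog and the 31-variable model
  list are synthetic stand-ins with the documented structure and the six
  named constituents (ROBO, VEGF, DAP12 pathways; M2-like macrophages,
  myeloid dendritic cells, stromal cells); real analyses must supply their
  own GMT and variable list.
- NNLS is a deliberate simplification of ν-SVR-based deconvolution; it
  shares the signature-restricted linear-mixture assumption but not the
  support-vector robustness properties.
- The Cox screen is univariate only; no proportionality diagnostics,
  multivariable models or competing risks.
- Housekeeping geometric-mean normalization stands in for the vendor's
  positive-control + content normalization; control probes are not modeled.
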