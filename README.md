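# hltme

Transcriptional tumor-microenvironment (TME) analysis for classic Hodgkin
lymphoma (cHL). In cHL the tumor mass is dominated by reactive immune and
stromal cells rather than the malignant Hodgkin/Reed–Sternberg clone, and
the composition of that microenvironment carries prognostic information.
`hltme` provides the full analysis chain for targeted expression panels
(NanoString-style, ~800 genes) profiled from patient biopsies:

- **Single-sample gene-set enrichment (ssGSEA)** — per-patient running-sum
  scores `ES = Σ_i [P_in(i) − P_out(i)]` contrasting the weighted ECDF of a
  gene set's members (weights `rank^α`, α = 0.25) against the ECDF of the
  remaining genes, normalized against an empirical null of random same-size
  sets: `NES = (ES − μ_null)/σ_null`, with add-one empirical p-values.
- **Immune-cell deconvolution** — per-sample cell-type fractions by
  nonnegative least squares against a genes × cell-types signature matrix
  (min ‖S f − x‖₂, f ≥ 0, renormalized to the simplex), with residual
  diagnostics: the per-patient "immune fingerprint".
- **Outcome statistics** — favorable (F, progression-free survival
  > 2 years) vs unfavorable (U) comparison of every variable through a
  Shapiro–Wilk normality gate: t-test when both groups pass, Kruskal–Wallis
  otherwise.
- **Survival analysis** — Kaplan–Meier curves, k-group log-rank tests,
  univariate Cox regression (Breslow ties, Newton–Raphson), and
  median/tertile/quartile dichotomization.
- **Composite prognostic score** — 31 adverse enrichment variables
  (13 cell populations + 18 pathways), each median-centered across the
  cohort and averaged per patient; a ROC cutpoint (Youden's J, U positive)
  splits high- from low-risk, and the medians + cutpoint transfer frozen to
  an independent validation cohort.
- **Synthetic cohorts** — a NanoString-like generator (cell-mixture counts,
  Dirichlet compositions with planted adverse shifts, two-year-rule
  survival) so the entire pipeline is testable without patient data.

See `docs/methods.md` for models, assumptions and parameter rationale.

## Worked example

Run the full synthetic pipeline (discovery preset: 25 patients, 11 F / 14 U,
800-gene panel, 111-set catalog) from the shell:

```bash
hltme run-all --outdir run --seed 0
cat run/report.txt
```

which prints:

```
tumor-microenvironment pipeline report
========================================
group comparison: 111 variables screened, 43 significant at alpha=0.05
  ROBO pathway: p=2.22e-06 (t_test, higher_in_U)
  VEGF pathway: p=6.19e-06 (t_test, higher_in_U)
  TRKA pathway: p=3.02e-05 (t_test, higher_in_U)
  IL7 pathway: p=6.45e-05 (t_test, higher_in_U)
  TCPTP pathway: p=0.000102 (kruskal_wallis, higher_in_U)
deconvolution fingerprint: 13 cell types x 25 samples
  mean fraction Myeloid dendritic cells: 0.116
  mean fraction M2-like macrophages: 0.097
  mean fraction MDSC: 0.095
  mean fraction Plasmacytoid dendritic cells: 0.094
  mean fraction CD8 T central memory: 0.091
survival screen: 111 variables, 29 with log-rank p < 0.05
prognostic model: accuracy 100.0%, sensitivity 100.0%, specificity 100.0% at cutpoint 0.0371 (31 variables)
```

Reading the output: the generator planted adverse effects in U patients —
higher Dirichlet concentration for the adverse cell populations and
upregulated adverse pathway blocks — and the screen recovers exactly those
variables (ROBO/VEGF/TRKA/IL7/TCPTP pathways enriched in U). The
deconvolution stage reports each patient's cell-type composition, the
survival screen flags variables whose tertile split separates the
Kaplan–Meier curves, and the composite score separates F from U patients
cleanly on this cohort. Individual stages are available as subcommands
(`simulate`, `normalize`, `ssgsea`, `deconvolve`, `compare`, `survive`,
`score`, `report`) on files you supply; the same operations are importable
from Python:

```python
from hltme import SimulationConfig, generate_cohort, score_all, EnrichmentParams
from hltme.io import normalize_counts
from hltme.synthetic import default_catalog

cohort = generate_cohort(SimulationConfig(seed=0))
norm = normalize_counts(cohort.expression, list(cohort.housekeeping_genes))
enrichment = score_all(norm, default_catalog(cohort.config), EnrichmentParams(seed=0))
```

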