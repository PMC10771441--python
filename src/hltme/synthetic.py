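"""Synthetic NanoString-like cHL cohorts with planted microenvironment effects.

Generates everything the downstream pipeline consumes — a signature matrix,
per-sample true cell fractions, probe-count expression, and a clinical table
— so the full analysis is testable without external data.

Generative model
----------------
* **Signature.** Each of K cell types expresses its marker genes at
  ``baseline_expression * marker_fold`` and all other types' markers at
  baseline; housekeeping, pathway-block and filler genes are flat across cell
  types (log-normal per-gene levels).
* **Fractions.** Each sample's cell-type composition is a Dirichlet draw;
  unfavorable (U) samples have the concentration of the adverse cell types
  multiplied by ``adverse_shift`` (1 = no planted compositional effect).
* **Expression.** Expected counts are ``signature @ fractions`` scaled by a
  log-normal per-sample library factor; U samples additionally have adverse
  pathway-block genes multiplied by ``pathway_fold``. Counts are negative
  binomial with one shared dispersion (variance ``mu + phi mu^2``).
* **Survival.** Label-first by default: group sizes are fixed by design, U
  patients progress within the two-year window (event = 1, PFS <= 24 months)
  and F patients progress or are censored beyond it, with within-group times
  accelerated by ``exp(beta * planted_score)``. A hazard-first mode (labels
  derived from simulated times by the two-year rule) is available via
  ``survival_mode``.
All randomness flows from one integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as _catalog
from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    FractionMatrix,
    GeneSetCollection,
    SignatureMatrix,
)
from . import io as _io

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "make_signature_matrix",
    "simulate_fractions",
    "simulate_expression",
    "simulate_survival",
    "generate_cohort",
    "default_catalog",
    "discovery_config",
    "discovery_scaled_config",
    "validation_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults emulate the discovery cohort."""

    n_favorable: int = 11
    n_unfavorable: int = 14
    n_celltypes: int = 13
    n_markers_per_type: int = 10
    n_housekeeping: int = 40
    total_genes: int = 800
    celltype_names: tuple[str, ...] | None = None  # default: packaged 13-type list
    marker_fold: float = 8.0
    baseline_expression: float = 30.0
    dirichlet_base: tuple[float, ...] | None = None  # default: all ones
    adverse_types: tuple[str, ...] = _catalog.ADVERSE_CELL_TYPES
    adverse_shift: float = 2.0
    adverse_pathways: tuple[str, ...] = _catalog.MODEL_PATHWAYS
    pathway_fold: float = 1.3
    library_size_logmean: float = 0.0
    library_size_logsd: float = 0.15
    nb_dispersion: float = 0.1
    baseline_hazard: float = 0.08  # events per month
    log_hazard_per_sd: float = 0.5
    censor_horizon_months: float = 120.0
    pfs_threshold_months: float = 24.0
    survival_mode: str = "label_first"  # or "hazard_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_favorable < 0 or self.n_unfavorable < 0 or self.n_favorable + self.n_unfavorable < 1:
            raise ValueError("cohort must contain at least one sample")
        if self.n_markers_per_type * self.n_celltypes + self.n_housekeeping > self.total_genes:
            raise ValueError("markers + housekeeping exceed total_genes")
        for name in ("marker_fold", "baseline_expression", "adverse_shift",
                     "nb_dispersion", "baseline_hazard", "pfs_threshold_months",
                     "censor_horizon_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.celltype_names is not None and len(self.celltype_names) != self.n_celltypes:
            raise ValueError("celltype_names length must equal n_celltypes")
        if self.dirichlet_base is not None:
            if len(self.dirichlet_base) != self.n_celltypes:
                raise ValueError("dirichlet_base length must equal n_celltypes")
            if any(a <= 0 for a in self.dirichlet_base):
                raise ValueError("dirichlet concentrations must be strictly positive")
        if self.survival_mode not in ("label_first", "hazard_first"):
            raise ValueError("survival_mode must be 'label_first' or 'hazard_first'")
        unknown = set(self.adverse_types) - set(self.celltypes)
        if unknown:
            raise ValueError(f"adverse_types not among cell-type names: {sorted(unknown)}")
        if self.censor_horizon_months <= self.pfs_threshold_months:
            raise ValueError("censor_horizon_months must exceed pfs_threshold_months")

    @property
    def celltypes(self) -> tuple[str, ...]:
        if self.celltype_names is not None:
            return self.celltype_names
        if self.n_celltypes <= len(_catalog.CELL_TYPES):
            return _catalog.CELL_TYPES[: self.n_celltypes]
        extra = tuple(f"Cell type {i + 1}" for i in range(len(_catalog.CELL_TYPES), self.n_celltypes))
        return _catalog.CELL_TYPES + extra

    @property
    def dirichlet(self) -> np.ndarray:
        if self.dirichlet_base is not None:
            return np.asarray(self.dirichlet_base, dtype=float)
        return np.ones(self.n_celltypes)

    @property
    def n_samples(self) -> int:
        return self.n_favorable + self.n_unfavorable

    def layout(self) -> _catalog.PanelLayout:
        return _catalog.build_panel_layout(
            self.celltypes, self.n_markers_per_type, self.n_housekeeping, self.total_genes
        )

    def labels(self) -> np.ndarray:
        return np.array(["F"] * self.n_favorable + ["U"] * self.n_unfavorable)

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


def make_signature_matrix(config: SimulationConfig) -> SignatureMatrix:
    """Genes x cell-types reference with the panel's full gene complement.

    Marker genes take ``baseline * marker_fold`` in their own type and
    ``baseline`` elsewhere; housekeeping / pathway / filler genes are flat
    across types with seeded log-normal per-gene levels (housekeeping higher,
    as reference genes are chosen to be well expressed).
    """
    layout = config.layout()
    rng = np.random.default_rng([config.seed, 1])
    celltypes = config.celltypes
    genes = layout.all_genes
    values = pd.DataFrame(
        config.baseline_expression, index=pd.Index(genes, name="gene_id"),
        columns=pd.Index(celltypes), dtype=float,
    )
    for ct in celltypes:
        values.loc[list(layout.markers[ct]), ct] = config.baseline_expression * config.marker_fold
    n_hk = len(layout.housekeeping)
    if n_hk:
        hk_level = config.baseline_expression * 4.0 * rng.lognormal(0.0, 0.3, size=n_hk)
        values.loc[list(layout.housekeeping), :] = hk_level[:, None]
    flat = [g for block in layout.pathway_genes.values() for g in block] + list(layout.filler)
    if flat:
        levels = config.baseline_expression * rng.lognormal(0.0, 0.5, size=len(flat))
        values.loc[flat, :] = levels[:, None]
    return SignatureMatrix(values=values)


def simulate_fractions(config: SimulationConfig, labels: np.ndarray) -> FractionMatrix:
    """Per-sample Dirichlet cell-type compositions with the adverse shift in U."""
    labels = np.asarray(labels)
    if len(labels) != config.n_samples:
        raise ValueError(
            f"labels length {len(labels)} != n_favorable + n_unfavorable = {config.n_samples}"
        )
    celltypes = config.celltypes
    base = config.dirichlet
    shifted = base.copy()
    adverse_mask = np.isin(celltypes, config.adverse_types)
    shifted[adverse_mask] *= config.adverse_shift
    rng = np.random.default_rng([config.seed, 2])
    out = np.empty((config.n_celltypes, len(labels)))
    for j, lab in enumerate(labels):
        alpha = shifted if lab == "U" else base
        out[:, j] = rng.dirichlet(alpha)
    return FractionMatrix(
        fractions=pd.DataFrame(out, index=pd.Index(celltypes, name="celltype_id"),
                               columns=pd.Index(config.sample_ids()[: len(labels)])),
    )


def simulate_expression(
    signature: SignatureMatrix,
    fractions: FractionMatrix,
    config: SimulationConfig,
    multipliers: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Negative-binomial probe counts around ``signature @ fractions``.

    ``multipliers`` (genes x samples, default all ones) scale expected counts
    gene- and sample-wise; the cohort generator uses this to plant pathway
    effects in U samples. Per-sample library factors are log-normal.
    """
    if list(signature.celltype_ids) != list(fractions.celltype_ids):
        raise ValueError("signature cell types do not match fraction rows")
    S = signature.values.to_numpy()
    F = fractions.fractions.to_numpy()
    mean = S @ F
    if multipliers is not None:
        mult = multipliers.reindex(index=signature.values.index,
                                   columns=fractions.fractions.columns).fillna(1.0).to_numpy()
        mean = mean * mult
    rng = np.random.default_rng([config.seed, 3])
    lib = rng.lognormal(config.library_size_logmean, config.library_size_logsd,
                        size=mean.shape[1])
    mean = mean * lib[None, :]
    phi = config.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    return ExpressionMatrix(
        values=pd.DataFrame(counts.astype(float), index=signature.values.index,
                            columns=fractions.fractions.columns),
        scale="raw",
    )


def _standardize(score: np.ndarray) -> np.ndarray:
    score = np.asarray(score, dtype=float)
    if not np.isfinite(score).all():
        raise ValueError("planted scores must be finite")
    sd = score.std()
    return (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)


def simulate_survival(
    labels: np.ndarray, config: SimulationConfig, planted_score: np.ndarray
) -> ClinicalTable:
    """Simulate PFS and events consistent with the two-year outcome rule.

    Label-first mode fixes the F/U group sizes by construction: U patients
    draw an exponential time with rate ``lambda0 * exp(beta*score)`` truncated
    to the two-year window (event = 1); F patients add an exponential tail
    beyond the window, censored at the follow-up horizon. The planted score is
    standardized internally (mean 0, sd 1 across the cohort).
    """
    labels = np.asarray(labels)
    score = _standardize(planted_score)
    if len(labels) != len(score):
        raise ValueError("labels and planted_score must align")
    rng = np.random.default_rng([config.seed, 4])
    rate = config.baseline_hazard * np.exp(config.log_hazard_per_sd * score)
    thr, horizon = config.pfs_threshold_months, config.censor_horizon_months
    u = rng.uniform(size=len(labels))
    time = np.empty(len(labels))
    event = np.empty(len(labels), dtype=int)
    if config.survival_mode == "label_first":
        for i, lab in enumerate(labels):
            if lab == "U":
                # exponential truncated to (0, thr]
                time[i] = -np.log1p(-u[i] * (1.0 - np.exp(-rate[i] * thr))) / rate[i]
                event[i] = 1
            else:
                tail = -np.log(u[i]) / rate[i]
                if thr + tail >= horizon:
                    time[i], event[i] = horizon, 0
                else:
                    time[i], event[i] = thr + tail, 1
        outcome = labels
    else:  # hazard_first
        raw = -np.log(u) / rate
        event = (raw < horizon).astype(int)
        time = np.minimum(raw, horizon)
        outcome = np.where(time > thr, "F", "U")
    return ClinicalTable(table=pd.DataFrame({
        "sample_id": config.sample_ids()[: len(labels)],
        "outcome": outcome,
        "pfs_months": time,
        "event": event,
    }))


@dataclass
class SyntheticCohort:
    """A complete simulated cohort plus the configuration that produced it."""

    expression: ExpressionMatrix
    true_fractions: FractionMatrix
    clinical: ClinicalTable
    signature: SignatureMatrix
    config: SimulationConfig

    def __post_init__(self) -> None:
        ids = self.expression.sample_ids
        if self.true_fractions.sample_ids != ids or self.clinical.sample_ids != ids:
            raise ValueError("sample ids inconsistent across cohort components")

    @property
    def housekeeping_genes(self) -> tuple[str, ...]:
        return self.config.layout().housekeeping

    def write(self, outdir: str | Path, provenance: dict | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_expression(self.expression, outdir / "expression.tsv", provenance=provenance)
        _io.write_fractions(self.true_fractions, outdir / "true_fractions.tsv",
                            provenance=provenance)
        _io.write_signature(self.signature, outdir / "signature.tsv", provenance=provenance)
        _io.write_clinical(self.clinical, outdir / "clinical.csv", provenance=provenance)
        self.config.to_yaml(outdir / "simulation_config.yaml")
        (outdir / "housekeeping.txt").write_text("\n".join(self.housekeeping_genes) + "\n")


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Compose signature, fractions, expression and survival into one cohort.

    The planted per-sample risk score driving survival is the standardized
    total adverse-type fraction, so compositional effect and outcome are
    linked the way the analysis assumes.
    """
    labels = config.labels()
    signature = make_signature_matrix(config)
    fractions = simulate_fractions(config, labels)
    layout = config.layout()
    multipliers = None
    adverse_genes = [g for pw in config.adverse_pathways
                     for g in layout.pathway_genes.get(pw, ())]
    if adverse_genes and config.pathway_fold != 1.0:
        mult = pd.DataFrame(1.0, index=signature.values.index,
                            columns=fractions.fractions.columns)
        u_cols = [s for s, lab in zip(mult.columns, labels) if lab == "U"]
        mult.loc[adverse_genes, u_cols] = config.pathway_fold
        multipliers = mult
    expression = simulate_expression(signature, fractions, config, multipliers)
    adverse_mask = np.isin(config.celltypes, config.adverse_types)
    burden = fractions.fractions.to_numpy()[adverse_mask].sum(axis=0)
    clinical = simulate_survival(labels, config, burden)
    return SyntheticCohort(expression=expression, true_fractions=fractions,
                           clinical=clinical, signature=signature, config=config)


def default_catalog(config: SimulationConfig) -> GeneSetCollection:
    """The packaged gene-set catalog instantiated over this configuration's panel."""
    return _catalog.build_catalog(config.layout(), seed=config.seed)


def discovery_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Discovery-scale preset: 25 samples, 11 F / 14 U (56% unfavorable)."""
    return SimulationConfig(n_favorable=11, n_unfavorable=14, seed=seed, **overrides)


def discovery_scaled_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Discovery preset scaled to 100 samples with the 56% U proportion preserved."""
    return SimulationConfig(n_favorable=44, n_unfavorable=56, seed=seed, **overrides)


def validation_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Validation-scale preset: 103 samples with a realistic ~27% U proportion."""
    return SimulationConfig(n_favorable=75, n_unfavorable=28, seed=seed, **overrides)
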