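"""Composite immune/stromal prognostic score with ROC cutpoint classification.

The model combines a fixed list of enrichment variables (cell populations and
signaling pathways, all oriented so that higher enrichment means higher risk)
into one per-patient score: each component is centered by its cohort median
(or by medians frozen on a training cohort), and the patient's score is the
mean of the centered components. A cutpoint between high-risk and low-risk
patients is chosen on the ROC curve by maximizing Youden's J
(sensitivity + specificity - 1) with the unfavorable class as positive.
Evaluation on an independent cohort applies the frozen training medians and
cutpoint without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, EnrichmentMatrix
from .group_stats import StatsConfig, gated_compare
from .survival import SurvivalData, cox_univariate, km_estimate, logrank_test, split_by_quantiles

__all__ = [
    "ModelConfig",
    "ScoreResult",
    "CutpointResult",
    "compute_model_score",
    "roc_cutpoint",
    "classify",
    "evaluate_model",
    "FrozenModel",
]


@dataclass(frozen=True)
class ModelConfig:
    """Which enrichment variables enter the score.

    All variables are treated as adverse (higher enrichment, higher risk);
    a variable protective in the data should be sign-flipped upstream before
    entering the model.
    """

    variable_ids: tuple[str, ...]
    aggregation: str = "median_centered_mean"

    def __post_init__(self) -> None:
        if len(self.variable_ids) < 2:
            raise ValueError("model needs at least 2 variables")
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise ValueError("duplicate variable ids in model config")
        if self.aggregation != "median_centered_mean":
            raise ValueError("only 'median_centered_mean' aggregation is implemented")


@dataclass
class ScoreResult:
    model_score: pd.Series  # per-sample composite score
    component_table: pd.DataFrame  # variables x samples, median-centered
    cohort_medians: pd.Series  # the centering medians actually used


@dataclass
class CutpointResult:
    cutpoint: float
    sensitivity: float
    specificity: float
    youden_j: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


def compute_model_score(
    enrichment: EnrichmentMatrix,
    config: ModelConfig,
    frozen_medians: pd.Series | None = None,
    use_nes: bool = True,
) -> ScoreResult:
    """Median-center each component and average per patient.

    ``frozen_medians`` (from a training cohort) are required to score a single
    sample and are what makes cross-cohort application leakage-free. Scores by
    default use normalized enrichment (NES); ``use_nes=False`` scores raw ES.
    """
    values = enrichment.nes if use_nes else enrichment.raw_es
    missing = [v for v in config.variable_ids if v not in values.index]
    if missing:
        raise KeyError(f"model variables missing from enrichment matrix: {missing}")
    sub = values.loc[list(config.variable_ids)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"model variables with missing scores: {bad}")
    if frozen_medians is not None:
        missing = [v for v in config.variable_ids if v not in frozen_medians.index]
        if missing:
            raise KeyError(f"frozen medians missing for: {missing}")
        medians = frozen_medians.loc[list(config.variable_ids)]
    else:
        if sub.shape[1] < 2:
            raise ValueError(
                "cohort medians undefined for a single sample; supply frozen_medians"
            )
        medians = sub.median(axis=1)
    centered = sub.sub(medians, axis=0)
    score = centered.mean(axis=0)
    score.name = "model_score"
    return ScoreResult(model_score=score, component_table=centered, cohort_medians=medians)


def roc_cutpoint(scores: np.ndarray | pd.Series, labels: np.ndarray,
                 criterion: str = "youden") -> CutpointResult:
    """Choose the score cutpoint on the ROC curve.

    Candidate cutpoints are midpoints between adjacent sorted unique scores
    (plus one below the minimum and one above the maximum). The unfavorable
    class U is positive and a score strictly above the cutpoint is a positive
    call. ``criterion`` is ``"youden"`` (default) or ``"accuracy"``; ties are
    broken toward the lower cutpoint.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(s).all():
        raise ValueError("non-finite scores")
    pos, neg = (y == "U"), (y == "F")
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present to place a cutpoint")
    if criterion not in ("youden", "accuracy"):
        raise ValueError("criterion must be 'youden' or 'accuracy'")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for c in candidates:
        call_pos = s > c
        tp = int((call_pos & pos).sum())
        fp = int((call_pos & neg).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        acc = (tp + tn) / (n_pos + n_neg)
        key = j if criterion == "youden" else acc
        if best is None or key > best[0] + 1e-12:  # strict improvement: ties keep lower cutpoint
            best = (key, CutpointResult(
                cutpoint=float(c), sensitivity=sens, specificity=spec,
                youden_j=j, accuracy=acc, tp=tp, fp=fp, tn=tn, fn=fn,
            ))
    return best[1]


def classify(scores: np.ndarray | pd.Series, cutpoint: float) -> np.ndarray:
    """``high_risk`` when score > cutpoint; a score exactly at the cutpoint is low_risk."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("non-finite scores")
    return np.where(s > cutpoint, "high_risk", "low_risk")


@dataclass
class FrozenModel:
    """Training-cohort centering medians and cutpoint, for cross-cohort scoring."""

    medians: pd.Series
    cutpoint: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"medians": self.medians.to_dict(), "cutpoint": self.cutpoint}, indent=2
        ))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrozenModel":
        d = json.loads(Path(path).read_text())
        return cls(medians=pd.Series(d["medians"]), cutpoint=float(d["cutpoint"]))


def _cohort_summary(enr: EnrichmentMatrix, clin: ClinicalTable, config: ModelConfig,
                    frozen: FrozenModel | None, stats: StatsConfig) -> dict:
    frozen_medians = frozen.medians if frozen is not None else None
    sc = compute_model_score(enr, config, frozen_medians=frozen_medians)
    scores = sc.model_score
    labels = clin.labels_for(scores.index)
    if frozen is None:
        cut = roc_cutpoint(scores, labels)
        frozen = FrozenModel(medians=sc.cohort_medians, cutpoint=cut.cutpoint)
    calls = classify(scores, frozen.cutpoint)
    truth = np.where(labels == "U", "high_risk", "low_risk")
    accuracy = float((calls == truth).mean())

    surv = clin.survival_for(list(scores.index))
    data = SurvivalData.from_clinical(surv)
    out = {
        "scores": scores,
        "accuracy": accuracy,
        "calls": pd.Series(calls, index=scores.index, name="risk_class"),
        "frozen": frozen,
        "fu_comparison": gated_compare(scores.to_numpy(), labels, stats,
                                       variable_id="model_score"),
    }
    for mode in ("median", "tertiles"):
        try:
            split = split_by_quantiles(scores.to_numpy(), mode=mode)
            grouped = SurvivalData(time=data.time, event=data.event, group=split.assignment)
            chi2_stat, df, p = logrank_test(grouped)
            curves = {
                int(g): km_estimate(SurvivalData(
                    time=data.time[split.assignment == g],
                    event=data.event[split.assignment == g]))
                for g in np.unique(split.assignment)
            }
            out[f"km_{mode}"] = {"logrank_chi2": chi2_stat, "df": df, "p": p, "curves": curves}
        except ValueError as exc:
            out[f"km_{mode}"] = {"error": str(exc)}
    return out


def evaluate_model(
    train: tuple[EnrichmentMatrix, ClinicalTable],
    test: tuple[EnrichmentMatrix, ClinicalTable],
    config: ModelConfig,
    stats: StatsConfig | None = None,
) -> dict:
    """Fit centering medians and cutpoint on the training cohort only, then
    apply them frozen to the test cohort.

    Returns a report with per-cohort accuracy, the frozen model, score
    Kaplan–Meier splits (median and tertiles) with log-rank p, and the F-vs-U
    score comparison from the normality-gated screen.
    """
    stats = stats or StatsConfig()
    train_rep = _cohort_summary(train[0], train[1], config, frozen=None, stats=stats)
    frozen = train_rep["frozen"]
    test_rep = _cohort_summary(test[0], test[1], config, frozen=frozen, stats=stats)
    return {"train": train_rep, "test": test_rep, "frozen": frozen}
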