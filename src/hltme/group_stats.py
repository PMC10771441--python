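"""Normality-gated two-group comparison screen for favorable vs unfavorable outcome.

Every per-sample variable (a gene's expression, an enrichment score, a cell
fraction) is compared between the F and U groups with a Shapiro–Wilk gate:
when both groups look normal the comparison is an unpaired Student t-test,
otherwise a Kruskal–Wallis test across the two groups (equivalent to a
Mann–Whitney test up to tie handling, retained in its k-group form for
fidelity with the published analysis pipeline). Raw p-values are reported;
Benjamini–Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["StatsConfig", "GroupComparisonResult", "gated_compare", "screen_variables"]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    normality_alpha: float = 0.05
    adjust: str = "none"  # or "benjamini_hochberg"
    welch: bool = False  # Welch's t instead of Student's (pooled variance)

    def __post_init__(self) -> None:
        for name in ("alpha", "normality_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.adjust not in ("none", "benjamini_hochberg"):
            raise ValueError("adjust must be 'none' or 'benjamini_hochberg'")


@dataclass
class GroupComparisonResult:
    variable_id: str
    mean_f: float
    mean_u: float
    median_f: float
    median_u: float
    normality_p_f: float
    normality_p_u: float
    test_used: str  # "t_test" | "kruskal_wallis"
    statistic: float
    p_value: float
    direction: str | None  # "higher_in_U" | "higher_in_F" | None when tied
    significant: bool


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p, or NaN when undefined (constant sample)."""
    if np.ptp(x) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(scipy.stats.shapiro(x).pvalue)


def gated_compare(
    values: np.ndarray | pd.Series,
    labels: np.ndarray,
    config: StatsConfig | None = None,
    variable_id: str = "",
) -> GroupComparisonResult:
    """Compare one variable between F and U samples with the normality gate.

    Requires at least 3 samples per group. A constant group makes the
    normality test undefined; the comparison then falls through to
    Kruskal–Wallis with a warning.
    """
    config = config or StatsConfig()
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in comparison input")
    f = x[labels == "F"]
    u = x[labels == "U"]
    if len(f) < 3 or len(u) < 3:
        raise ValueError(f"need >=3 samples per group, got F={len(f)}, U={len(u)}")

    p_f, p_u = _shapiro_p(f), _shapiro_p(u)
    both_normal = (
        np.isfinite(p_f) and np.isfinite(p_u)
        and p_f > config.normality_alpha and p_u > config.normality_alpha
    )
    if not (np.isfinite(p_f) and np.isfinite(p_u)):
        logger.warning("normality test undefined for %r (constant group); using Kruskal–Wallis",
                       variable_id)

    if both_normal:
        test_used = "t_test"
        res = scipy.stats.ttest_ind(u, f, equal_var=not config.welch)
        stat, p = float(res.statistic), float(res.pvalue)
        center_f, center_u = float(np.mean(f)), float(np.mean(u))
    else:
        test_used = "kruskal_wallis"
        try:
            res = scipy.stats.kruskal(u, f)
            stat, p = float(res.statistic), float(res.pvalue)
        except ValueError:  # all values identical across both groups
            stat, p = 0.0, 1.0
        center_f, center_u = float(np.median(f)), float(np.median(u))

    if center_u > center_f:
        direction = "higher_in_U"
    elif center_u < center_f:
        direction = "higher_in_F"
    else:
        direction = None
    return GroupComparisonResult(
        variable_id=variable_id,
        mean_f=float(np.mean(f)),
        mean_u=float(np.mean(u)),
        median_f=float(np.median(f)),
        median_u=float(np.median(u)),
        normality_p_f=p_f,
        normality_p_u=p_u,
        test_used=test_used,
        statistic=stat,
        p_value=p,
        direction=direction,
        significant=bool(p < config.alpha),
    )


def screen_variables(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: StatsConfig | None = None,
) -> pd.DataFrame:
    """Run :func:`gated_compare` on every row of a variables x samples matrix.

    Returns a DataFrame sorted by p-value, one row per variable. Per-variable
    failures (constant data, too few samples after NaN removal) are logged and
    omitted rather than aborting the screen. With
    ``config.adjust="benjamini_hochberg"`` an adjusted-p column is appended;
    raw p-values are never altered.
    """
    config = config or StatsConfig()
    labels = np.asarray(labels)
    if len(labels) != matrix.shape[1]:
        raise ValueError("labels must cover all samples")
    rows = []
    for var_id, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        mask = np.isfinite(vals)
        try:
            res = gated_compare(vals[mask], labels[mask], config, variable_id=str(var_id))
        except ValueError as exc:
            logger.warning("skipping variable %r: %s", var_id, exc)
            continue
        rows.append(vars(res))
    out = pd.DataFrame(rows, columns=[f.name for f in GroupComparisonResult.__dataclass_fields__.values()]
                       if not rows else None)
    if rows:
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
        if config.adjust == "benjamini_hochberg":
            out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
            out["significant_adjusted"] = out["p_adjusted"] < config.alpha
    return out
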