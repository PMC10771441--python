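"""Kaplan–Meier estimation, log-rank tests, univariate Cox screening, quantile splits.

Progression-free survival (months) is the endpoint throughout. Kaplan–Meier
curves and the k-group log-rank test delegate to ``lifelines``; the
univariate Cox proportional-hazards fit is implemented here as a
Newton–Raphson maximizer of the partial likelihood with Breslow handling of
tied event times (Efron available via flag), which keeps the exact identity
between the log-rank statistic and the Cox score test at beta = 0 available
for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2, norm

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxResult",
    "QuantileSplit",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_score_test",
    "split_by_quantiles",
]


@dataclass
class SurvivalData:
    """Time-to-event data: times in months, event=1 progression / 0 censored."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        if not np.isfinite(self.time).all():
            raise ValueError("times must be finite")
        if (self.time < 0).any():
            raise ValueError("negative survival times")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != self.time.shape:
                raise ValueError("group must align with time")

    @classmethod
    def from_clinical(cls, df: pd.DataFrame, group: np.ndarray | None = None) -> "SurvivalData":
        return cls(time=df["pfs_months"].to_numpy(), event=df["event"].to_numpy(), group=group)


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) right-continuous step function."""

    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray  # n at risk just before each event time
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray  # times of censored observations

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.event_times, "at_risk": self.at_risk,
             "events": self.n_events, "survival": self.survival}
        )


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    if data.time.size < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    return KMCurve(
        event_times=times,
        at_risk=ev["at_risk"].to_numpy(),
        n_events=ev["observed"].to_numpy(),
        survival=surv,
        censor_times=np.sort(data.time[data.event == 0]),
    )


def logrank_test(data: SurvivalData) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square statistic, df = k-1, p).

    Observed minus expected events over the shared risk sets, with
    hypergeometric variance; identical groups give statistic 0 and p = 1.
    """
    if data.group is None:
        raise ValueError("grouped data required")
    groups = pd.unique(data.group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(data.group).value_counts()
    if (counts == 0).any():
        raise ValueError("empty group")
    if data.event.sum() < 1:
        raise ValueError("no events: log-rank test undefined")
    res = multivariate_logrank_test(data.time, data.group, data.event)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


@dataclass
class CoxResult:
    variable_id: str
    log_hazard_ratio: float
    se: float
    wald_z: float
    p_value: float
    converged: bool
    n_iter: int


def _cox_derivatives(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray,
                     ties: str) -> tuple[float, float, float]:
    """(log partial likelihood, score U, information I) at beta."""
    order = np.argsort(-time, kind="stable")  # decreasing time: cumulative sums give risk sets
    t, d, xv = time[order], event[order], x[order]
    eta = beta * xv
    eta -= eta.max()  # guards overflow; constant shifts cancel in all three quantities
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xv)
    s2 = np.cumsum(w * xv * xv)
    loglik = score = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # observations i..j-1 share this time; risk set = everything up to j-1
        ev = d[i:j] == 1
        m = int(ev.sum())
        if m > 0:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xs = xv[i:j][ev]
            if ties == "breslow":
                loglik += beta * xs.sum() - m * np.log(S0)
                score += xs.sum() - m * S1 / S0
                info += m * (S2 / S0 - (S1 / S0) ** 2)
            else:  # efron
                wd = w[i:j][ev]
                S0d, S1d, S2d = wd.sum(), (wd * xs).sum(), (wd * xs * xs).sum()
                for k in range(m):
                    c = k / m
                    S0k = S0 - c * S0d
                    S1k = S1 - c * S1d
                    S2k = S2 - c * S2d
                    loglik -= np.log(S0k)
                    score -= S1k / S0k
                    info += S2k / S0k - (S1k / S0k) ** 2
                loglik += beta * xs.sum()
                score += xs.sum()
        i = j
    return loglik, score, info


def cox_univariate(
    values: np.ndarray,
    data: SurvivalData,
    variable_id: str = "",
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton–Raphson.

    Convergence when the score (gradient) magnitude drops below ``tol``.
    Monotone likelihood (complete separation drives |beta| to infinity) is
    reported as ``converged=False`` rather than a spurious estimate.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != data.time.shape:
        raise ValueError("covariate must align with survival data")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: hazard ratio unidentifiable")
    if data.event.sum() < 2:
        raise ValueError("need at least 2 events")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    # standardize internally for conditioning; transform back afterwards
    mu, sd = x.mean(), x.std()
    z = (x - mu) / sd
    beta = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        _, score, info = _cox_derivatives(beta, data.time, data.event, z, ties)
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -5.0, 5.0)
        if abs(score) < tol:
            converged = True
            break
        if abs(beta) > 50:  # monotone likelihood
            break
    _, _, info = _cox_derivatives(beta, data.time, data.event, z, ties)
    se_z = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    if abs(beta) > 8 or not np.isfinite(se_z) or se_z > 50:
        # a hazard ratio beyond e^8 per SD marks a monotone partial likelihood
        converged = False
    b = beta / sd
    se = se_z / sd
    wald = b / se if se > 0 else float("nan")
    p = float(2 * norm.sf(abs(wald))) if np.isfinite(wald) else float("nan")
    return CoxResult(
        variable_id=variable_id,
        log_hazard_ratio=float(b),
        se=float(se),
        wald_z=float(wald),
        p_value=p,
        converged=converged,
        n_iter=n_iter,
    )


def cox_score_test(values: np.ndarray, data: SurvivalData, ties: str = "breslow") -> tuple[float, float]:
    """Cox score test at beta = 0: (chi-square statistic, p with 1 df).

    For a binary covariate without tied event times this equals the two-group
    log-rank statistic exactly.
    """
    x = np.asarray(values, dtype=float)
    _, score, info = _cox_derivatives(0.0, data.time, data.event, x, ties)
    stat = score**2 / info
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class QuantileSplit:
    variable_id: str
    cutoffs: np.ndarray  # ascending; 1 for median, 2 for tertiles, 3 for quartiles
    assignment: np.ndarray  # integer group per sample, 0 = lowest

    @property
    def n_groups(self) -> int:
        return len(self.cutoffs) + 1


_MODES = {"median": 2, "tertiles": 3, "quartiles": 4}


def split_by_quantiles(values: np.ndarray, mode: str = "tertiles",
                       variable_id: str = "") -> QuantileSplit:
    """Assign samples to quantile groups of a variable.

    Cutoffs use the linear-interpolation quantile definition; a value exactly
    at a cutoff goes to the lower group. ``mode`` is ``median`` (2 groups),
    ``tertiles`` (3) or ``quartiles`` (4).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}")
    k = _MODES[mode]
    x = np.asarray(values, dtype=float)
    if x.size < k:
        raise ValueError(f"need >= {k} samples for {mode}")
    if np.ptp(x) == 0:
        raise ValueError("all values equal: degenerate split")
    qs = np.arange(1, k) / k
    cutoffs = np.quantile(x, qs)  # linear interpolation
    assignment = np.searchsorted(cutoffs, x, side="left")  # value == cutoff -> lower group
    return QuantileSplit(variable_id=variable_id, cutoffs=cutoffs, assignment=assignment)
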