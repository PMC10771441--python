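"""Signature-based estimation of cell-type proportions from bulk expression.

Given a genes x cell-types reference signature S and a bulk expression vector
x on linear scale, each sample is deconvolved independently by nonnegative
least squares over the discriminating signature genes:

    minimize ||S f - x||_2   subject to   f >= 0,

after which f is renormalized to unit sum, yielding the per-patient
cell-abundance fingerprint. NNLS is convex and deterministic; the regression
backend is pluggable so a support-vector variant can be added.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .containers import ExpressionMatrix, FractionMatrix, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["select_signature_genes", "deconvolve_sample", "deconvolve_all"]

#: fold over the cross-type median above which a signature gene counts as discriminating
DEFAULT_MARKER_FOLD = 2.0


def select_signature_genes(S: SignatureMatrix, fold: float = DEFAULT_MARKER_FOLD) -> list[str]:
    """Genes whose value in some cell type is ``>= fold`` x the median of the others.

    The leave-one-out median keeps the rule meaningful at small K (with only
    two types an all-type median sits midway between the values, so no finite
    fold would ever fire). Genes flat across cell types (housekeeping,
    filler) carry no mixture information and are excluded from the fit.
    """
    vals = S.values.to_numpy()
    n_genes, K = vals.shape
    keep = np.zeros(n_genes, dtype=bool)
    for k in range(K):
        others = np.delete(vals, k, axis=1)
        med = np.median(others, axis=1)
        keep |= vals[:, k] >= fold * np.maximum(med, np.finfo(float).tiny)
        keep &= ~np.all(vals == vals[:, [0]], axis=1)  # drop exactly flat rows
    return [g for g, flag in zip(S.gene_ids, keep) if flag]


def _nnls(S: np.ndarray, x: np.ndarray) -> np.ndarray:
    f, _ = scipy.optimize.nnls(S, x)
    return f


def deconvolve_sample(
    x: pd.Series,
    S: SignatureMatrix,
    signature_genes: Sequence[str] | None = None,
    solver: Callable[[np.ndarray, np.ndarray], np.ndarray] = _nnls,
) -> tuple[np.ndarray, dict]:
    """Estimate one sample's cell-type fractions.

    Parameters
    ----------
    x
        Per-gene expression for one sample (linear scale), indexed by gene id.
    S
        Reference signature matrix.
    signature_genes
        Genes to fit on; defaults to :func:`select_signature_genes`.

    Returns
    -------
    fractions
        Length-K vector, nonnegative, summing to 1. If the fit collapses to
        the zero vector the fractions fall back to uniform and the diagnostics
        carry ``degenerate=True``.
    diagnostics
        ``rmse`` (residual root-mean-square over fitted genes), ``pearson_r``
        (fitted vs observed expression), ``n_genes`` used, ``degenerate`` flag.
    """
    if (x < 0).any():
        raise ValueError("negative expression: deconvolution expects linear-scale values")
    # a bare DataFrame is accepted for fits against ad-hoc references
    ref = S.values if isinstance(S, SignatureMatrix) else S
    if signature_genes is not None:
        genes = list(signature_genes)
    elif isinstance(S, SignatureMatrix):
        genes = select_signature_genes(S)
    else:
        genes = list(ref.index)
    shared = [g for g in genes if g in x.index]
    K = ref.shape[1]
    if len(shared) < K:
        raise ValueError(
            f"only {len(shared)} signature genes shared with the sample; need >= {K}"
        )
    A = ref.loc[shared].to_numpy()
    b = x.loc[shared].to_numpy(dtype=float)
    f = solver(A, b)
    fitted = A @ f
    resid = b - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(fitted) > 0 and np.std(b) > 0:
        r = float(np.corrcoef(fitted, b)[0, 1])
    else:
        r = float("nan")
    total = f.sum()
    degenerate = total <= 0
    if degenerate:
        logger.warning("NNLS returned the zero vector; falling back to uniform fractions")
        f = np.full(K, 1.0 / K)
    else:
        f = f / total
    return f, {"rmse": rmse, "pearson_r": r, "n_genes": len(shared), "degenerate": degenerate}


def deconvolve_all(
    m: ExpressionMatrix,
    S: SignatureMatrix,
    signature_genes: Sequence[str] | None = None,
) -> FractionMatrix:
    """Per-sample independent fits over a cohort; the Fig-1-style fingerprint table.

    Samples whose fit fails are flagged (uniform fractions, ``degenerate``
    diagnostic) rather than aborting the cohort.
    """
    genes = list(signature_genes) if signature_genes is not None else select_signature_genes(S)
    K = S.n_celltypes
    out = np.empty((K, m.n_samples))
    rmse = np.empty(m.n_samples)
    corr = np.empty(m.n_samples)
    degen = np.zeros(m.n_samples, dtype=bool)
    for j, sample_id in enumerate(m.sample_ids):
        try:
            f, diag = deconvolve_sample(m.values[sample_id], S, signature_genes=genes)
        except ValueError:
            raise
        except Exception as exc:  # solver failure: flag, do not abort the cohort
            logger.warning("deconvolution failed for sample %r: %s", sample_id, exc)
            f = np.full(K, 1.0 / K)
            diag = {"rmse": float("nan"), "pearson_r": float("nan"), "degenerate": True}
        out[:, j] = f
        rmse[j] = diag["rmse"]
        corr[j] = diag["pearson_r"]
        degen[j] = diag["degenerate"]
    cols = pd.Index(m.sample_ids)
    return FractionMatrix(
        fractions=pd.DataFrame(out, index=pd.Index(S.celltype_ids, name="celltype_id"), columns=cols),
        fit_residual=pd.Series(rmse, index=cols, name="rmse"),
        correlation=pd.Series(corr, index=cols, name="pearson_r"),
        degenerate=pd.Series(degen, index=cols, name="degenerate"),
    )
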