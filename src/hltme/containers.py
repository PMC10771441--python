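"""In-memory containers for expression, gene sets, enrichment, fractions and clinical data.

All matrix-like containers wrap a :class:`pandas.DataFrame` with features
(genes, gene sets, or cell types) as rows and samples as columns, mirroring
the orientation of the delimited files they are read from and written to.
Validation happens at construction so downstream code can rely on the stated
invariants (unique identifiers, non-negativity, simplex columns, ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SignatureMatrix",
    "ClinicalTable",
    "EnrichmentMatrix",
    "FractionMatrix",
    "PFS_THRESHOLD_MONTHS",
]

#: Favorable outcome means progression-free survival beyond two years.
PFS_THRESHOLD_MONTHS = 24.0


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``scale`` records whether values are raw probe counts, normalized linear
    expression, or log2 expression; operations that require a particular
    scale check this flag rather than guessing from the values.
    """

    values: pd.DataFrame
    scale: str = "raw"

    _SCALES = ("raw", "normalized", "log2")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"scale must be one of {self._SCALES}, got {self.scale!r}")
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, scale=scale or self.scale)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered collection of named gene sets (cell populations and pathways)."""

    def __init__(self, sets: Sequence[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        missing = [n for n in names if n not in self._sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        return GeneSetCollection([self._sets[n] for n in names])


@dataclass
class SignatureMatrix:
    """Genes x cell-types reference expression on linear scale (an LM22-style matrix)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "cell type ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature matrix contains negative values")
        # at least one discriminating marker must exist per cell type
        vals = self.values.to_numpy()
        med = np.median(vals, axis=1, keepdims=True)
        if not ((vals > med).any(axis=0)).all():
            flat = self.values.columns[~(vals > med).any(axis=0)].tolist()
            raise ValueError(f"cell types without discriminating markers: {flat}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_celltypes(self) -> int:
        return self.values.shape[1]


@dataclass
class ClinicalTable:
    """Per-sample outcome label (F/U), PFS in months, and event indicator."""

    table: pd.DataFrame  # columns: sample_id, outcome, pfs_months, event

    REQUIRED = ("sample_id", "outcome", "pfs_months", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        t = self.table.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["pfs_months"] = t["pfs_months"].astype(float)
        t["event"] = t["event"].astype(int)
        if t["sample_id"].isna().any() or (t["sample_id"] == "").any():
            raise ValueError("missing sample ids")
        _check_unique(pd.Index(t["sample_id"]), "sample ids")
        if (t["pfs_months"] < 0).any():
            raise ValueError("negative PFS times")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if not t["outcome"].isin(["F", "U"]).all():
            bad = sorted(set(t["outcome"]) - {"F", "U"})
            raise ValueError(f"outcome labels must be 'F' or 'U', got {bad}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def outcome(self) -> pd.Series:
        return self.table.set_index("sample_id")["outcome"]

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Outcome labels aligned to ``sample_ids`` (raises on unknown ids)."""
        out = self.outcome
        missing = [s for s in sample_ids if s not in out.index]
        if missing:
            raise KeyError(f"samples missing from clinical table: {missing[:5]}")
        return out.loc[list(sample_ids)].to_numpy()

    def survival_for(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        t = self.table.set_index("sample_id").loc[list(sample_ids)]
        return t[["pfs_months", "event"]].reset_index()


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples enrichment scores: the per-patient immune fingerprint.

    Holds raw running-sum scores, empirically normalized scores, empirical
    p-values and the number of set members actually present in the panel.
    """

    raw_es: pd.DataFrame
    nes: pd.DataFrame
    empirical_p: pd.DataFrame
    effective_set_size: pd.Series

    def __post_init__(self) -> None:
        for name in ("nes", "empirical_p"):
            df = getattr(self, name)
            if not df.index.equals(self.raw_es.index) or not df.columns.equals(self.raw_es.columns):
                raise ValueError(f"{name} not aligned with raw_es")
        p = self.empirical_p.to_numpy()
        finite = np.isfinite(p)
        if ((p[finite] < 0) | (p[finite] > 1)).any():
            raise ValueError("empirical p-values outside [0, 1]")

    @property
    def set_ids(self) -> list[str]:
        return list(self.raw_es.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw_es.columns)


@dataclass
class FractionMatrix:
    """Cell types x samples estimated (or true) proportions; columns on the simplex."""

    fractions: pd.DataFrame
    fit_residual: pd.Series | None = None  # per-sample RMSE
    correlation: pd.Series | None = None  # per-sample Pearson r, fitted vs observed
    degenerate: pd.Series | None = None  # per-sample flag: fit collapsed to uniform

    def __post_init__(self) -> None:
        self.fractions = self.fractions.astype(float)
        _check_unique(self.fractions.index, "cell type ids")
        _check_unique(self.fractions.columns, "sample ids")
        f = self.fractions.to_numpy()
        if (f < -1e-9).any():
            raise ValueError("negative fractions")
        sums = f.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("fraction columns must sum to 1")

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.columns)
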