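"""Readers, writers and normalization for the pipeline's delimited file formats.

Formats handled: TSV/CSV gene-by-sample matrices, GMT gene-set collections,
TSV signature matrices, TSV fraction matrices, and CSV clinical tables.
Lines starting with ``#`` are treated as comments (provenance headers) in all
matrix formats. Gene identifiers are matched case-sensitively after stripping
surrounding whitespace; no symbol aliasing is attempted.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    PFS_THRESHOLD_MONTHS,
    ClinicalTable,
    ExpressionMatrix,
    FractionMatrix,
    GeneSet,
    GeneSetCollection,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "read_fractions",
    "write_fractions",
    "read_clinical",
    "write_clinical",
    "normalize_counts",
]


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if str(path).endswith(".csv") else "\t"


def _read_matrix(path: str | Path, sep: str, what: str) -> pd.DataFrame:
    with open(path) as fh:  # pandas silently renames duplicate headers; check first
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = [c.strip() for c in line.rstrip("\n").split(sep)][1:]
                if len(header) != len(set(header)):
                    dupes = sorted({c for c in header if header.count(c) > 1})
                    raise ValueError(f"{path}: duplicate sample headers {dupes}")
                break
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r} (value {df.iat[bad[0], bad[1]]!r})"
        )
    return numeric


def read_expression(
    path: str | Path, dialect: str | None = None, scale: str = "raw"
) -> ExpressionMatrix:
    """Read a gene-by-sample matrix (gene ids in first column, sample header row).

    Duplicate gene rows are collapsed by taking the per-sample maximum, with a
    warning; any non-numeric or empty cell is a parse error naming its location.
    """
    sep = _sep_for(path, dialect)
    df = _read_matrix(path, sep, "expression")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene ids by max: %s", len(dupes), dupes[:5])
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(values=df, scale=scale)


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_expression(m: ExpressionMatrix, path: str | Path, dialect: str | None = None,
                     provenance: dict | None = None) -> None:
    sep = _sep_for(path, dialect)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        m.values.to_csv(fh, sep=sep, index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, description, *genes = fields
            genes = tuple(g.strip() for g in genes if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            try:
                coll.add(GeneSet(name=name, description=description, genes=genes))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in gs:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_signature(path: str | Path, dialect: str | None = None) -> SignatureMatrix:
    sep = _sep_for(path, dialect)
    return SignatureMatrix(values=_read_matrix(path, sep, "signature"))


def write_signature(s: SignatureMatrix, path: str | Path, dialect: str | None = None,
                    provenance: dict | None = None) -> None:
    sep = _sep_for(path, dialect)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        s.values.to_csv(fh, sep=sep, index_label="gene_id")


def read_fractions(path: str | Path, dialect: str | None = None) -> FractionMatrix:
    sep = _sep_for(path, dialect)
    return FractionMatrix(fractions=_read_matrix(path, sep, "fractions"))


def write_fractions(f: FractionMatrix, path: str | Path, dialect: str | None = None,
                    provenance: dict | None = None) -> None:
    sep = _sep_for(path, dialect)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        f.fractions.to_csv(fh, sep=sep, index_label="celltype_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV (sample_id, pfs_months, event[, outcome]).

    When the outcome column is absent, labels are derived from PFS under the
    two-year rule: favorable (F) iff PFS exceeds 24 months; a progression at or
    before 24 months, or follow-up censored within 24 months, is unfavorable (U).
    """
    df = pd.read_csv(path, comment="#")
    required = ["sample_id", "pfs_months", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    if "outcome" not in df.columns:
        df["outcome"] = np.where(df["pfs_months"] > PFS_THRESHOLD_MONTHS, "F", "U")
    return ClinicalTable(table=df[["sample_id", "outcome", "pfs_months", "event"]])


def write_clinical(c: ClinicalTable, path: str | Path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        c.table.to_csv(fh, index=False)


def _geometric_mean(values: np.ndarray) -> np.ndarray:
    """Column-wise geometric mean with a +1 pseudocount applied to zeros."""
    v = values.copy()
    if (v == 0).any():
        n_zero = int((v == 0).sum())
        logger.warning("applying +1 pseudocount to %d zero housekeeping counts", n_zero)
        v = v + (v == 0)
    return np.exp(np.log(v).mean(axis=0))


def normalize_counts(m: ExpressionMatrix, housekeeping: Sequence[str]) -> ExpressionMatrix:
    """Housekeeping geometric-mean normalization (nCounter-style content normalization).

    Each sample is scaled by ``(cohort geometric mean of per-sample housekeeping
    geometric means) / (sample housekeeping geometric mean)``, which equalizes
    housekeeping geometric means across samples while preserving the cohort's
    overall level. Idempotent up to floating-point tolerance.
    """
    if m.scale != "raw" and m.scale != "normalized":
        raise ValueError(f"normalize_counts expects raw counts, got scale={m.scale!r}")
    hk = [h.strip() for h in housekeeping]
    if len(hk) < 3:
        raise ValueError(f"need at least 3 housekeeping genes, got {len(hk)}")
    missing = [g for g in hk if g not in m.values.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk_counts = m.values.loc[hk].to_numpy()
    sample_geomeans = _geometric_mean(hk_counts)
    cohort_geomean = math.exp(float(np.mean(np.log(sample_geomeans))))
    factors = cohort_geomean / sample_geomeans
    normalized = m.values * factors[np.newaxis, :]
    return ExpressionMatrix(values=normalized, scale="normalized")
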