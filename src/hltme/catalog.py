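"""Packaged panel layout, gene-set catalog, and default prognostic-model variables.

The real assay is an ~800-gene immune-profiling panel scored against a
catalog of 89 immune/stromal cell-population gene sets plus signaling-pathway
sets, and a 31-variable prognostic model (13 cell types + 18 pathways). The
exact commercial panel content and the full catalog are not redistributable,
so this module generates a synthetic, structurally faithful stand-in: marker
genes per cell type, housekeeping genes, pathway gene blocks, and filler
genes, with gene-set membership defined over those names. All construction is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import GeneSet, GeneSetCollection

__all__ = [
    "CELL_TYPES",
    "MODEL_PATHWAYS",
    "EXTRA_PATHWAYS",
    "ADVERSE_CELL_TYPES",
    "PanelLayout",
    "build_panel_layout",
    "build_catalog",
    "default_model_variables",
]

#: The 13 cell types of the packaged signature matrix (and the model's
#: cell-type variables). The adverse subset mirrors populations reported as
#: enriched in unfavorable-outcome patients.
CELL_TYPES: tuple[str, ...] = (
    "M1-like macrophages",
    "M2-like macrophages",
    "Monocytes",
    "Myeloid dendritic cells",
    "Plasmacytoid dendritic cells",
    "MDSC",
    "CD8 T effector memory",
    "CD8 T central memory",
    "NK cells immature",
    "Th17 cells",
    "Tr1 cells",
    "Mast cells",
    "Stromal cells",
)

ADVERSE_CELL_TYPES: tuple[str, ...] = (
    "M2-like macrophages",
    "Myeloid dendritic cells",
    "Plasmacytoid dendritic cells",
    "MDSC",
    "Stromal cells",
)

#: The 18 signaling-pathway variables of the packaged prognostic model
#: (all oriented adverse: higher enrichment, higher risk).
MODEL_PATHWAYS: tuple[str, ...] = (
    "ROBO pathway",
    "VEGF pathway",
    "DAP12 pathway",
    "IL6 pathway",
    "TNF pathway",
    "IFN-gamma pathway",
    "IL3 pathway",
    "GMCSF pathway",
    "IL10 pathway",
    "IL12 pathway",
    "FCGR pathway",
    "CREB pathway",
    "TRKA pathway",
    "Hypoxia pathway",
    "SHP2 pathway",
    "Semaphorin pathway",
    "TCPTP pathway",
    "IL7 pathway",
)

#: Additional pathways scored by the screen but outside the model
#: (includes the favorable-leaning signatures).
EXTRA_PATHWAYS: tuple[str, ...] = (
    "TGF-beta pathway",
    "NFAT pathway",
    "MHC-I pathway",
    "MHC-II pathway",
)

#: Variant qualifiers used to expand each base cell type into related
#: functional subpopulations.
_VARIANTS: tuple[str, ...] = ("Activated", "Immature", "Mature", "Naive", "Effector")

#: Lineage groupings (unions over base-type markers) completing the catalog.
_LINEAGES: Mapping[str, tuple[str, ...]] = {
    "Myeloid cells": ("M1-like macrophages", "M2-like macrophages", "Monocytes"),
    "Macrophages": ("M1-like macrophages", "M2-like macrophages"),
    "Dendritic cells": ("Myeloid dendritic cells", "Plasmacytoid dendritic cells"),
    "Monocytic lineage": ("Monocytes", "MDSC"),
    "CD8 T cells": ("CD8 T effector memory", "CD8 T central memory"),
    "Cytotoxic cells": ("CD8 T effector memory", "NK cells immature"),
    "NK cells": ("NK cells immature",),
    "CD4 T cells": ("Th17 cells", "Tr1 cells"),
    "Regulatory T cells": ("Tr1 cells",),
    "Lymphoid cells": ("CD8 T central memory", "Th17 cells", "Tr1 cells"),
    "Antigen-presenting cells": ("Myeloid dendritic cells", "M1-like macrophages"),
}

#: Genes per packaged pathway set.
PATHWAY_SET_SIZE = 12


def _abbreviate(names: Sequence[str]) -> dict[str, str]:
    """Short unique uppercase prefixes for gene naming, deterministic."""
    out: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        tokens = [t for t in "".join(c if c.isalnum() else " " for c in name).split() if t]
        abbr = "".join(t[:2].upper() for t in tokens)[:8] or "X"
        base, k = abbr, 1
        while abbr in used:
            k += 1
            abbr = f"{base}{k}"
        used.add(abbr)
        out[name] = abbr
    return out


@dataclass
class PanelLayout:
    """Partition of the synthetic panel's gene names by role."""

    markers: dict[str, tuple[str, ...]]  # cell type -> marker genes
    housekeeping: tuple[str, ...]
    pathway_genes: dict[str, tuple[str, ...]]  # pathway -> dedicated genes
    filler: tuple[str, ...]  # unstructured background genes

    @property
    def all_genes(self) -> tuple[str, ...]:
        genes: list[str] = []
        for g in self.markers.values():
            genes.extend(g)
        genes.extend(self.housekeeping)
        for g in self.pathway_genes.values():
            genes.extend(g)
        genes.extend(self.filler)
        return tuple(genes)


def build_panel_layout(
    celltype_names: Sequence[str],
    n_markers_per_type: int,
    n_housekeeping: int,
    total_genes: int,
    pathways: Sequence[str] | None = None,
) -> PanelLayout:
    """Lay out the synthetic panel: markers, housekeeping, pathway blocks, filler.

    Pathway blocks of :data:`PATHWAY_SET_SIZE` genes are carved from the
    endogenous non-marker budget in order, as long as room remains; small test
    panels simply get no pathway blocks.
    """
    n_marker = n_markers_per_type * len(celltype_names)
    if n_marker + n_housekeeping > total_genes:
        raise ValueError(
            f"{n_marker} marker + {n_housekeeping} housekeeping genes exceed "
            f"total_genes={total_genes}"
        )
    abbr = _abbreviate(list(celltype_names))
    markers = {
        ct: tuple(f"{abbr[ct]}_MK{i + 1:02d}" for i in range(n_markers_per_type))
        for ct in celltype_names
    }
    housekeeping = tuple(f"HK{i + 1:03d}" for i in range(n_housekeeping))
    remaining = total_genes - n_marker - n_housekeeping
    pathway_genes: dict[str, tuple[str, ...]] = {}
    if pathways is None:
        pathways = MODEL_PATHWAYS + EXTRA_PATHWAYS
    pw_abbr = _abbreviate(list(pathways))
    for pw in pathways:
        if remaining < PATHWAY_SET_SIZE:
            break
        pathway_genes[pw] = tuple(
            f"{pw_abbr[pw]}_G{i + 1:02d}" for i in range(PATHWAY_SET_SIZE)
        )
        remaining -= PATHWAY_SET_SIZE
    filler = tuple(f"FIL{i + 1:04d}" for i in range(remaining))
    return PanelLayout(markers=markers, housekeeping=housekeeping,
                       pathway_genes=pathway_genes, filler=filler)


def build_catalog(layout: PanelLayout, seed: int = 0) -> GeneSetCollection:
    """The packaged gene-set catalog over a panel layout.

    Contains 89 cell-population sets when built over the default 13-type
    panel — the 13 base types (their full marker sets), five functional
    variants of each (marker subsets plus a little background, emulating
    partially overlapping signatures), and 11 lineage unions — plus one set
    per pathway block. Descriptions mark each entry as ``cell population`` or
    ``signaling pathway``.
    """
    rng = np.random.default_rng([seed, 97])
    sets: list[GeneSet] = []
    background = list(layout.filler) or [g for gs in layout.pathway_genes.values() for g in gs]
    for ct, genes in layout.markers.items():
        sets.append(GeneSet(name=ct, description="cell population", genes=genes))
    for variant in _VARIANTS:
        for ct, genes in layout.markers.items():
            n_keep = max(1, (len(genes) * 3) // 5)
            keep = tuple(sorted(rng.choice(genes, size=n_keep, replace=False)))
            extra: tuple[str, ...] = ()
            if background:
                extra = tuple(sorted(rng.choice(background, size=min(2, len(background)),
                                                replace=False)))
            sets.append(GeneSet(name=f"{variant} {ct[0].lower()}{ct[1:]}",
                                description="cell population", genes=keep + extra))
    for lineage, members in _LINEAGES.items():
        genes: list[str] = []
        for ct in members:
            if ct in layout.markers:
                half = max(1, len(layout.markers[ct]) // 2)
                genes.extend(layout.markers[ct][:half])
        if genes:
            sets.append(GeneSet(name=lineage, description="cell population",
                                genes=tuple(dict.fromkeys(genes))))
    for pw, genes in layout.pathway_genes.items():
        sets.append(GeneSet(name=pw, description="signaling pathway", genes=genes))
    return GeneSetCollection(sets)


def default_model_variables(
    celltype_names: Sequence[str] = CELL_TYPES,
    pathways: Sequence[str] = MODEL_PATHWAYS,
) -> tuple[str, ...]:
    """The packaged 31-variable model list: 13 cell types + 18 pathways.

    The named constituents highlighted in the source analysis (ROBO, VEGF and
    DAP12 pathways; M2-like macrophages, myeloid dendritic cells, stromal
    cells) appear verbatim; the remainder are the documented stand-in entries.
    Users supply their own list for real cohorts.
    """
    return tuple(celltype_names) + tuple(pathways)
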