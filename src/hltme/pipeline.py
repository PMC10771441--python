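"""End-to-end orchestration: simulate/normalize -> ssGSEA + deconvolution ->
outcome statistics + survival -> prognostic score -> report.

Each stage reads its inputs from files written by upstream stages (or
user-supplied paths), writes plain-text outputs with a provenance header
(config hash, seed, package version), and is individually re-runnable:
deleting a downstream output and re-running only that stage reproduces it
bitwise from the upstream artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import catalog as _catalog
from . import io as _io
from .containers import ClinicalTable, EnrichmentMatrix, ExpressionMatrix
from .deconvolution import deconvolve_all
from .group_stats import StatsConfig, screen_variables
from .prognostic import FrozenModel, ModelConfig, classify, compute_model_score, roc_cutpoint
from .ssgsea import EnrichmentParams, score_all
from .survival import SurvivalData, cox_univariate, km_estimate, logrank_test, split_by_quantiles
from .synthetic import SimulationConfig, generate_cohort, default_catalog

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "ssgsea", "deconvolve", "compare", "survive",
              "score", "report")

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    outdir: str | Path = "hltme_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None  # default: discovery preset with `seed`
    enrichment: EnrichmentParams | None = None
    stats: StatsConfig | None = None
    model_variables: tuple[str, ...] | None = None  # default: packaged 31-variable list
    survive_mode: str = "tertiles"
    # external inputs used when the simulate stage is disabled
    expression_path: str | None = None
    clinical_path: str | None = None
    signature_path: str | None = None
    gmt_path: str | None = None
    housekeeping_path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.enrichment is None:
            self.enrichment = EnrichmentParams(seed=self.seed)
        if self.stats is None:
            self.stats = StatsConfig()
        if "simulate" not in self.stages:
            needed = {"normalize": ["expression_path", "housekeeping_path"],
                      "ssgsea": ["expression_path"],
                      "deconvolve": ["expression_path", "signature_path"],
                      "compare": ["clinical_path"],
                      "survive": ["clinical_path"],
                      "score": ["clinical_path"]}
            for stage, paths in needed.items():
                if stage in self.stages:
                    for p in paths:
                        if getattr(self, p) is None:
                            raise ValueError(
                                f"stage {stage!r} enabled without simulate: {p} required"
                            )
        for p_name in ("expression_path", "clinical_path", "signature_path",
                       "gmt_path", "housekeeping_path"):
            p = getattr(self, p_name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{p_name} does not exist: {p}")

    def config_hash(self) -> str:
        # the hash identifies the analysis parameters, not run location,
        # stage selection or input file paths, so partial re-runs from the
        # same upstream artifacts reproduce identical provenance headers
        payload = dataclasses.asdict(self)
        for key in ("outdir", "stages", "expression_path", "clinical_path",
                    "signature_path", "gmt_path", "housekeeping_path"):
            payload[key] = None
        blob = yaml.safe_dump(payload, sort_keys=True, default_flow_style=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}


def _enrichment_to_long(enr: EnrichmentMatrix) -> pd.DataFrame:
    rows = []
    for set_id in enr.set_ids:
        for sample_id in enr.sample_ids:
            rows.append({
                "set": set_id, "sample": sample_id,
                "es": enr.raw_es.at[set_id, sample_id],
                "nes": enr.nes.at[set_id, sample_id],
                "p": enr.empirical_p.at[set_id, sample_id],
                "effective_size": int(enr.effective_set_size[set_id]),
            })
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, provenance: dict, sep: str = ",",
               index: bool = False, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("".join(f"# {k}={v}\n" for k, v in provenance.items()))
        df.to_csv(fh, sep=sep, index=index, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns a run report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    report: dict = {"outdir": str(outdir), "stages": {}, "provenance": prov}
    failed: set[str] = set()
    deps = {"simulate": (), "normalize": (), "ssgsea": ("normalize",),
            "deconvolve": ("normalize",), "compare": ("ssgsea",),
            "survive": ("ssgsea",), "score": ("ssgsea",),
            "report": ()}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        blocked = [d for d in deps[stage] if d in failed]
        if blocked:
            report["stages"][stage] = {"status": "skipped", "blocked_by": blocked}
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, outdir, prov)
            report["stages"][stage] = {"status": "ok",
                                       "seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
        except Exception as exc:
            failed.add(stage)
            report["stages"][stage] = {"status": "failed", "error": f"{stage}: {exc}"}
            logger.error("stage %s failed: %s", stage, exc)
    return report


def _stage_simulate(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    cohort = generate_cohort(config.simulation)
    cohort.write(outdir / "simulate", provenance=prov)
    _io.write_gmt(default_catalog(config.simulation), outdir / "simulate" / "catalog.gmt")


def _expression_input(config: PipelineConfig, outdir: Path) -> Path:
    if config.expression_path:
        return Path(config.expression_path)
    return outdir / "simulate" / "expression.tsv"


def _clinical_input(config: PipelineConfig, outdir: Path) -> ClinicalTable:
    path = Path(config.clinical_path) if config.clinical_path else outdir / "simulate" / "clinical.csv"
    return _io.read_clinical(path)


def _stage_normalize(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    expr = _io.read_expression(_expression_input(config, outdir))
    hk_path = (Path(config.housekeeping_path) if config.housekeeping_path
               else outdir / "simulate" / "housekeeping.txt")
    housekeeping = [l.strip() for l in Path(hk_path).read_text().splitlines() if l.strip()]
    normalized = _io.normalize_counts(expr, housekeeping)
    _io.write_expression(normalized, outdir / "normalized.tsv", provenance=prov)


def _normalized_expression(config: PipelineConfig, outdir: Path) -> ExpressionMatrix:
    return _io.read_expression(outdir / "normalized.tsv", scale="normalized")


def _gene_sets(config: PipelineConfig, outdir: Path):
    if config.gmt_path:
        return _io.read_gmt(config.gmt_path)
    return _io.read_gmt(outdir / "simulate" / "catalog.gmt")


def _stage_ssgsea(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    expr = _normalized_expression(config, outdir)
    enr = score_all(expr, _gene_sets(config, outdir), config.enrichment)
    _write_csv(_enrichment_to_long(enr), outdir / "enrichment.tsv", prov, sep="\t")
    _write_csv(enr.nes, outdir / "nes_matrix.tsv", prov, sep="\t", index=True,
               index_label="set_id")


def _read_nes(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "nes_matrix.tsv", sep="\t", index_col=0, comment="#")


def _stage_deconvolve(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    expr = _normalized_expression(config, outdir)
    sig_path = (Path(config.signature_path) if config.signature_path
                else outdir / "simulate" / "signature.tsv")
    S = _io.read_signature(sig_path)
    fr = deconvolve_all(expr, S)
    _io.write_fractions(fr, outdir / "fractions.tsv", provenance=prov)
    diag = pd.DataFrame({"sample_id": fr.sample_ids,
                         "rmse": fr.fit_residual.to_numpy(),
                         "pearson_r": fr.correlation.to_numpy(),
                         "degenerate": fr.degenerate.to_numpy()})
    _write_csv(diag, outdir / "fractions_diagnostics.csv", prov)


def _stage_compare(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    nes = _read_nes(outdir)
    clinical = _clinical_input(config, outdir)
    labels = clinical.labels_for(list(nes.columns))
    results = screen_variables(nes.dropna(axis=0), labels, config.stats)
    _write_csv(results, outdir / "group_comparison.csv", prov)


def _stage_survive(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    nes = _read_nes(outdir).dropna(axis=0)
    clinical = _clinical_input(config, outdir)
    surv = clinical.survival_for(list(nes.columns))
    data = SurvivalData.from_clinical(surv)
    rows = []
    for var_id, row in nes.iterrows():
        vals = row.to_numpy(dtype=float)
        entry = {"variable_id": var_id}
        try:
            cox = cox_univariate(vals, data, variable_id=str(var_id))
            entry.update(cox_loghr=cox.log_hazard_ratio, cox_se=cox.se,
                         cox_p=cox.p_value, cox_converged=cox.converged)
        except ValueError as exc:
            entry.update(cox_loghr=np.nan, cox_se=np.nan, cox_p=np.nan,
                         cox_converged=False)
            logger.warning("Cox failed for %r: %s", var_id, exc)
        try:
            split = split_by_quantiles(vals, mode=config.survive_mode)
            grouped = SurvivalData(time=data.time, event=data.event,
                                   group=split.assignment)
            chi2_stat, df_, p = logrank_test(grouped)
            entry.update(logrank_chi2=chi2_stat, logrank_df=df_, logrank_p=p)
        except ValueError as exc:
            entry.update(logrank_chi2=np.nan, logrank_df=np.nan, logrank_p=np.nan)
            logger.warning("log-rank failed for %r: %s", var_id, exc)
        rows.append(entry)
    _write_csv(pd.DataFrame(rows), outdir / "survival_screen.csv", prov)
    km = km_estimate(data)
    _write_csv(km.as_frame(), outdir / "km_overall.csv", prov)


def _stage_score(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    nes = _read_nes(outdir)
    clinical = _clinical_input(config, outdir)
    variables = config.model_variables or _catalog.default_model_variables()
    variables = tuple(v for v in variables if v in nes.index and not nes.loc[v].isna().any())
    if len(variables) < 2:
        raise ValueError("fewer than 2 model variables available in the enrichment matrix")
    enr = EnrichmentMatrix(raw_es=nes, nes=nes, empirical_p=nes * np.nan,
                           effective_set_size=pd.Series(0, index=nes.index))
    sc = compute_model_score(enr, ModelConfig(variable_ids=variables))
    labels = clinical.labels_for(list(sc.model_score.index))
    cut = roc_cutpoint(sc.model_score, labels)
    calls = classify(sc.model_score, cut.cutpoint)
    frozen = FrozenModel(medians=sc.cohort_medians, cutpoint=cut.cutpoint)
    frozen.to_json(outdir / "frozen_model.json")
    out = pd.DataFrame({"sample_id": sc.model_score.index,
                        "model_score": sc.model_score.to_numpy(),
                        "risk_class": calls, "outcome": labels})
    _write_csv(out, outdir / "model_scores.csv", prov)
    summary = {"cutpoint": cut.cutpoint, "sensitivity": cut.sensitivity,
               "specificity": cut.specificity, "youden_j": cut.youden_j,
               "accuracy": cut.accuracy, "n_variables": len(variables)}
    (outdir / "model_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_report(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    make_report(outdir)


_STAGE_FNS = {"simulate": _stage_simulate, "normalize": _stage_normalize,
              "ssgsea": _stage_ssgsea, "deconvolve": _stage_deconvolve,
              "compare": _stage_compare, "survive": _stage_survive,
              "score": _stage_score, "report": _stage_report}


def make_report(run_dir: str | Path) -> str:
    """Summarize a run directory into ``report.txt``; regeneration is idempotent.

    Partial runs are summarized with the missing stages flagged.
    """
    run_dir = Path(run_dir)
    if not run_dir.exists() or not any(run_dir.iterdir()):
        raise FileNotFoundError(f"run directory empty or missing: {run_dir}")
    lines = ["tumor-microenvironment pipeline report", "=" * 40]
    gaps = []

    comp = run_dir / "group_comparison.csv"
    if comp.exists():
        df = pd.read_csv(comp, comment="#")
        n_sig = int(df["significant"].sum()) if "significant" in df else 0
        lines.append(f"group comparison: {len(df)} variables screened, "
                     f"{n_sig} significant at alpha=0.05")
        top = df.head(5)
        for _, r in top.iterrows():
            lines.append(f"  {r['variable_id']}: p={r['p_value']:.3g} "
                         f"({r['test_used']}, {r['direction']})")
    else:
        gaps.append("group_comparison.csv")

    frac = run_dir / "fractions.tsv"
    if frac.exists():
        fr = pd.read_csv(frac, sep="\t", index_col=0, comment="#")
        lines.append(f"deconvolution fingerprint: {fr.shape[0]} cell types x "
                     f"{fr.shape[1]} samples")
        means = fr.mean(axis=1).sort_values(ascending=False)
        for ct, v in means.head(5).items():
            lines.append(f"  mean fraction {ct}: {v:.3f}")
    else:
        gaps.append("fractions.tsv")

    ss = run_dir / "survival_screen.csv"
    if ss.exists():
        df = pd.read_csv(ss, comment="#")
        n_sig = int((df["logrank_p"] < 0.05).sum())
        lines.append(f"survival screen: {len(df)} variables, {n_sig} with "
                     f"log-rank p < 0.05")
    else:
        gaps.append("survival_screen.csv")

    ms = run_dir / "model_summary.json"
    if ms.exists():
        summary = json.loads(ms.read_text())
        lines.append(
            "prognostic model: accuracy {accuracy:.1%}, sensitivity {sensitivity:.1%}, "
            "specificity {specificity:.1%} at cutpoint {cutpoint:.4f} "
            "({n_variables} variables)".format(**summary))
    else:
        gaps.append("model_summary.json")

    if gaps:
        lines.append("missing stage outputs: " + ", ".join(gaps))
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
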