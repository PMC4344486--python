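"""Configuration-driven orchestration of the full synthetic pipeline.

``run`` executes the five analysis stages (exchange kinetics, granule
quantification, qPCR decay, array decay slopes, steady-state fold-change
classification) on synthetic data with a single global seed, writing plain
CSV/JSON outputs plus a provenance record to a run directory. Reruns with the
same config and seed are byte-identical. ``report`` renders a markdown summary
from a completed run directory.

Each stage draws its randomness from a named substream of the global seed, so
changing one stage's parameters does not perturb another stage's data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (DecayTruth, FieldSpec, TimecourseSpec, gen_ct_table,
                        gen_conversion_trace, gen_decay_matrix, gen_frap_trace,
                        gen_steady_state_matrix, gen_stress_timecourse, preset_truth)
from .granules import DetectionParams, PositiveRule, quantify_field, summarize_conditions
from .kinetics import (classify_dynamics, fit_conversion, fit_recovery,
                       flux_balance_check, normalize_trace)
from .qpcr import condition_contrast, relative_abundance_ddct, relative_abundance_dct
from .array_decay import (background_correct, classify_fold_change, decay_slopes,
                          filter_reliable, slope_correlation)
from .io import write_csv

logger = logging.getLogger(__name__)

ALL_STAGES = ("kinetics", "granules", "qpcr", "array_decay", "fold_change")

# substream indices per stage (stable across releases)
_STAGE_STREAM = {name: i + 1 for i, name in enumerate(ALL_STAGES)}


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass(frozen=True)
class KineticsConfig:
    n_traces_per_class: int = 10
    noise_sd: float = 0.02
    acquisition_bleach_rate: float = 0.01


@dataclass(frozen=True)
class GranulesConfig:
    times: tuple[float, ...] = (30.0, 120.0)
    n_fields_per_point: int = 3
    n_cells: int = 5
    gaussian_sd: float = 2.0


@dataclass(frozen=True)
class QpcrConfig:
    n_genes: int = 5
    replicates: int = 3
    ct_noise_sd: float = 0.15
    reference_gene: str = "RPLP0"
    times: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class ArrayConfig:
    n_transcripts: int = 600
    replicates: int = 2
    alpha: float = 0.001
    fold_mode: str = "chebyshev"


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    granules: GranulesConfig = field(default_factory=GranulesConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    array: ArrayConfig = field(default_factory=ArrayConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v, f"{path}.{f.name}")
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a (YAML-loaded) dict, rejecting unknown keys."""
    data = dict(data or {})
    sub = {
        "kinetics": KineticsConfig, "granules": GranulesConfig,
        "qpcr": QpcrConfig, "array": ArrayConfig,
    }
    kwargs: dict = {}
    for key, cls in sub.items():
        if key in data:
            kwargs[key] = _build(cls, data.pop(key) or {}, key)
    top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "stages" in data:
        kwargs["stages"] = tuple(data.pop("stages"))
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{_STAGE_STREAM[stage]}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_kinetics(cfg: RunConfig, outdir: Path) -> None:
    kc = cfg.kinetics
    seed = _stage_seed(cfg, "kinetics")
    rows, balance_rows = [], []
    for ci, class_label in enumerate(("transient", "stable")):
        for i in range(kc.n_traces_per_class):
            fr_truth = preset_truth(class_label, "frap", noise_sd=kc.noise_sd,
                                    seed=seed + 1000 * ci + 2 * i,
                                    acquisition_bleach_rate=kc.acquisition_bleach_rate)
            cv_truth = preset_truth(class_label, "conversion", noise_sd=kc.noise_sd,
                                    seed=seed + 1000 * ci + 2 * i + 1,
                                    acquisition_bleach_rate=kc.acquisition_bleach_rate)
            frap_fit = fit_recovery(normalize_trace(gen_frap_trace(fr_truth)))
            conv_fit = fit_conversion(normalize_trace(gen_conversion_trace(cv_truth).red))
            for fit, kind in ((frap_fit, "frap"), (conv_fit, "conversion")):
                label = classify_dynamics(fit).label
                rows.append({
                    "trace": f"{class_label}_{kind}_{i}", "true_class": class_label,
                    "kind": kind, "k_per_s": fit.k, "t_half_s": fit.t_half,
                    "mobile_fraction": fit.mobile_fraction,
                    "immobile_fraction": fit.immobile_fraction,
                    "retained_fraction_30s": fit.retained_fraction_30s,
                    "r_squared": fit.r_squared, "converged": fit.converged,
                    "flags": ";".join(fit.flags), "class": label,
                })
            rep = flux_balance_check(frap_fit, conv_fit)
            balance_rows.append({
                "trace": f"{class_label}_{i}", "t_half_frap_s": rep.t_half_frap,
                "t_half_conversion_s": rep.t_half_conversion,
                "rel_difference": rep.rel_difference, "balanced": rep.balanced,
            })
    write_csv(pd.DataFrame(rows), outdir / "kinetics_fits.csv")
    write_csv(pd.DataFrame(balance_rows), outdir / "kinetics_flux_balance.csv")


def _stage_granules(cfg: RunConfig, outdir: Path) -> None:
    gc = cfg.granules
    seed = _stage_seed(cfg, "granules")
    tspec = TimecourseSpec(times=gc.times, n_fields_per_point=gc.n_fields_per_point,
                           seed=seed)
    fspec = FieldSpec(n_cells=gc.n_cells, gaussian_sd=gc.gaussian_sd, seed=seed)
    fields = gen_stress_timecourse(tspec, fspec)
    per_cell = pd.concat([quantify_field(f) for f in fields.values()], ignore_index=True)
    write_csv(per_cell, outdir / "granules_per_cell.csv")
    write_csv(summarize_conditions(per_cell), outdir / "granules_summary.csv")


def _stage_qpcr(cfg: RunConfig, outdir: Path) -> None:
    qc = cfg.qpcr
    seed = _stage_seed(cfg, "qpcr")
    truth = DecayTruth(n_transcripts=qc.n_genes, times=qc.times,
                       replicates_per_point=qc.replicates, ct_noise_sd=qc.ct_noise_sd,
                       seed=seed)
    table = gen_ct_table(truth, reference_gene=qc.reference_gene)
    write_csv(table, outdir / "qpcr_ct.csv")
    ddct = relative_abundance_ddct(table, qc.reference_gene)
    write_csv(ddct, outdir / "qpcr_abundance_ddct.csv")
    write_csv(relative_abundance_dct(table), outdir / "qpcr_abundance_dct.csv")
    reps = relative_abundance_ddct(table, qc.reference_gene, collapse_replicates=False)
    tests = condition_contrast(reps, groups=truth.conditions[:2])
    write_csv(tests, outdir / "qpcr_contrasts.csv")


def _stage_array_decay(cfg: RunConfig, outdir: Path) -> dict:
    ac = cfg.array
    seed = _stage_seed(cfg, "array_decay")
    truth = DecayTruth(n_transcripts=ac.n_transcripts, replicates_per_point=ac.replicates,
                       seed=seed)
    matrix, truth_slopes = gen_decay_matrix(truth)
    kept = filter_reliable(matrix, alpha=ac.alpha)
    corrected, offsets = background_correct(matrix)
    # slopes are fitted on the background-corrected scale, on which the
    # generative truth slopes are defined; quantile normalization is for
    # real data with per-sample technical distribution shifts, which the
    # generator does not produce (see docs/methods.md)
    slopes = decay_slopes(corrected, transcripts=kept)
    write_csv(slopes, outdir / "array_decay_slopes.csv")
    write_csv(truth_slopes, outdir / "array_truth_slopes.csv")
    conds = list(truth.conditions)
    r_between, paired = slope_correlation(
        slopes[slopes["condition"] == conds[0]], slopes[slopes["condition"] == conds[1]])
    paired.index.name = "transcript"
    write_csv(paired.reset_index(), outdir / "array_slope_pairs.csv")
    recovery = {}
    for cond in conds:
        fitted = slopes[slopes["condition"] == cond].set_index("transcript")["slope"]
        true = truth_slopes[truth_slopes["condition"] == cond].set_index("transcript")["slope"]
        r, _ = slope_correlation(fitted, true)
        recovery[cond] = r
    report = {"n_reliable": len(kept), "n_total": ac.n_transcripts,
              "pearson_r_between_conditions": r_between,
              "pearson_r_vs_truth": recovery}
    (outdir / "array_correlation.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_fold_change(cfg: RunConfig, outdir: Path) -> None:
    ac = cfg.array
    seed = _stage_seed(cfg, "fold_change")
    truth = DecayTruth(n_transcripts=ac.n_transcripts, replicates_per_point=ac.replicates,
                       seed=seed)
    matrix, planted = gen_steady_state_matrix(truth)
    records, class_counts, quadrants = classify_fold_change(matrix, mode=ac.fold_mode)
    write_csv(records, outdir / "fold_change.csv")
    write_csv(planted, outdir / "fold_change_planted.csv")
    summary = {"class_counts": class_counts, "quadrant_counts": quadrants,
               "n_transcripts": int(len(records))}
    (outdir / "fold_change_counts.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


_STAGE_FUNCS = {
    "kinetics": _stage_kinetics,
    "granules": _stage_granules,
    "qpcr": _stage_qpcr,
    "array_decay": _stage_array_decay,
    "fold_change": _stage_fold_change,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages into ``outdir``; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    provenance = {
        "sgdyn_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "stages": list(config.stages),
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=list))
    return outdir


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _md_table(df: pd.DataFrame, max_rows: int | None = None) -> str:
    if max_rows is not None and len(df) > max_rows:
        df = df.head(max_rows)
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.4g}")
    header = "| " + " | ".join(map(str, out.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(out.columns)) + "|"
    body = ["| " + " | ".join(map(str, row)) + " |" for row in out.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def report(run_dir: str | Path) -> str:
    """Render a markdown summary of a run directory; returns the report text."""
    run_dir = Path(run_dir)
    if not run_dir.is_dir() or not any(run_dir.iterdir()):
        raise FileNotFoundError(f"empty or missing run directory: {run_dir}")
    parts = ["# sgdyn run report", ""]
    prov = run_dir / "provenance.json"
    if prov.exists():
        meta = json.loads(prov.read_text())
        parts.append(f"seed {meta['seed']}, config hash `{meta['config_hash']}`, "
                     f"sgdyn {meta['sgdyn_version']}")
        parts.append("")
    sections = [
        ("granules_summary.csv", "## SG formation over the stress time course", None),
        ("kinetics_fits.csv", "## Exchange-kinetics fits", None),
        ("kinetics_flux_balance.csv", "## In/out flux balance (FRAP vs conversion)", None),
        ("qpcr_abundance_ddct.csv", "## qPCR relative abundance (ddCt)", 20),
        ("qpcr_contrasts.csv", "## qPCR condition contrasts", 20),
        ("array_decay_slopes.csv", "## Array decay slopes (first rows)", 10),
    ]
    for fname, heading, max_rows in sections:
        path = run_dir / fname
        if not path.exists():
            parts.append(f"_{fname} not present; stage skipped or incomplete._")
            parts.append("")
            continue
        parts.append(heading)
        parts.append("")
        parts.append(_md_table(pd.read_csv(path), max_rows))
        parts.append("")
    corr = run_dir / "array_correlation.json"
    if corr.exists():
        data = json.loads(corr.read_text())
        parts.append("## Bulk-decay slope correlation")
        parts.append("")
        parts.append(f"- reliably detected transcripts: {data['n_reliable']} / {data['n_total']}")
        parts.append(f"- Pearson r between conditions: {data['pearson_r_between_conditions']:.4f}")
        for cond, r in data["pearson_r_vs_truth"].items():
            parts.append(f"- Pearson r vs generative slopes ({cond}): {r:.4f}")
        parts.append("")
    counts = run_dir / "fold_change_counts.json"
    if counts.exists():
        data = json.loads(counts.read_text())
        parts.append("## Fold-change scatter classes")
        parts.append("")
        for cls, n in data["class_counts"].items():
            parts.append(f"- {cls}: {n}")
        parts.append(f"- quadrant counts (>=2-fold): {data['quadrant_counts']}")
        parts.append("")
    text = "\n".join(parts)
    (run_dir / "report.md").write_text(text)
    return text
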