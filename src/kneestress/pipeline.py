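"""Study orchestration: generate -> frames -> measure3d -> measure2d -> stats.

``run_study`` executes the whole synthetic study from one seed: phantom
generation, per-cell 3D and 2D measurements (the 2D stage is read twice by
simulated readers with independent tangent-placement jitter), delta
referencing against the ACL-intact unloaded cell, per-measure RM-ANOVA with
Tukey post-hoc, two-reader ICC on the 2D measures, Pearson correlations
between selected 3D and 2D measures, and violin-plot figures.  Reruns with
the same config and seed are bit-identical.
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
from .errors import DesignError
from .kinematics import MEASURES_3D, compute_cell
from .phantom import ConditionEffect, PhantomSpec, generate_study
from .reference2d import MEASURES_2D, compute_cell_2d
from .stats import (
    compute_deltas,
    icc_two_readers,
    pearson,
    required_sample_size,
    rm_anova_tukey,
)
from .volume_io import (
    CONDITIONS,
    CONFIGURATIONS,
    ManifestRecord,
    read_annotations,
    read_volume,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Study-level configuration; flags override the config file."""

    outdir: str = "study_out"
    seed: int = 0
    # phantom
    n_specimens: int = 10
    spacing_mm: tuple[float, float, float] = (0.36, 0.36, 3.3)
    volume_shape: tuple[int, int, int] = (224, 288, 48)
    effect_means_mm: dict[str, float] = field(
        default_factory=lambda: {"intact": 2.5, "partial": 8.1, "complete": 12.6})
    effect_sds_mm: dict[str, float] = field(
        default_factory=lambda: {"intact": 1.0, "partial": 3.0, "complete": 3.0})
    rotation_means_deg: dict[str, float] = field(
        default_factory=lambda: {"intact": 0.0, "partial": 4.0, "complete": 2.0})
    rotation_sds_deg: dict[str, float] = field(
        default_factory=lambda: {"intact": 1.0, "partial": 1.5, "complete": 1.5})
    noise_sd_mm: float = 0.5
    meniscus_attachment: str = "tibia"
    # geometry
    mode: str = "estimated"  # or "annotated"
    shaft_fraction: float = 0.5
    angle_eps: float = 0.1
    # 2D readers
    reader_noise_sd_mm: float = 0.3
    # stats
    significance_threshold: float = 0.01
    sphericity_correction: bool = False
    delta_reference: str = "intact_d0"
    correlation_pairs: tuple[tuple[str, str], ...] = (
        ("y_ABI", "LTP_LFC"), ("y_ABI", "LMD"))
    # report rounding (display only): 0.1 mm for distances, 1 deg for angles
    round_mm: float = 0.1
    round_deg: float = 1.0

    def phantom_spec(self) -> PhantomSpec:
        effects = {
            c: ConditionEffect(self.effect_means_mm[c], self.effect_sds_mm[c],
                               self.rotation_means_deg[c], self.rotation_sds_deg[c])
            for c in CONDITIONS}
        return PhantomSpec(
            n_specimens=self.n_specimens,
            spacing_mm=tuple(self.spacing_mm),
            volume_shape=tuple(self.volume_shape),
            condition_effects=effects,
            noise_sd_mm=self.noise_sd_mm,
            seed=self.seed,
            meniscus_attachment=self.meniscus_attachment,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DesignError(f"unknown config keys: {sorted(unknown)}")
        if "correlation_pairs" in raw:
            raw["correlation_pairs"] = tuple(tuple(p) for p in raw["correlation_pairs"])
        for key in ("spacing_mm", "volume_shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["spacing_mm"] = list(d["spacing_mm"])
        d["volume_shape"] = list(d["volume_shape"])
        d["correlation_pairs"] = [list(p) for p in d["correlation_pairs"]]
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Measurement over a manifest
# ---------------------------------------------------------------------------

def check_design(records: list[ManifestRecord]) -> None:
    """Every specimen must contribute all six condition x configuration cells."""
    cells: dict[str, set] = {}
    for rec in records:
        cells.setdefault(rec.specimen, set()).add((rec.condition, rec.configuration))
    expected = {(c, g) for c in CONDITIONS for g in CONFIGURATIONS}
    for specimen, have in sorted(cells.items()):
        if have != expected:
            missing = sorted(expected - have)
            raise DesignError(f"specimen {specimen}: missing study cells {missing}")


def measure_manifest_3d(records: list[ManifestRecord], config: PipelineConfig) -> pd.DataFrame:
    """Long-format table of the eleven 3D measures per manifest cell."""
    rows = []
    for rec in records:
        volume = read_volume(rec.volume_path)
        ann = read_annotations(rec.annotation_path)
        try:
            kin = compute_cell(volume, ann, side=rec.side, mode=config.mode,
                               shaft_fraction=config.shaft_fraction, eps=config.angle_eps)
        except Exception as exc:
            raise type(exc)(
                f"cell ({rec.specimen}, {rec.condition}, {rec.configuration}): {exc}"
            ) from exc
        for measure in MEASURES_3D:
            rows.append({"specimen": rec.specimen, "condition": rec.condition,
                         "configuration": rec.configuration, "measure": measure,
                         "value": getattr(kin, measure),
                         "flag": bool(kin.flags.get(measure, False))})
    return pd.DataFrame(rows)


def measure_manifest_2d(records: list[ManifestRecord], config: PipelineConfig,
                        readers: tuple[str, ...] = ("A", "B")) -> pd.DataFrame:
    """Long-format table of the four 2D measures per cell and simulated reader."""
    rows = []
    for cell_idx, rec in enumerate(records):
        volume = read_volume(rec.volume_path)
        ann = read_annotations(rec.annotation_path)
        for reader_idx, reader in enumerate(readers):
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=config.seed, spawn_key=(97, cell_idx, reader_idx)))
            try:
                ref = compute_cell_2d(volume, side=rec.side, annotations=ann,
                                      reader_noise_sd=config.reader_noise_sd_mm, rng=rng)
            except Exception as exc:
                raise type(exc)(
                    f"cell ({rec.specimen}, {rec.condition}, {rec.configuration}): {exc}"
                ) from exc
            for measure in MEASURES_2D:
                rows.append({"specimen": rec.specimen, "condition": rec.condition,
                             "configuration": rec.configuration, "measure": measure,
                             "value": getattr(ref, measure), "reader": reader,
                             "flag": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics + report
# ---------------------------------------------------------------------------

def analyse_study(table_3d: pd.DataFrame, table_2d: pd.DataFrame,
                  config: PipelineConfig) -> dict:
    """Delta referencing and the full statistical stage; returns the report dict."""
    study = pd.concat([table_3d.drop(columns="flag"),
                       table_2d.drop(columns="flag")], ignore_index=True)
    deltas = compute_deltas(study, reference=config.delta_reference)

    anova = {}
    for measure in list(MEASURES_3D) + list(MEASURES_2D):
        res = rm_anova_tukey(study, measure, threshold=config.significance_threshold,
                             sphericity_correction=config.sphericity_correction)
        anova[measure] = {
            "F": res.f_value, "p": res.p_value, "significant": res.significant,
            "df_effect": res.df_effect, "df_error": res.df_error,
            "cell_means": res.cell_means,
            "tukey": res.tukey.to_dict(orient="records"),
        }

    delta_means = (deltas.groupby(["measure", "condition", "configuration"])["value"]
                   .mean().reset_index())

    icc = {}
    wide_2d = table_2d.pivot_table(
        index=["specimen", "condition", "configuration", "measure"],
        columns="reader", values="value").reset_index()
    for measure in MEASURES_2D:
        sub = wide_2d[wide_2d["measure"] == measure]
        icc[measure] = icc_two_readers(sub["A"].to_numpy(), sub["B"].to_numpy())

    correlations = {}
    pooled = deltas.copy()
    if "reader" in pooled.columns:
        pooled = (pooled.groupby(["specimen", "condition", "configuration", "measure"],
                                 as_index=False)["value"].mean())
    wide = pooled.pivot(index=["specimen", "condition", "configuration"],
                        columns="measure", values="value")
    for a, b in config.correlation_pairs:
        correlations[f"{a}_vs_{b}"] = pearson(wide[a].to_numpy(), wide[b].to_numpy())

    return {
        "anova": anova,
        "delta_means": delta_means.to_dict(orient="records"),
        "icc": icc,
        "pearson": correlations,
        "power": {"power": 0.8, "alpha": 0.05, "effect_size_d": 1.6, "tails": "two",
                  "required_n_per_group": required_sample_size(0.8, 0.05, 1.6, "two")},
    }


def _violin_figures(study: pd.DataFrame, outdir: Path,
                    measures=("length_ABI", "length_landmarks", "y_ABI", "y_landmarks")):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    cells = [(c, g) for c in CONDITIONS for g in CONFIGURATIONS]
    for measure in measures:
        sub = study[study["measure"] == measure]
        data = [sub[(sub["condition"] == c) & (sub["configuration"] == g)]["value"].to_numpy()
                for c, g in cells]
        fig, ax = plt.subplots(figsize=(6, 4))
        parts = ax.violinplot(data, showmedians=True, showextrema=False, quantiles=[
            [0.25, 0.75]] * len(data))
        parts["cmedians"].set_linestyle("solid")
        parts["cquantiles"].set_linestyle("dotted")
        ax.set_xticks(range(1, len(cells) + 1))
        ax.set_xticklabels([f"{c}\n{'d0' if g == 'd0' else 'd1'}" for c, g in cells],
                           fontsize=8)
        ax.set_ylabel(f"{measure} [{'deg' if 'angle' in measure else 'mm'}]")
        ax.set_title(measure)
        fig.tight_layout()
        fig.savefig(outdir / f"violin_{measure}.png", dpi=120)
        plt.close(fig)


@dataclass
class StudyReport:
    outdir: Path
    report: dict
    table_3d: pd.DataFrame
    table_2d: pd.DataFrame
    deltas: pd.DataFrame


def run_study(config: PipelineConfig, make_figures: bool = True) -> StudyReport:
    """Execute the full synthetic study; outputs land under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run_study: seed=%d config_hash=%s", config.seed, config.config_hash())

    records, _gt = generate_study(config.phantom_spec(), outdir / "phantom")
    check_design(records)

    table_3d = measure_manifest_3d(records, config)
    table_2d = measure_manifest_2d(records, config)
    table_3d.to_csv(outdir / "measures_3d.csv", index=False, float_format="%.6f")
    table_2d.to_csv(outdir / "measures_2d.csv", index=False, float_format="%.6f")

    study = pd.concat([table_3d.drop(columns="flag"),
                       table_2d.drop(columns="flag")], ignore_index=True)
    deltas = compute_deltas(study, reference=config.delta_reference)
    deltas.to_csv(outdir / "deltas.csv", index=False, float_format="%.6f")

    report = analyse_study(table_3d, table_2d, config)
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
    pd.DataFrame([
        {"measure": m, "F": v["F"], "p": v["p"], "significant": v["significant"]}
        for m, v in report["anova"].items()
    ]).to_csv(outdir / "anova_summary.csv", index=False, float_format="%.6g")

    if make_figures:
        _violin_figures(study, outdir / "figures")

    run_log = {"seed": config.seed, "config_hash": config.config_hash(),
               "version": __version__, "n_cells": len(records),
               "config": yaml.safe_load(config.to_yaml())}
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return StudyReport(outdir=outdir, report=report, table_3d=table_3d,
                       table_2d=table_2d, deltas=deltas)
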