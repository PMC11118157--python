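"""End-to-end orchestration: cohort in, report bundle out.

A run loads a cohort (packaged study data, CSV triplet, or simulation),
builds the per-course change tables, computes every requested
correlation matrix (whole-cohort and subgroups) with n / rho / p /
stars, writes per-patient selection reports, and records a
machine-readable manifest (config, seed, package version) so reruns are
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .association import (
    benjamini_hochberg,
    build_change_frames,
    correlation_matrix,
    export_heatmap_table,
    plot_heatmap,
    subgroup_analyses,
)
from .fixture import load_study_cohort
from .indices import FIXTURE_INDICES, build_index_change_table, change_table_frame
from .io import read_cohort_csv
from .model import CohortDataset
from .selection import rank_biologics
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("psoriscreen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    input_source: str = "fixture"  # "fixture" | "csv" | "simulate"
    csv_paths: Optional[tuple[str, str, str]] = None
    simulation: Optional[SimulationConfig] = None
    indices: tuple[str, ...] = FIXTURE_INDICES
    modes: tuple[str, ...] = ("rate", "difference")
    subgroups: tuple[str, ...] = ()  # subset of {"by_biologic", "by_disease"}
    output_dir: str = "psoriscreen_out"
    significance_thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)
    bh_correct: bool = False
    heatmaps: bool = False
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.input_source not in ("fixture", "csv", "simulate"):
            raise ValueError(f"unknown input_source {self.input_source!r}")
        if self.input_source == "csv" and not self.csv_paths:
            raise ValueError("csv input requires the three csv paths")
        if not self.modes or not set(self.modes) <= {"rate", "difference"}:
            raise ValueError("modes must be a non-empty subset of {rate, difference}")
        if not set(self.subgroups) <= {"by_biologic", "by_disease"}:
            raise ValueError("subgroups must be within {by_biologic, by_disease}")
        a, b, c = self.significance_thresholds
        if not a > b > c > 0:
            raise ValueError("significance thresholds must be strictly decreasing")


def _load(cfg: RunConfig) -> CohortDataset:
    if cfg.input_source == "fixture":
        return load_study_cohort()
    if cfg.input_source == "csv":
        return read_cohort_csv(*cfg.csv_paths)
    sim = cfg.simulation or SimulationConfig()
    if cfg.seed is not None:
        sim.seed = cfg.seed
    return simulate_cohort(sim)


def _matrix_files(matrix, out: Path, tag: str, heatmaps: bool, bh: bool) -> list[str]:
    written = []
    long = export_heatmap_table(matrix)
    if bh and long["p_value"].notna().any():
        mask = long["p_value"].notna()
        long.loc[mask, "q_value_bh"] = benjamini_hochberg(list(long.loc[mask, "p_value"]))
    f_long = out / f"correlations_{tag}_long.csv"
    long.to_csv(f_long, index=False)
    written.append(f_long.name)
    f_wide = out / f"correlations_{tag}_rho.csv"
    matrix.to_wide_frame("rho").to_csv(f_wide)
    written.append(f_wide.name)
    if heatmaps:
        f_png = out / f"heatmap_{tag}.png"
        plot_heatmap(matrix, f_png)
        written.append(f_png.name)
    return written


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _load(cfg)
    log.info("cohort: %d patients, %d courses, %d assay rows",
             len(ds.patients), len(ds.courses), len(ds.assays))

    written: list[str] = []
    records = build_index_change_table(ds, cfg.indices)
    f = out / "index_changes.csv"
    change_table_frame(records).to_csv(f, index=False)
    written.append(f.name)

    frames = build_change_frames(ds, cfg.indices)
    for mode in cfg.modes:
        frame = frames[mode]
        f = out / f"changes_{mode}.csv"
        frame.to_csv(f, index=False)
        written.append(f.name)
        m = correlation_matrix(frame, mode)
        written += _matrix_files(m, out, mode, cfg.heatmaps, cfg.bh_correct)

    for grouping in cfg.subgroups:
        for m in subgroup_analyses(ds, grouping, cfg.indices):
            if m.mode not in cfg.modes:
                continue
            tag = f"{m.mode}_{m.subgroup.replace('+', 'p').replace(' ', '_')}"
            written += _matrix_files(m, out, tag, cfg.heatmaps, cfg.bh_correct)

    failures: list[str] = []
    sel_dir = out / "selection"
    sel_dir.mkdir(exist_ok=True)
    for pid in ds.patient_ids():
        if len(ds.courses_for(pid)) < 2:
            continue
        try:
            report = rank_biologics(ds, pid, cfg.indices)
        except ValueError as exc:  # e.g. fully censored panels
            failures.append(f"selection {pid}: {exc}")
            continue
        fp = sel_dir / f"{pid}.json"
        fp.write_text(report.to_json(), encoding="utf-8")
        written.append(f"selection/{fp.name}")

    cfg_doc = {
        "input_source": cfg.input_source,
        "indices": list(cfg.indices),
        "modes": list(cfg.modes),
        "subgroups": list(cfg.subgroups),
        "significance_thresholds": list(cfg.significance_thresholds),
        "bh_correct": cfg.bh_correct,
        "seed": cfg.seed,
    }
    manifest = {
        "package": "psoriscreen",
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg_doc,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_doc, sort_keys=True).encode()
        ).hexdigest(),
        "cohort": {
            "patients": len(ds.patients),
            "courses": len(ds.courses),
            "assays": len(ds.assays),
        },
        "outputs": written,
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
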