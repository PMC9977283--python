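"""Config-driven end-to-end runs.

A :class:`RunConfig` (usually loaded from YAML) names the stages to execute,
the analysis thresholds, a single global seed, and an output directory.  The
pipeline executes stages in dependency order::

    simulate -> screen -> celltype -> cutrun -> stereology -> qpcr

The ``simulate`` stage writes every downstream input under
``<out_dir>/inputs`` using the same on-disk formats the analysis stages read,
so later stages exercise the full read path.  Each stage draws its
randomness from a child seed derived deterministically from the global seed
and the stage name, so a rerun with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltype as ct
from . import cutrun as cr
from . import io as dio
from . import qpcr, screen, stereology, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "celltype", "cutrun", "stereology", "qpcr")

try:
    __version__ = version("dosagescreen")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


class ConfigError(ValueError):
    """Invalid run configuration (distinct exit code in the CLI)."""


_THRESHOLD_RANGES = {
    "rho_threshold": (0.0, 1.0),
    "pli_min": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "marker_min": (0, 1_000_000),
    "halfwidth": (1, 10_000_000),
    "spike_constant": (0.0, float("inf")),
    "pseudocount": (0.0, float("inf")),
}

_KNOWN_KEYS = {"seed", "out_dir", "stages", "thresholds"}


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    rho_threshold: float = 0.75
    pli_min: float = 0.9
    alpha: float = 0.1
    halfwidth: int = 3500
    marker_min: int = 5
    spike_constant: float = 10_000.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ConfigError(f"{name}={val} outside allowed range [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        thresholds = raw.get("thresholds", {}) or {}
        unknown_t = set(thresholds) - set(_THRESHOLD_RANGES)
        if unknown_t:
            raise ConfigError(f"{path}: unknown threshold(s): {sorted(unknown_t)}")
        return cls(
            out_dir=raw.get("out_dir", "dosagescreen_out"),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", STAGES)),
            **thresholds,
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed below 2**31, independent of stage order."""
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StageReport:
    name: str
    status: str
    n_in: int = 0
    n_out: int = 0
    warnings: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


@dataclass
class RunReport:
    seed: int
    software_version: str
    stages: list[StageReport] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "software_version": self.software_version,
            "stages": [
                {
                    "name": s.name,
                    "status": s.status,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "warnings": s.warnings,
                    "params": s.params,
                }
                for s in self.stages
            ],
        }


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _stage_simulate(cfg: RunConfig, inputs: Path, written: list[Path]) -> StageReport:
    inputs.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("simulate")

    tc, prot, tc_truth = synthetic.simulate_timecourse(seed=seed)
    dio.write_timecourse(tc, inputs / "timecourse.tsv")
    dio.write_protein(prot, inputs / "protein.tsv")
    pli, _ = synthetic.simulate_constraint_table(
        tc.gene_ids, constrained_genes=sorted(tc_truth.tracking_genes), seed=seed + 1
    )
    dio.write_pli(pli, inputs / "pli.tsv")
    # the panel's robust gene is the screen's top planted tracker
    robust = sorted(tc_truth.tracking_genes)[0]
    panel, _ = synthetic.simulate_study_panel(
        n_genes=len(tc.gene_ids), robust_gene=robust, seed=seed + 2
    )
    dio.write_panel(panel, inputs / "panel")

    counts, annotation, _ = synthetic.simulate_cells(seed=seed + 3)
    dio.write_counts_mtx(counts, inputs / "cells")
    dio.write_annotation(annotation, inputs / "annotation.tsv")

    peaks = [("chr1", 199_900, 200_100), ("chr1", 499_800, 500_200), ("chr1", 799_900, 800_100)]
    windows = [
        cr.expand_peak(c, s, e, halfwidth=cfg.halfwidth, window_id=f"w{i + 1}")
        for i, (c, s, e) in enumerate(peaks)
    ]
    genotypes = {f"WT_{i}": "WT" for i in range(1, 7)}
    genotypes.update({f"KO_{i}": "KO" for i in range(1, 4)})
    genotypes.update({f"TG_{i}": "TG" for i in range(1, 4)})
    enrichment = {"w1": {"WT": 8.0, "KO": 0.05, "TG": 16.0}}
    frags, libs, _ = synthetic.simulate_fragments(
        windows, genotypes, enrichment=enrichment, seed=seed + 4
    )
    dio.write_fragments(frags, inputs / "fragments.tsv")
    dio.write_peaks_bed(windows=[cr.GenomicWindow(c, s, e, f"peak{i+1}") for i, (c, s, e) in enumerate(peaks)], path=inputs / "peaks.bed")
    dio.write_library_manifest(libs, inputs / "libraries.yaml")

    sections, areas, _ = synthetic.simulate_sections(seed=seed + 5)
    dio.write_sections(sections, areas, inputs / "sections.tsv")

    ct_table, _ = synthetic.simulate_ct_table(seed=seed + 6)
    dio.write_ct_table(ct_table, inputs / "ct.tsv")

    files = sorted(p for p in inputs.rglob("*") if p.is_file())
    written.extend(files)
    return StageReport("simulate", "ok", n_in=0, n_out=len(files), params={"seed": seed})


def _stage_screen(cfg: RunConfig, inputs: Path, out: Path, written: list[Path]) -> StageReport:
    tc = dio.read_timecourse(inputs / "timecourse.tsv")
    prot = dio.read_protein(inputs / "protein.tsv")
    pli = dio.read_pli(inputs / "pli.tsv")
    panel = dio.read_panel(inputs / "panel" / "panel.yaml")
    report = screen.run_screen(
        tc, prot, pli, panel,
        rho_threshold=cfg.rho_threshold, pli_min=cfg.pli_min, alpha=cfg.alpha,
    )
    path = out / "candidates.tsv"
    report.to_csv(path, sep="\t", index=False, float_format=dio.FLOAT_FMT)
    written.append(path)
    return StageReport(
        "screen", "ok", n_in=len(tc.gene_ids), n_out=len(report),
        params={"rho_threshold": cfg.rho_threshold, "pli_min": cfg.pli_min, "alpha": cfg.alpha},
    )


def _stage_celltype(cfg: RunConfig, inputs: Path, out: Path, written: list[Path]) -> StageReport:
    counts = dio.read_counts_mtx(inputs / "cells")
    annotation = dio.read_annotation(inputs / "annotation.tsv")
    per_class = ct.correlate_pair(counts, "Gdf11", "Mecp2", annotation)
    neurons = list(annotation.index[annotation == "neuron"])
    rows = [per_class]
    if neurons:
        split = ct.split_neurons(counts, neurons, ct.MarkerRule(min_count=cfg.marker_min))
        by_sub = ct.correlate_pair(counts, "Gdf11", "Mecp2", split)
        rows.append(by_sub.drop(index=ct.POOLED_LABEL))
    result = pd.concat(rows)
    path = out / "celltype_correlation.tsv"
    result.to_csv(path, sep="\t", float_format=dio.FLOAT_FMT)
    written.append(path)
    return StageReport(
        "celltype", "ok", n_in=counts.shape[1], n_out=len(result),
        params={"marker_min": cfg.marker_min},
    )


def _stage_cutrun(cfg: RunConfig, inputs: Path, out: Path, written: list[Path]) -> StageReport:
    frags = dio.read_fragments(inputs / "fragments.tsv")
    peaks = dio.read_peaks_bed(inputs / "peaks.bed")
    windows = [
        cr.expand_peak(c, s, e, halfwidth=cfg.halfwidth, window_id=f"w{i + 1}")
        for i, (c, s, e) in enumerate(peaks)
    ]
    meta = dio.read_library_manifest(inputs / "libraries.yaml")
    genotypes = {m["sample"]: m["genotype"] for m in meta}
    libs = cr.libraries_from_fragments(
        frags, genotypes, scale_constant=cfg.spike_constant
    )
    table = cr.count_fragments(frags, windows)
    norm = cr.normalized_occupancy(table, libs)
    occ_path = out / "occupancy.tsv"
    pd.concat({"raw": table.counts, "normalized": norm}, axis=1).to_csv(
        occ_path, sep="\t", float_format=dio.FLOAT_FMT
    )
    written.append(occ_path)
    n_out = len(table.counts)
    for pert in ("KO", "TG"):
        if pert in genotypes.values():
            diff = cr.differential_occupancy(
                table, libs, contrast=(pert, "WT"), pseudocount=cfg.pseudocount
            )
            path = out / f"differential_{pert}_vs_WT.tsv"
            diff.to_csv(path, sep="\t", float_format=dio.FLOAT_FMT)
            written.append(path)
    return StageReport(
        "cutrun", "ok", n_in=len(frags), n_out=n_out,
        params={"halfwidth": cfg.halfwidth, "spike_constant": cfg.spike_constant,
                "pseudocount": cfg.pseudocount},
    )


def _stage_stereology(cfg: RunConfig, inputs: Path, out: Path, written: list[Path]) -> StageReport:
    sections, areas = dio.read_sections(inputs / "sections.tsv")
    n = stereology.estimate_total_cells(sections)
    dens = stereology.cell_density(n, areas, sections.t, sections.ssf)
    path = out / "stereology.tsv"
    pd.DataFrame(
        [{"total_cells": n, "density_cells_per_mm3": dens, "n_sections": len(sections.q)}]
    ).to_csv(path, sep="\t", index=False, float_format=dio.FLOAT_FMT)
    written.append(path)
    return StageReport("stereology", "ok", n_in=len(sections.q), n_out=1, params={})


def _stage_qpcr(cfg: RunConfig, inputs: Path, out: Path, written: list[Path]) -> StageReport:
    table = dio.read_ct_table(inputs / "ct.tsv")
    result = qpcr.ddct_relative_expression(table, "Gdf11", "Ppia", control_group="WT")
    path = out / "qpcr_relative_expression.tsv"
    result.to_csv(path, sep="\t", float_format=dio.FLOAT_FMT)
    written.append(path)
    return StageReport("qpcr", "ok", n_in=len(table), n_out=len(result), params={})


_STAGE_FUNCS = {
    "screen": _stage_screen,
    "celltype": _stage_celltype,
    "cutrun": _stage_cutrun,
    "stereology": _stage_stereology,
    "qpcr": _stage_qpcr,
}


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured stages; returns (and writes) the run report.

    On failure, files written during this run are removed so a partial output
    tree is never left behind.
    """
    report = RunReport(seed=cfg.seed, software_version=__version__)
    out = cfg.out_dir
    inputs = out / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("dosagescreen")
    pkg_logger.addHandler(collector)
    try:
        for stage in cfg.stages:
            collector.messages = []
            if stage == "simulate":
                sr = _stage_simulate(cfg, inputs, written)
            else:
                sr = _STAGE_FUNCS[stage](cfg, inputs, out, written)
            sr.warnings = list(collector.messages)
            report.stages.append(sr)
            logger.info("stage %s: ok (%d out)", stage, sr.n_out)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    finally:
        pkg_logger.removeHandler(collector)
    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return report
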