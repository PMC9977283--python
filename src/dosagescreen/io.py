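"""Readers and writers for the pipeline's on-disk formats.

All tabular files are TSV with a header; BED dialects are tab-separated
without a header and use 0-based half-open coordinates.  Count matrices are
Matrix Market (MTX) with gene/cell sidecar TSVs, or a dense TSV for small
data.  Schema violations are reported with the offending column or line
number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .cutrun import FRAGMENT_COLUMNS, GenomicWindow, SampleLibrary
from .screen import ProteinTrajectory, StudyDEResult, TimeCourse
from .stereology import SectionCounts

FLOAT_FMT = "%.17g"  # lossless float round trip


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path | str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _read_tsv(path: Path | str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, required, path)
    return df


# --- time course -----------------------------------------------------------


def write_timecourse(tc: TimeCourse, path: Path | str) -> None:
    out = tc.lfc.copy()
    out.columns = [FLOAT_FMT % c for c in out.columns]
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_timecourse(path: Path | str) -> TimeCourse:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df.columns = [float(c) for c in df.columns]
    except ValueError as exc:
        raise ValueError(f"{path}: timepoint columns must be numeric") from exc
    return TimeCourse(df)


def write_protein(prot: ProteinTrajectory, path: Path | str) -> None:
    pd.DataFrame(
        {"timepoint": prot.timepoints, "protein_log2fc": prot.values.to_numpy()}
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_protein(path: Path | str) -> ProteinTrajectory:
    df = _read_tsv(path, ["timepoint", "protein_log2fc"])
    return ProteinTrajectory(
        pd.Series(df["protein_log2fc"].to_numpy(), index=df["timepoint"].to_numpy())
    )


# --- pLI -------------------------------------------------------------------


def write_pli(pli: pd.Series, path: Path | str) -> None:
    pli.rename("pLI").rename_axis("gene").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_pli(path: Path | str) -> pd.Series:
    df = _read_tsv(path, ["gene", "pLI"])
    return df.set_index("gene")["pLI"]


# --- DE panel --------------------------------------------------------------


def write_de_table(study: StudyDEResult, path: Path | str) -> None:
    out = study.table.rename(columns={"log2fc": "log2FoldChange"})
    out.rename_axis("gene").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_de_table(path: Path | str, study_id: str, model_class: str, **meta) -> StudyDEResult:
    df = _read_tsv(path, ["gene", "log2FoldChange", "padj"])
    table = df.set_index("gene").rename(columns={"log2FoldChange": "log2fc"})
    return StudyDEResult(study_id=study_id, model_class=model_class, table=table, **meta)


def write_panel(panel: list[StudyDEResult], out_dir: Path | str) -> Path:
    """Write per-study TSVs plus a YAML manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for study in panel:
        fname = f"{study.study_id}.tsv"
        write_de_table(study, out_dir / fname)
        entries.append(
            {
                "study_id": study.study_id,
                "model_class": study.model_class,
                "tissue": study.tissue,
                "path": fname,
            }
        )
    manifest = out_dir / "panel.yaml"
    manifest.write_text(yaml.safe_dump({"studies": entries}, sort_keys=False))
    return manifest


def read_panel(manifest_path: Path | str) -> list[StudyDEResult]:
    manifest_path = Path(manifest_path)
    payload = yaml.safe_load(manifest_path.read_text())
    if not isinstance(payload, dict) or "studies" not in payload:
        raise ValueError(f"{manifest_path}: manifest must contain a 'studies' list")
    panel = []
    for entry in payload["studies"]:
        path = manifest_path.parent / entry["path"]
        panel.append(
            read_de_table(
                path,
                study_id=entry["study_id"],
                model_class=entry["model_class"],
                tissue=entry.get("tissue", ""),
            )
        )
    return panel


# --- cell counts -----------------------------------------------------------


def write_counts_mtx(counts: pd.DataFrame, out_dir: Path | str) -> None:
    """MTX (genes x cells) plus genes.tsv / cells.tsv sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "counts.mtx", scipy.sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="gene").to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    pd.Series(counts.columns, name="cell").to_csv(out_dir / "cells.tsv", sep="\t", index=False)


def read_counts_mtx(in_dir: Path | str) -> pd.DataFrame:
    in_dir = Path(in_dir)
    mat = scipy.io.mmread(in_dir / "counts.mtx").toarray().astype(np.int64)
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t")["gene"]
    cells = pd.read_csv(in_dir / "cells.tsv", sep="\t")["cell"]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(f"{in_dir}: MTX dimensions do not match sidecar files")
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=pd.Index(cells, name="cell"))


def write_counts_tsv(counts: pd.DataFrame, path: Path | str) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_counts_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_annotation(annotation: pd.Series, path: Path | str) -> None:
    annotation.rename("class").rename_axis("cell_id").to_csv(path, sep="\t")


def read_annotation(path: Path | str) -> pd.Series:
    df = _read_tsv(path, ["cell_id", "class"])
    return df.set_index("cell_id")["class"]


# --- BED dialects ----------------------------------------------------------


def write_peaks_bed(windows: list[GenomicWindow], path: Path | str) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")


def read_peaks_bed(path: Path | str) -> list[tuple[str, int, int]]:
    """BED3: no header, 0-based half-open; start < end enforced per line."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            peaks.append((chrom, start, end))
    return peaks


def write_fragments(fragments: pd.DataFrame, path: Path | str) -> None:
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_fragments(path: Path | str) -> pd.DataFrame:
    frags = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS)
    bad = frags.index[frags["start"] >= frags["end"]]
    if len(bad):
        raise ValueError(f"{path}:{bad[0] + 1}: invalid interval (start >= end)")
    if frags["start"].min() < 0:
        raise ValueError(f"{path}: negative coordinates")
    return frags


# --- library manifest ------------------------------------------------------


def write_library_manifest(libs: list[SampleLibrary], path: Path | str) -> None:
    entries = [
        {
            "sample": lib.sample,
            "genotype": lib.genotype,
            "antibody": lib.antibody,
            "scale_constant": float(lib.scale_constant),
        }
        for lib in libs
    ]
    Path(path).write_text(yaml.safe_dump({"libraries": entries}, sort_keys=False))


def read_library_manifest(path: Path | str) -> list[dict]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "libraries" not in payload:
        raise ValueError(f"{path}: manifest must contain a 'libraries' list")
    return payload["libraries"]


# --- stereology / qPCR -----------------------------------------------------


def write_sections(s: SectionCounts, areas_um2: np.ndarray, path: Path | str) -> None:
    pd.DataFrame(
        {
            "section_id": np.arange(1, len(s.q) + 1),
            "Q": s.q,
            "area_um2": areas_um2,
            "t": s.t,
            "h": s.h,
            "asf": s.asf,
            "ssf": s.ssf,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_sections(path: Path | str) -> tuple[SectionCounts, np.ndarray]:
    df = _read_tsv(path, ["section_id", "Q", "area_um2", "t", "h", "asf", "ssf"])
    for col in ("t", "h", "asf", "ssf"):
        if df[col].nunique() != 1:
            raise ValueError(f"{path}: column {col!r} must be constant across sections")
    s = SectionCounts(
        q=df["Q"].to_numpy(),
        t=float(df["t"].iloc[0]),
        h=float(df["h"].iloc[0]),
        asf=float(df["asf"].iloc[0]),
        ssf=float(df["ssf"].iloc[0]),
    )
    return s, df["area_um2"].to_numpy(dtype=float)


def write_ct_table(table: pd.DataFrame, path: Path | str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ct_table(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path, ["gene", "sample", "group", "ct", "detected"])
    if df["detected"].dtype == object:
        df["detected"] = df["detected"].map({"True": True, "False": False}).astype(bool)
    else:
        df["detected"] = df["detected"].astype(bool)
    return df
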