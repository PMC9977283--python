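"""Dosage-sensitivity gene screen.

The screen identifies genes whose expression tracks the protein level of a
dosage-sensitive regulator (the motivating case: MeCP2 and its target Gdf11).
It proceeds in three stages:

1. **Dynamic correlation** — Spearman rank correlation between each gene's
   time-course log2 fold-change (perturbed vs control) and the regulator
   protein's log2 fold-change trajectory on the same time axis.
2. **Loss-intolerance filter** — genes with gnomAD-style pLI above a cutoff
   are retained, on the premise that constrained genes are the ones whose
   mild dysregulation has phenotypic consequences.
3. **Cross-study replication tally** — for each candidate, count the studies
   in an independent panel of differential-expression results where the gene
   is significant (BH-adjusted p below alpha), and how many of those calls
   are direction-concordant with the study's model class (down in
   loss-of-function models, up in gain-of-function models, for a positively
   regulated target).

All thresholds default to the conventional values for this screen:
|rho| > 0.75, pLI > 0.9, padj < 0.1 (strict inequalities throughout).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOF = "LOF"
GOF = "GOF"
MODEL_CLASSES = (LOF, GOF)


@dataclass
class TimeCourse:
    """Genes x timepoints matrix of log2 fold-changes.

    ``lfc`` has one row per gene (unique index) and one float column per
    timepoint (age in weeks, strictly increasing).
    """

    lfc: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.lfc.index
        if idx.has_duplicates:
            raise ValueError("duplicate gene ids in time-course matrix")
        tps = np.asarray(self.lfc.columns, dtype=float)
        if len(tps) < 3:
            raise ValueError("time course needs >=3 timepoints")
        if not np.all(np.diff(tps) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(self.lfc.to_numpy(dtype=float))):
            raise ValueError("non-finite fold-change values")
        self.lfc.columns = tps

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.lfc.columns, dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lfc.index)


@dataclass
class ProteinTrajectory:
    """Regulator-protein log2 fold-change per timepoint (weeks)."""

    values: pd.Series  # index: timepoints (float weeks)

    def __post_init__(self) -> None:
        self.values.index = np.asarray(self.values.index, dtype=float)
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("non-finite protein fold-change values")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.values.index, dtype=float)


@dataclass
class StudyDEResult:
    """One study's differential-expression table.

    ``table`` is indexed by gene with columns ``log2fc`` and ``padj``
    (``padj`` may contain NaN for genes tested without a reported adjusted p).
    ``model_class`` is "LOF" (knockout/mutant) or "GOF"
    (duplication/overexpression).
    """

    study_id: str
    model_class: str
    table: pd.DataFrame
    tissue: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(
                f"model_class must be one of {MODEL_CLASSES}, got {self.model_class!r}"
            )
        missing = {"log2fc", "padj"} - set(self.table.columns)
        if missing:
            raise ValueError(f"study {self.study_id}: missing columns {sorted(missing)}")
        padj = self.table["padj"].dropna()
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError(f"study {self.study_id}: padj outside [0, 1]")


@dataclass
class CrossStudyTally:
    gene: str
    n_significant: int
    n_tested: int
    n_concordant: int
    calls: pd.DataFrame  # per study: tested, significant, concordant, log2fc, padj


@dataclass
class CandidateReport:
    gene: str
    rho: float
    pli: float
    n_significant: int
    n_tested: int
    n_concordant: int
    rank: int = 0
    extras: dict = field(default_factory=dict)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; NaN if either side constant."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def compute_dynamic_correlation(tc: TimeCourse, prot: ProteinTrajectory) -> pd.Series:
    """Spearman rho of every gene's fold-change series against the protein trajectory.

    Both inputs must share the identical (set and order) timepoint axis with at
    least three timepoints.  Genes whose series are constant (rank correlation
    undefined) get NaN, never a silent 0.
    """
    if len(tc.timepoints) < 3:
        raise ValueError("need >=3 timepoints for a rank correlation")
    if len(tc.timepoints) != len(prot.timepoints) or not np.array_equal(
        tc.timepoints, prot.timepoints
    ):
        raise ValueError("time-course and protein trajectory timepoint axes differ")
    y = prot.values.to_numpy(dtype=float)
    mat = tc.lfc.to_numpy(dtype=float)
    rhos = np.array([_spearman(row, y) for row in mat])
    n_undef = int(np.isnan(rhos).sum())
    if n_undef:
        logger.warning("%d gene(s) with constant series: rho undefined", n_undef)
    return pd.Series(rhos, index=tc.lfc.index, name="rho")


def select_correlated(rhos: pd.Series, threshold: float = 0.75) -> list[str]:
    """Genes with |rho| strictly greater than ``threshold`` (NaN excluded)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mask = rhos.abs() > threshold
    return list(rhos.index[mask.fillna(False)])


def filter_by_constraint(
    genes: list[str], pli: pd.Series, pli_min: float = 0.9
) -> tuple[list[str], list[str]]:
    """Keep genes with pLI strictly greater than ``pli_min``.

    Returns ``(kept, missing)`` where ``missing`` lists genes absent from the
    constraint table (dropped with a warning — absence of constraint evidence
    is not evidence of tolerance, but such genes cannot pass the filter).
    """
    if not 0 <= pli_min <= 1:
        raise ValueError("pli_min must be in [0, 1]")
    vals = pli.dropna()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("pLI values outside [0, 1]")
    kept, missing = [], []
    for g in genes:
        if g not in pli.index or pd.isna(pli[g]):
            missing.append(g)
        elif pli[g] > pli_min:
            kept.append(g)
    if missing:
        logger.warning("%d gene(s) missing from pLI table, dropped: %s", len(missing), missing)
    return kept, missing


def tally_cross_study(
    gene: str, panel: list[StudyDEResult], alpha: float = 0.1
) -> CrossStudyTally:
    """Count replication of a gene across a panel of DE studies.

    A study counts as *significant* when the gene's padj is strictly below
    ``alpha``; *concordant* when additionally the fold-change sign matches the
    model class under the positive-regulation convention (negative in LOF,
    positive in GOF).  Studies lacking the gene, or reporting it without a
    padj, count toward neither tally and are listed as untested.
    """
    if not panel:
        raise ValueError("empty study panel")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for study in panel:
        tested = gene in study.table.index and not pd.isna(study.table.loc[gene, "padj"])
        lfc = float(study.table.loc[gene, "log2fc"]) if gene in study.table.index else math.nan
        padj = float(study.table.loc[gene, "padj"]) if tested else math.nan
        sig = bool(tested and padj < alpha)
        expected_sign = -1 if study.model_class == LOF else 1
        conc = bool(sig and np.sign(lfc) == expected_sign)
        rows.append(
            {
                "study_id": study.study_id,
                "model_class": study.model_class,
                "tested": tested,
                "significant": sig,
                "concordant": conc,
                "log2fc": lfc,
                "padj": padj,
            }
        )
    calls = pd.DataFrame(rows).set_index("study_id")
    return CrossStudyTally(
        gene=gene,
        n_significant=int(calls["significant"].sum()),
        n_tested=int(calls["tested"].sum()),
        n_concordant=int(calls["concordant"].sum()),
        calls=calls,
    )


def rank_candidates(reports: list[CandidateReport]) -> list[CandidateReport]:
    """Deterministic total order: n_significant desc, n_concordant desc,
    |rho| desc, gene id ascending.  Assigns 1-based ranks in place."""
    ordered = sorted(
        reports,
        key=lambda r: (-r.n_significant, -r.n_concordant, -abs(r.rho), r.gene),
    )
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def run_screen(
    tc: TimeCourse,
    prot: ProteinTrajectory,
    pli: pd.Series,
    panel: list[StudyDEResult],
    rho_threshold: float = 0.75,
    pli_min: float = 0.9,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Full screen: correlate, select, constraint-filter, tally, rank.

    Returns the candidate report as a DataFrame with columns gene, rho, pLI,
    n_significant, n_tested, n_concordant, rank (one row per candidate that
    survived selection and the constraint filter).
    """
    rhos = compute_dynamic_correlation(tc, prot)
    selected = select_correlated(rhos, rho_threshold)
    kept, _missing = filter_by_constraint(selected, pli, pli_min)
    reports = []
    for g in kept:
        tally = tally_cross_study(g, panel, alpha)
        reports.append(
            CandidateReport(
                gene=g,
                rho=float(rhos[g]),
                pli=float(pli[g]),
                n_significant=tally.n_significant,
                n_tested=tally.n_tested,
                n_concordant=tally.n_concordant,
            )
        )
    ranked = rank_candidates(reports)
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "rho": r.rho,
                "pLI": r.pli,
                "n_significant": r.n_significant,
                "n_tested": r.n_tested,
                "n_concordant": r.n_concordant,
                "rank": r.rank,
            }
            for r in ranked
        ],
        columns=["gene", "rho", "pLI", "n_significant", "n_tested", "n_concordant", "rank"],
    )
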