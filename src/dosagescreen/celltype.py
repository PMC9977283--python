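"""Cell-type-resolved correlation between two focal genes.

Single-cell (or single-nucleus) counts are grouped by an externally supplied
annotation, and Spearman correlation between a gene pair is computed on raw
counts within each group.  Neurons can additionally be split into excitatory
and inhibitory classes with a marker-count rule (Slc17a7/Vglut1 >= 5 counts
per cell denotes an excitatory neuron).

Counts are a genes x cells DataFrame of non-negative integers.  No
normalization is applied: Spearman's rank basis makes per-gene monotone
scalings irrelevant, and zero-count cells are retained as rank ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

POOLED_LABEL = "all"
EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass
class MarkerRule:
    """Marker-gene threshold for the excitatory/inhibitory neuron split."""

    marker_gene: str = "Slc17a7"
    min_count: int = 5

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene or cell ids are not unique")
    arr = counts.to_numpy()
    if (arr < 0).any() or not np.array_equal(arr, arr.astype(int)):
        raise ValueError("counts must be non-negative integers")


def split_neurons(
    counts: pd.DataFrame, neuron_cells: list[str], rule: MarkerRule | None = None
) -> pd.Series:
    """Label each neuron excitatory (marker count >= threshold) or inhibitory.

    The partition is exhaustive and disjoint over ``neuron_cells``.
    """
    rule = rule or MarkerRule()
    if rule.marker_gene not in counts.index:
        raise KeyError(f"marker gene {rule.marker_gene!r} absent from count matrix")
    marker = counts.loc[rule.marker_gene, neuron_cells]
    labels = np.where(marker >= rule.min_count, EXCITATORY, INHIBITORY)
    return pd.Series(labels, index=pd.Index(neuron_cells, name="cell"), name="neuron_class")


def correlate_pair(
    counts: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-group Spearman correlation between two genes on raw counts.

    ``groups`` maps cell id -> group label; cells absent from it are excluded
    (they are unannotated).  A pooled row labeled ``"all"`` covers every
    annotated cell.  Groups in which either gene's counts are constant yield
    an undefined correlation, reported with ``defined=False`` and NaN rho.

    Returns a DataFrame indexed by group label with columns
    ``n_cells``, ``rho``, ``defined``.
    """
    for g in (gene_a, gene_b):
        if g not in counts.index:
            raise KeyError(f"gene {g!r} absent from count matrix")
    cells = [c for c in groups.index if c in counts.columns]
    if not cells:
        raise ValueError("no annotated cells present in the count matrix")
    a = counts.loc[gene_a, cells].to_numpy(dtype=float)
    b = counts.loc[gene_b, cells].to_numpy(dtype=float)
    labels = groups.loc[cells].to_numpy()

    def one(mask: np.ndarray) -> tuple[int, float, bool]:
        n = int(mask.sum())
        if n == 0:
            raise ValueError("empty group")
        xa, xb = a[mask], b[mask]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            return n, float("nan"), False
        rho = float(np.corrcoef(stats.rankdata(xa), stats.rankdata(xb))[0, 1])
        return n, rho, True

    rows = {}
    for lab in sorted(set(labels)):
        rows[lab] = one(labels == lab)
    rows[POOLED_LABEL] = one(np.ones_like(labels, dtype=bool))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["n_cells", "rho", "defined"])
    out.index.name = "group"
    out["n_cells"] = out["n_cells"].astype(int)
    out["defined"] = out["defined"].astype(bool)
    return out
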