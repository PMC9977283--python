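import numpy as np
import pandas as pd
import pytest

from dosagescreen import ProteinTrajectory, TimeCourse


@pytest.fixture
def small_timecourse() -> tuple[TimeCourse, ProteinTrajectory]:
    """Four genes with known relationships to a 5-point protein trajectory."""
    tps = [2.0, 4.0, 6.0, 8.0, 10.0]
    prot = np.array([0.0, -1.0, -2.0, -1.2, -0.2])
    mat = np.vstack(
        [
            prot,                                    # identical to protein
            -prot,                                   # negated
            np.array([0.1, 0.2, 0.15, 0.12, 0.18]),  # unrelated
            np.zeros(5),                             # constant -> undefined rho
        ]
    )
    lfc = pd.DataFrame(
        mat,
        index=pd.Index(["tracker", "antitracker", "noise", "flat"], name="gene"),
        columns=tps,
    )
    return TimeCourse(lfc), ProteinTrajectory(pd.Series(prot, index=tps))


def spearman_oracle(x, y) -> float:
    """Definitional Spearman: average ranks, then the explicit Pearson formula."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based positions
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))
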