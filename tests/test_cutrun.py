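"""Window expansion, fragment counting, spike calibration, differential test."""

import numpy as np
import pandas as pd
import pytest

from dosagescreen import (
    GenomicWindow,
    OccupancyTable,
    SampleLibrary,
    count_fragments,
    differential_occupancy,
    expand_peak,
    normalized_occupancy,
    spike_scale_factor,
)
from dosagescreen.cutrun import spike_size_factors


def _frag_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "genome"])


def brute_force_counts(fragments, windows):
    """Quadratic all-pairs overlap oracle (>=1 bp, half-open)."""
    prim = fragments[fragments["genome"] == "primary"]
    samples = sorted(fragments["sample"].unique())
    out = pd.DataFrame(0, index=pd.Index([w.window_id for w in windows], name="window"),
                       columns=samples)
    for _, f in prim.iterrows():
        for w in windows:
            if f["chrom"] == w.chrom and f["start"] < w.end and f["end"] > w.start:
                out.loc[w.window_id, f["sample"]] += 1
    return out


class TestExpandPeak:
    def test_default_halfwidth_seven_kb_window(self):
        w = expand_peak("chr1", 49_900, 50_100)
        assert (w.start, w.end, w.width) == (46_500, 53_500, 7_000)

    def test_clipped_at_origin(self):
        w = expand_peak("chr1", 1_000, 1_200)
        assert (w.start, w.end) == (0, 4_600)

    def test_minimal_halfwidth(self):
        w = expand_peak("chr1", 10, 12, halfwidth=1)
        assert (w.start, w.end) == (10, 12)

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValueError, match="invalid peak"):
            expand_peak("chr1", 100, 100)


class TestSpikeScaling:
    def test_direct_ratio_and_identity_point(self):
        assert spike_scale_factor(SampleLibrary("s", "WT", spike_count=100)) == 100.0
        assert spike_scale_factor(SampleLibrary("s", "WT", spike_count=10_000)) == 1.0

    def test_zero_spike_hard_error_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            spike_scale_factor(SampleLibrary("s1", "WT", spike_count=0))

    def test_duplication_invariance_of_normalized_signal(self):
        """k-fold duplication of one sample's primary+spike fragments leaves
        its spike-calibrated window signal exactly unchanged."""
        rng = np.random.default_rng(4)
        win = GenomicWindow("chr1", 1000, 2000, "w1")
        rows = [("chr1", int(s), int(s) + 150, "a", "primary")
                for s in rng.integers(0, 3000, 60)]
        rows += [("ecoli", 0, 150, "a", "spike")] * 20
        frags = _frag_df(rows)
        k = 3
        dup = _frag_df(rows * k)
        norm1 = normalized_occupancy(
            count_fragments(frags, [win]), [SampleLibrary("a", "WT", spike_count=20)])
        normk = normalized_occupancy(
            count_fragments(dup, [win]), [SampleLibrary("a", "WT", spike_count=20 * k)])
        pd.testing.assert_frame_equal(norm1, normk)


class TestCounting:
    WIN = GenomicWindow("chr1", 46_500, 53_500, "w")

    @pytest.mark.parametrize(
        "start,end,counted",
        [
            (46_400, 46_600, True),   # partial overlap
            (46_000, 46_500, False),  # half-open abutment on the left
            (53_500, 53_700, False),  # abutment on the right
            (53_499, 53_700, True),   # 1 bp overlap
            (50_000, 50_100, True),   # contained
        ],
    )
    def test_half_open_overlap_rule(self, start, end, counted):
        frags = _frag_df([("chr1", start, end, "s", "primary")])
        table = count_fragments(frags, [self.WIN])
        assert table.counts.loc["w", "s"] == (1 if counted else 0)

    def test_spike_fragments_never_counted(self):
        frags = _frag_df([("chr1", 50_000, 50_100, "s", "spike"),
                          ("chr1", 50_000, 50_100, "s", "primary")])
        assert count_fragments(frags, [self.WIN]).counts.loc["w", "s"] == 1

    def test_fragment_in_two_windows_counts_in_both(self):
        w1 = GenomicWindow("chr1", 0, 1000, "w1")
        w2 = GenomicWindow("chr1", 900, 2000, "w2")
        frags = _frag_df([("chr1", 950, 1100, "s", "primary")])
        counts = count_fragments(frags, [w1, w2]).counts
        assert counts.loc["w1", "s"] == 1 and counts.loc["w2", "s"] == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            frags = _frag_df([
                ("chr1" if rng.random() < 0.8 else "chr2",
                 int(s), int(s + rng.integers(120, 181)),
                 f"s{rng.integers(3)}", "primary" if rng.random() < 0.9 else "spike")
                for s in rng.integers(0, 100_000, 300)
            ])
            windows = []
            for j in range(8):
                start = int(rng.integers(0, 95_000))
                windows.append(GenomicWindow(
                    "chr1" if rng.random() < 0.8 else "chr2",
                    start, start + int(rng.integers(500, 5_000)), f"w{j}"))
            fast = count_fragments(frags, windows).counts
            slow = brute_force_counts(frags, windows)
            pd.testing.assert_frame_equal(fast, slow.astype(fast.dtypes.iloc[0]))

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_fragments(_frag_df([("chr1", 0, 100, "s", "primary")]), [])


def _nb(rng, mean, disp, size):
    shape = 1.0 / disp
    return rng.negative_binomial(shape, shape / (shape + mean), size).astype(float)


def _libs(samples_a, samples_b, spike=1000):
    return (
        [SampleLibrary(s, "KO", spike_count=spike) for s in samples_a]
        + [SampleLibrary(s, "WT", spike_count=spike) for s in samples_b]
    )


class TestDifferentialOccupancy:
    def test_exact_null_identical_counts(self):
        counts = pd.DataFrame(
            {"k1": [100, 7], "k2": [100, 7], "w1": [100, 7], "w2": [100, 7]},
            index=["a", "b"])
        table = OccupancyTable(counts=counts)
        out = differential_occupancy(table, _libs(["k1", "k2"], ["w1", "w2"]))
        assert (out["log2fc"] == 0).all()
        assert (out["p"] >= 0.99).all()

    def test_doubled_counts_log2fc_near_one(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5000, (50, 3)).astype(float)
        counts = pd.DataFrame(
            np.hstack([base * 2, base]),
            columns=["k1", "k2", "k3", "w1", "w2", "w3"])
        table = OccupancyTable(counts=counts)
        out = differential_occupancy(table, _libs(["k1", "k2", "k3"], ["w1", "w2", "w3"]))
        assert np.allclose(out["log2fc"], 1.0, atol=0.01)

    def test_spike_size_factors_geometric_mean_one(self):
        libs = [SampleLibrary(f"s{i}", "WT", spike_count=c)
                for i, c in enumerate([500, 1000, 2000])]
        sf = spike_size_factors(libs)
        assert np.prod(sf) == pytest.approx(1.0)

    def test_sample_and_window_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(_nb(rng, 100, 0.05, (30, 6)),
                              columns=["k1", "k2", "k3", "w1", "w2", "w3"],
                              index=[f"win{i}" for i in range(30)])
        libs = _libs(["k1", "k2", "k3"], ["w1", "w2", "w3"])
        ref = differential_occupancy(OccupancyTable(counts=counts), libs)
        perm_rows = list(rng.permutation(counts.index))
        perm_cols = list(rng.permutation(counts.columns))
        out = differential_occupancy(
            OccupancyTable(counts=counts.loc[perm_rows, perm_cols]), libs[::-1])
        pd.testing.assert_frame_equal(ref.loc[perm_rows], out)

    def test_single_sample_group_rejected(self):
        table = OccupancyTable(counts=pd.DataFrame({"k1": [1], "w1": [1], "w2": [2]}))
        with pytest.raises(ValueError, match=">=2 samples"):
            differential_occupancy(table, _libs(["k1"], ["w1", "w2"]))

    def test_zero_spike_group_rejected(self):
        table = OccupancyTable(counts=pd.DataFrame(
            {"k1": [1], "k2": [1], "w1": [1], "w2": [1]}))
        libs = _libs(["k1", "k2"], ["w1", "w2"], spike=0)
        with pytest.raises(ValueError, match="zero spike"):
            differential_occupancy(table, libs)

    def test_power_on_planted_twofold(self):
        """>=80% of 2-fold windows detected at alpha=0.05 (mean 100, disp 0.05, 3v3)."""
        rng = np.random.default_rng(6)
        w = 400
        counts = pd.DataFrame(
            np.hstack([_nb(rng, 200, 0.05, (w, 3)), _nb(rng, 100, 0.05, (w, 3))]),
            columns=["k1", "k2", "k3", "w1", "w2", "w3"])
        out = differential_occupancy(
            OccupancyTable(counts=counts), _libs(["k1", "k2", "k3"], ["w1", "w2", "w3"]))
        assert (out["p"] < 0.05).mean() >= 0.8
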