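"""Dosage screen: dynamic correlation, selection, constraint filter, tally."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosagescreen import (
    CandidateReport,
    ProteinTrajectory,
    StudyDEResult,
    TimeCourse,
    compute_dynamic_correlation,
    filter_by_constraint,
    rank_candidates,
    select_correlated,
    tally_cross_study,
)
from conftest import spearman_oracle


def _tc(rows: dict, tps) -> TimeCourse:
    return TimeCourse(pd.DataFrame(rows, index=[float(t) for t in tps]).T)


class TestDynamicCorrelation:
    def test_identical_series_gives_one(self, small_timecourse):
        tc, prot = small_timecourse
        rhos = compute_dynamic_correlation(tc, prot)
        assert rhos["tracker"] == pytest.approx(1.0)

    def test_negated_series_gives_minus_one(self, small_timecourse):
        tc, prot = small_timecourse
        rhos = compute_dynamic_correlation(tc, prot)
        assert rhos["antitracker"] == pytest.approx(-1.0)

    def test_constant_series_undefined(self, small_timecourse):
        tc, prot = small_timecourse
        rhos = compute_dynamic_correlation(tc, prot)
        assert np.isnan(rhos["flat"])

    def test_tied_series_matches_hand_computed_value(self):
        # gene (0.1, 0.1, 0.4, 0.9) has tied average ranks (1.5, 1.5, 3, 4);
        # Pearson on ranks against (1, 2, 3, 4) gives 4.5/sqrt(22.5) = sqrt(0.9)
        tc = _tc({"g": [0.1, 0.1, 0.4, 0.9]}, [1, 2, 3, 4])
        prot = ProteinTrajectory(pd.Series([0.0, 0.2, 0.5, 0.8], index=[1.0, 2.0, 3.0, 4.0]))
        rho = compute_dynamic_correlation(tc, prot)["g"]
        assert rho == pytest.approx(0.9486832980505138, abs=1e-12)
        assert rho == pytest.approx(spearman_oracle([0.1, 0.1, 0.4, 0.9], [0.0, 0.2, 0.5, 0.8]))

    def test_matches_definitional_oracle_on_all_orderings(self):
        """Exhaustive agreement with average-rank Pearson over all 5! orderings."""
        prot_vals = np.array([0.0, -0.5, -1.4, -0.9, -0.2])
        tps = [1.0, 2.0, 3.0, 4.0, 5.0]
        prot = ProteinTrajectory(pd.Series(prot_vals, index=tps))
        base = np.array([0.3, -0.1, 0.8, -0.6, 0.2])
        for perm in itertools.permutations(range(5)):
            series = base[list(perm)]
            rho = compute_dynamic_correlation(_tc({"g": series}, tps), prot)["g"]
            assert rho == pytest.approx(spearman_oracle(series, prot_vals), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        data=st.lists(st.integers(-1000, 1000), min_size=4, max_size=10, unique=True)
        .map(lambda xs: [x / 100.0 for x in xs]),
        scale=st.floats(0.1, 10),
        shift=st.floats(-3, 3),
    )
    def test_invariant_under_monotone_transform(self, data, scale, shift):
        tps = [float(i) for i in range(1, len(data) + 1)]
        prot = ProteinTrajectory(pd.Series(np.linspace(0, -2, len(data)), index=tps))
        raw = compute_dynamic_correlation(_tc({"g": data}, tps), prot)["g"]
        transformed = [scale * x + shift for x in data]
        mono = compute_dynamic_correlation(_tc({"g": transformed}, tps), prot)["g"]
        assert mono == pytest.approx(raw, abs=1e-9)
        assert -1.0 <= raw <= 1.0

    def test_mismatched_axes_rejected(self, small_timecourse):
        tc, _ = small_timecourse
        wrong = ProteinTrajectory(pd.Series([0.0, -1.0, -2.0], index=[2.0, 4.0, 6.0]))
        with pytest.raises(ValueError, match="axes differ"):
            compute_dynamic_correlation(tc, wrong)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match=">=3 timepoints"):
            TimeCourse(pd.DataFrame({"g": [0.1, 0.2]}, index=[1.0, 2.0]).T)


class TestSelection:
    @pytest.mark.parametrize(
        "rho,selected",
        [(0.76, True), (-0.80, True), (0.75, False), (-0.75, False), (np.nan, False)],
    )
    def test_absolute_strict_threshold(self, rho, selected):
        rhos = pd.Series({"g": rho, "anchor": 0.9})
        assert ("g" in select_correlated(rhos, 0.75)) is selected

    @pytest.mark.parametrize(
        "pli,kept", [(0.95, True), (0.90, False), (0.9001, True), (0.0, False)]
    )
    def test_pli_strict_boundary(self, pli, kept):
        table = pd.Series({"g": pli})
        out, missing = filter_by_constraint(["g"], table, 0.9)
        assert ("g" in out) is kept
        assert missing == []

    def test_missing_gene_dropped_and_reported(self, caplog):
        table = pd.Series({"other": 0.99})
        with caplog.at_level("WARNING", logger="dosagescreen.screen"):
            out, missing = filter_by_constraint(["g", "other"], table, 0.9)
        assert out == ["other"] and missing == ["g"]
        assert "missing" in caplog.text


def _study(i, padjs, lfcs, model_class="LOF"):
    table = pd.DataFrame(
        {"log2fc": lfcs, "padj": padjs},
        index=[f"g{j}" for j in range(len(padjs))],
    )
    return StudyDEResult(study_id=f"s{i}", model_class=model_class, table=table)


class TestCrossStudyTally:
    def test_nineteen_of_twenty(self):
        panel = [_study(i, [0.01 if i < 19 else 0.5], [-1.0]) for i in range(20)]
        t = tally_cross_study("g0", panel)
        assert (t.n_significant, t.n_tested) == (19, 20)

    def test_padj_boundary_is_strict(self):
        t = tally_cross_study("g0", [_study(0, [0.1], [-1.0])], alpha=0.1)
        assert t.n_significant == 0 and t.n_tested == 1

    @pytest.mark.parametrize(
        "mc,lfc,concordant",
        [("LOF", -1.0, True), ("LOF", 1.0, False), ("GOF", 1.0, True), ("GOF", -1.0, False)],
    )
    def test_sign_convention(self, mc, lfc, concordant):
        t = tally_cross_study("g0", [_study(0, [0.01], [lfc], model_class=mc)])
        assert t.n_significant == 1
        assert t.n_concordant == (1 if concordant else 0)

    def test_missing_padj_counts_as_untested(self):
        panel = [_study(0, [np.nan], [-2.0]), _study(1, [0.01], [-2.0])]
        t = tally_cross_study("g0", panel)
        assert (t.n_tested, t.n_significant) == (1, 1)
        assert not t.calls.loc["s0", "tested"]

    def test_permutation_invariance_and_ordering_invariant(self):
        rng = np.random.default_rng(0)
        panel = [
            _study(i, rng.uniform(0, 0.3, 5), rng.normal(0, 1, 5),
                   model_class="LOF" if i % 2 else "GOF")
            for i in range(12)
        ]
        ref = tally_cross_study("g2", panel)
        shuffled = [panel[i] for i in rng.permutation(12)]
        out = tally_cross_study("g2", shuffled)
        assert (out.n_significant, out.n_tested, out.n_concordant) == (
            ref.n_significant, ref.n_tested, ref.n_concordant)
        assert out.n_concordant <= out.n_significant <= out.n_tested

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tally_cross_study("g0", [])


class TestRanking:
    def test_total_order_keys(self):
        reports = [
            CandidateReport("b", rho=0.80, pli=1.0, n_significant=12, n_tested=20, n_concordant=10),
            CandidateReport("a", rho=0.92, pli=1.0, n_significant=19, n_tested=20, n_concordant=18),
            CandidateReport("d", rho=-0.92, pli=1.0, n_significant=12, n_tested=20, n_concordant=10),
            CandidateReport("c", rho=0.92, pli=1.0, n_significant=12, n_tested=20, n_concordant=10),
        ]
        ordered = rank_candidates(reports)
        # primary: significance; tertiary: |rho| (0.92 beats 0.80); final: gene id
        assert [r.gene for r in ordered] == ["a", "c", "d", "b"]
        assert [r.rank for r in ordered] == [1, 2, 3, 4]
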