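"""Epoch design, Friedman test, Dunn's post hoc: formulas vs oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ductokym.pharmstats import (EpochDesign, compare_conditions,
                                 dunns_posthoc, epoch_frequencies,
                                 friedman_exact_p, friedman_test)
from ductokym.stackio import DrugSchedule
from _util import small_params

STRICT = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])


def _design(*additions):
    return EpochDesign(schedule=DrugSchedule(list(additions)))


class TestEpochDesign:
    def test_drug_response_windows_recover_both_regimes(
            self, drug_response_events):
        events, truth = drug_response_events
        design = _design((300.0, "sildenafil 5 uM"))
        row = epoch_frequencies(events, design, 600.0)
        assert row == {"Spont": 7.5, "sildenafil 5 uM": 3.0}

    def test_no_events_give_zero_everywhere(self):
        row = epoch_frequencies([], _design((300.0, "x")), 600.0)
        assert row == {"Spont": 0.0, "x": 0.0}

    def test_pre_window_leaving_recording_names_the_addition(self):
        with pytest.raises(ValueError, match="early"):
            epoch_frequencies([], _design((60.0, "early")), 600.0)

    def test_post_window_overlapping_next_pre_window_is_reported(self):
        with pytest.raises(ValueError, match="overlap"):
            epoch_frequencies([], _design((200.0, "a"), (400.0, "b")), 600.0)


class TestFriedman:
    def test_identical_columns_give_q0_p1(self):
        table = np.tile([[4.0, 4.0, 4.0]], (4, 1))
        res = friedman_test(table)
        assert res.Q == 0.0 and res.p_value == 1.0

    def test_consistent_strict_ordering_gives_q6(self):
        res = friedman_test(STRICT)
        assert res.Q == pytest.approx(6.0, abs=1e-12)
        assert list(res.rank_sums) == [3.0, 6.0, 9.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_including_tied_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = np.round(rng.uniform(0, 12, (6, 4)))    # ties likely
        mine = friedman_test(table)
        ref_q, ref_p = sps.friedmanchisquare(*table.T)
        if np.isnan(ref_q):          # scipy's 0/0 on fully tied rows
            assert mine.Q == 0.0
        else:
            assert mine.Q == pytest.approx(ref_q, abs=1e-12)
            assert mine.p_value == pytest.approx(ref_p, abs=1e-12)

    def test_incomplete_table_is_rejected_without_imputation(self):
        table = STRICT.copy()
        table[1, 2] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            friedman_test(table)

    def test_too_few_segments_or_conditions_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            friedman_test(np.array([[1.0, 2.0]]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_q_invariant_under_monotone_row_transforms(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.normal(size=(4, 3))
        warped = np.exp(table) + np.arange(4)[:, None]   # per-row monotone
        assert friedman_test(warped).Q == pytest.approx(
            friedman_test(table).Q, abs=1e-9)

    def test_column_permutation_preserves_q_and_permutes_ranks(self):
        rng = np.random.default_rng(7)
        table = rng.normal(size=(5, 4))
        perm = [2, 0, 3, 1]
        r1 = friedman_test(table)
        r2 = friedman_test(table[:, perm])
        assert r2.Q == pytest.approx(r1.Q, abs=1e-12)
        np.testing.assert_allclose(r2.rank_sums, r1.rank_sums[perm])


def _exact_p_oracle(table):
    """Brute-force permutation p using scipy's statistic on raw values."""
    n, k = table.shape
    q_obs = friedman_test(table).Q
    count = total = 0
    for perm_rows in itertools.product(
            *[list(itertools.permutations(row)) for row in table]):
        arr = np.array(perm_rows)
        q, _ = sps.friedmanchisquare(*arr.T)
        if np.isnan(q):
            q = 0.0
        total += 1
        if q >= q_obs - 1e-9:
            count += 1
    return count / total


class TestExactPermutation:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration_on_3x3(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.normal(size=(3, 3))
        assert friedman_exact_p(table) == pytest.approx(
            _exact_p_oracle(table), abs=1e-12)

    def test_fully_tied_table_gives_p1(self):
        assert friedman_exact_p(np.ones((3, 3))) == 1.0

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="chi-square"):
            friedman_exact_p(np.random.default_rng(0).normal(size=(12, 5)))


class TestDunn:
    def test_strict_ordering_pair_z_and_p(self):
        cmp = dunns_posthoc(STRICT, comparisons=[("C3", "C1")])[0]
        # mean-rank difference 2, SE = sqrt(3*4/(6*3)) = sqrt(2/3)
        assert cmp.z == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert cmp.p_unadjusted == pytest.approx(
            2 * sps.norm.sf(2.449489742783178), abs=1e-12)

    def test_self_comparison_is_null(self):
        cmp = dunns_posthoc(STRICT, comparisons=[("C1", "C1")])[0]
        assert cmp.z == 0.0 and cmp.p_adjusted == 1.0

    def test_unknown_column_is_an_error(self):
        with pytest.raises(ValueError, match="unknown column"):
            dunns_posthoc(STRICT, comparisons=[("C1", "C9")])

    def test_default_comparisons_target_spont(self):
        import pandas as pd
        table = pd.DataFrame(STRICT, columns=["Spont", "SNP", "sildenafil"])
        pairs = [c.pair for c in dunns_posthoc(table)]
        assert pairs == [("Spont", "SNP"), ("Spont", "sildenafil")]

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_adjusted_p_never_below_unadjusted(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.normal(size=(4, 4))
        for method in ("bonferroni", "holm"):
            for cmp in dunns_posthoc(table, adjustment=method):
                assert cmp.p_adjusted >= cmp.p_unadjusted - 1e-15
                assert 0.0 <= cmp.p_adjusted <= 1.0

    def test_holm_is_no_more_conservative_than_bonferroni(self):
        rng = np.random.default_rng(3)
        table = rng.normal(size=(5, 4))
        bonf = dunns_posthoc(table, adjustment="bonferroni")
        holm = dunns_posthoc(table, adjustment="holm")
        for b, h in zip(bonf, holm):
            assert h.p_adjusted <= b.p_adjusted + 1e-15


class TestCompareConditions:
    def test_single_condition_is_rejected(self):
        design = _design((300.0, "x"))
        events = [np.arange(0, 600, 8.0)] * 3
        # strip the drug column to force k=1
        with pytest.raises(ValueError, match="k >= 2|conditions"):
            friedman_test(np.ones((3, 1)))
        # and fewer than two segments is rejected outright
        with pytest.raises(ValueError, match="2 segments"):
            compare_conditions(events[:1], design, 600.0)

    def test_slowing_drug_is_detected_across_8_segments(self):
        """Eight simulated segments switching 7.5 -> 3.0 beats/min: the
        drug-vs-Spont comparison must reach adjusted p < 0.05."""
        from ductokym.contract import detect_contractions, trace_diameter
        from ductokym.kymo import extract_kymograph
        from ductokym.simdata import simulate_movie
        from _util import vline

        design = _design((300.0, "sildenafil 5 uM"))
        segments = []
        for seed in range(8):
            p = small_params(duration_s=600.0, seed=100 + seed,
                             schedule=[(300.0, 20.0, "sildenafil 5 uM")])
            stack, _ = simulate_movie(p)
            trace = trace_diameter(
                extract_kymograph(stack, vline(64.0, 8.0, 56.0)))
            segments.append(detect_contractions(trace))
        result, table = compare_conditions(segments, design, 600.0)
        drug = result.pairwise[0]
        assert drug.pair == ("Spont", "sildenafil 5 uM")
        assert drug.p_adjusted < 0.05
        assert drug.stars in ("*", "**")

    def test_no_regime_change_is_not_called_significant(self):
        """Type-I control: segments without any frequency change must not
        produce spurious drug effects."""
        from ductokym.contract import detect_contractions, trace_diameter
        from ductokym.kymo import extract_kymograph
        from ductokym.simdata import simulate_movie
        from _util import vline

        design = _design((180.0, "vehicle"))
        n_sig = 0
        n_rep = 10
        for rep in range(n_rep):
            segments = []
            for s in range(4):
                p = small_params(duration_s=320.0, seed=500 + 10 * rep + s,
                                 schedule=[(180.0, 8.0, "vehicle")])
                stack, _ = simulate_movie(p)
                trace = trace_diameter(
                    extract_kymograph(stack, vline(64.0, 8.0, 56.0)))
                segments.append(detect_contractions(trace))
            result, _ = compare_conditions(segments, design, 320.0)
            if result.pairwise[0].p_adjusted < 0.05:
                n_sig += 1
        assert n_sig <= 1
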