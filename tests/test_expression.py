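"""ΔCt relative expression, allelic percentages and CPM t-tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

import oometh as om

from oracles import brute_holm_sidak


def _ct_rows(entries):
    """entries: (sample, group, gene, [ct, ct, ...])"""
    rows = []
    for sample, group, gene, cts in entries:
        for i, ct in enumerate(cts, start=1):
            rows.append((sample, group, gene, i, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])


class TestCollapseTechnical:
    def test_mean_of_triplicate(self):
        table = _ct_rows([("s1", "A", "g", [20.1, 20.2, 20.0])])
        out = om.collapse_technical(table)
        assert out.iloc[0].ct == pytest.approx(20.1)
        assert not out.iloc[0].high_range

    def test_single_value_passthrough(self):
        out = om.collapse_technical(_ct_rows([("s1", "A", "g", [25.0])]))
        assert out.iloc[0].ct == 25.0

    def test_wide_range_flagged_not_excluded(self):
        out = om.collapse_technical(_ct_rows([("s1", "A", "g", [20.0, 22.0])]))
        assert out.iloc[0].ct == pytest.approx(21.0)
        assert out.iloc[0].high_range

    def test_requires_columns(self):
        with pytest.raises(ValueError):
            om.collapse_technical(pd.DataFrame({"sample": [], "ct": []}))


class TestRelativeExpression:
    def test_delta_ct_against_three_housekeepers(self):
        table = _ct_rows(
            [
                ("s1", "A", "Actb", [20.0]),
                ("s1", "A", "18S", [21.0]),
                ("s1", "A", "Hprt", [22.0]),
                ("s1", "A", "tgt", [25.0]),
            ]
        )
        summary, delta = om.relative_expression(
            om.collapse_technical(table), ["Actb", "18S", "Hprt"]
        )
        assert delta.iloc[0].delta_ct == pytest.approx(4.0)
        assert summary.iloc[0].geo_mean == pytest.approx(2.0**-4)

    def test_identical_replicates_have_geometric_sd_one(self):
        table = _ct_rows(
            [(f"s{i}", "A", "Actb", [20.0]) for i in range(1, 4)]
            + [(f"s{i}", "A", "tgt", [21.0]) for i in range(1, 4)]
        )
        summary, _ = om.relative_expression(om.collapse_technical(table), "Actb")
        assert summary.iloc[0].geo_mean == pytest.approx(0.5)
        assert summary.iloc[0].geo_sd == pytest.approx(1.0)
        assert summary.iloc[0].n == 3

    def test_invariant_to_uniform_ct_shift(self):
        base = _ct_rows(
            [
                ("s1", "A", "Actb", [19.5]),
                ("s1", "A", "tgt", [22.5]),
                ("s2", "A", "Actb", [20.5]),
                ("s2", "A", "tgt", [23.0]),
            ]
        )
        shifted = base.copy()
        shifted.loc[shifted["sample"] == "s1", "ct"] += 1.0
        s0, _ = om.relative_expression(om.collapse_technical(base), "Actb")
        s1, _ = om.relative_expression(om.collapse_technical(shifted), "Actb")
        pd.testing.assert_frame_equal(s0, s1)

    def test_sample_missing_housekeeper_excluded(self):
        table = _ct_rows(
            [
                ("s1", "A", "Actb", [20.0]),
                ("s1", "A", "tgt", [22.0]),
                ("s2", "A", "tgt", [23.0]),  # no housekeeper for s2
            ]
        )
        summary, delta = om.relative_expression(om.collapse_technical(table), "Actb")
        assert summary.iloc[0].n == 1
        assert set(delta["sample"]) == {"s1"}

    def test_unknown_housekeeper_raises(self):
        table = _ct_rows([("s1", "A", "tgt", [22.0])])
        with pytest.raises(ValueError, match="absent"):
            om.relative_expression(om.collapse_technical(table), "Actb")


class TestAllelicSplit:
    @pytest.mark.parametrize(
        "delta, paternal",
        [(0.0, 50.0), (3.0, 100 * 8 / 9), (-1.0, 100 / 3)],
    )
    def test_known_values(self, delta, paternal):
        row = om.allelic_split(20.0 + delta, 20.0).iloc[0]
        assert row.paternal_pct == pytest.approx(paternal)
        assert row.maternal_pct == pytest.approx(100 - paternal)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_round_trip_recovers_fraction(self, f):
        """Cts built from ΔCt = log2(f/(1-f)) recover the paternal fraction."""
        delta = np.log2(f / (1 - f))
        row = om.allelic_split(25.0 + delta, 25.0).iloc[0]
        assert row.paternal_pct == pytest.approx(100 * f, abs=1e-9)

    def test_strictly_increasing_and_bounded(self):
        deltas = np.linspace(-12, 12, 101)
        pct = om.allelic_split(20.0 + deltas, np.full(101, 20.0))["paternal_pct"]
        assert (np.diff(pct) > 0).all()
        assert (pct > 0).all() and (pct < 100).all()

    def test_percentages_sum_to_100(self):
        out = om.allelic_split([18.0, 21.0, 26.0], [20.0, 20.0, 20.0])
        np.testing.assert_allclose(out["paternal_pct"] + out["maternal_pct"], 100.0)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            om.allelic_split(np.nan, 20.0)


class TestCpm:
    def test_simple_scaling(self):
        counts = pd.DataFrame({"s1": [100, 10**6 - 100]})
        assert om.cpm(counts).iloc[0, 0] == pytest.approx(100.0)

    def test_library_size_normalisation(self):
        counts = pd.DataFrame({"s1": [5, 10**5 - 5], "s2": [10, 2 * 10**5 - 10]})
        mat = om.cpm(counts)
        assert mat.iloc[0].tolist() == pytest.approx([50.0, 50.0])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero library total"):
            om.cpm(pd.DataFrame({"s1": [0, 0]}))

    def test_identical_groups_null_result(self):
        counts = pd.DataFrame(
            {"a1": [10, 90], "a2": [20, 180], "b1": [30, 270], "b2": [5, 45]}
        )
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = om.cpm_and_test(counts, groups)
        assert out["t"].tolist() == pytest.approx([0.0, 0.0])
        assert out["p_value"].tolist() == pytest.approx([1.0, 1.0])
        assert out["p_adjusted"].tolist() == pytest.approx([1.0, 1.0])

    def test_needs_two_samples_per_group(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2], "b2": [3]})
        with pytest.raises(ValueError, match="2 samples"):
            om.cpm_and_test(counts, {"a1": "A", "b1": "B", "b2": "B"})

    def test_adjusted_never_below_raw(self):
        counts, groups, _ = om.simulate_count_matrix(
            n_features=200, fold_changes={0: 4.0, 1: 0.25}, seed=9
        )
        out = om.cpm_and_test(counts, groups)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(om.holm_sidak([0.2]), [0.2])

    def test_worked_example(self):
        expected = [1 - 0.99**3, 1 - 0.97**2, 1 - 0.97**2]
        np.testing.assert_allclose(om.holm_sidak([0.01, 0.04, 0.03]), expected)

    def test_zeros_stay_zero(self):
        np.testing.assert_allclose(om.holm_sidak([0.0, 0.0, 0.0]), [0.0, 0.0, 0.0])

    def test_empty(self):
        assert om.holm_sidak([]).size == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_stepdown_bisection_oracle(self, p):
        np.testing.assert_allclose(om.holm_sidak(p), brute_holm_sidak(p), atol=1e-9)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_dominated_by_single_step_sidak(self, p):
        """Step-down adjusted values never exceed the single-step 1-(1-p)^m."""
        p = np.asarray(p)
        single = 1 - (1 - p) ** len(p)
        assert (om.holm_sidak(p) <= single + 1e-12).all()

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=30)
        expected = sm.stats.multipletests(p, method="holm-sidak")[1]
        np.testing.assert_allclose(om.holm_sidak(p), expected)
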