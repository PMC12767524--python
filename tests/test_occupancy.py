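"""Transcription-normalized occupancy, rank-sum tests, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nexuskit.coverage import ProfileMatrix
from nexuskit.occupancy import (
    binding_correlation,
    cage_normalize,
    compare_types,
    delta_correlation,
    rank_sum_test,
    tbp_window_sums,
)


def uniform_matrix(ids, window_total, w=60):
    n = len(ids)
    width = 2 * w + 1
    pos = np.zeros((n, width))
    sl = slice(w - 50, w + 51)
    for i, t in enumerate(window_total):
        pos[i, sl] = t / 101.0 / 2.0
    return ProfileMatrix(list(ids), w, pos, pos.copy())


class TestCageNormalize:
    def test_occupancy_scalar(self):
        m = uniform_matrix(["a"], [50.0])
        out = cage_normalize(m, {"a": 10.0}, mode="occupancy")
        assert out["normalized"].iloc[0] == pytest.approx(5.0)

    def test_doubling_cage_halves_occupancy(self):
        m = uniform_matrix(["a"], [50.0])
        once = cage_normalize(m, {"a": 10.0})["normalized"].iloc[0]
        twice = cage_normalize(m, {"a": 20.0})["normalized"].iloc[0]
        assert twice == pytest.approx(once / 2)

    def test_zero_cage_excluded_not_raised(self):
        m = uniform_matrix(["a", "b"], [50.0, 50.0])
        out = cage_normalize(m, {"a": 10.0, "b": 0.0})
        assert list(out["promoter_id"]) == ["a"]

    def test_profile_mode_divides_base_values(self):
        m = uniform_matrix(["a"], [101.0 * 2])
        out = cage_normalize(m, {"a": 2.0}, mode="profile")
        sl = out.window_slice(-50, 50)
        np.testing.assert_allclose(out.sense_positive[0, sl], 0.5)


def exact_ranksum_enumeration(x, y) -> float:
    """Two-sided p by enumerating all group assignments of the pooled data."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2
    stats = [
        sum(sorted(ranks[pooled[i]] for i in comb))
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestRankSumTest:
    def test_identical_groups_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_matches_exact_enumeration(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(
            exact_ranksum_enumeration([1, 2, 3], [4, 5, 6])
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = list(rng.normal(size=4))
            y = list(rng.normal(size=5))
            assert rank_sum_test(x, y) == pytest.approx(exact_ranksum_enumeration(x, y))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(loc=0.5, size=25)
        assert rank_sum_test(x, y) == pytest.approx(
            rank_sum_test(np.exp(x), np.exp(y))
        )

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])

    def test_null_calibration_and_power(self):
        """False-positive rate near alpha under the generator's noise model;
        a 2x occupancy deficit at n = 100/class is detected reliably."""
        rng = np.random.default_rng(2)
        alpha = 0.05
        false_pos = 0
        detected = 0
        n_sims = 200
        for _ in range(n_sims):
            a = rng.lognormal(0.0, 0.25, size=100)
            b = rng.lognormal(0.0, 0.25, size=100)
            if rank_sum_test(a, b) < alpha:
                false_pos += 1
        for _ in range(50):
            a = rng.lognormal(0.0, 0.25, size=100)
            b = 0.5 * rng.lognormal(0.0, 0.25, size=100)
            if rank_sum_test(a, b) < alpha:
                detected += 1
        assert false_pos <= 24  # ~binomial(200, 0.05) upper tail
        assert detected / 50 >= 0.8


class TestCompareTypes:
    def test_pairwise_frame(self):
        df = pd.DataFrame(
            {
                "group": ["A"] * 3 + ["B"] * 3,
                "normalized": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        out = compare_types(df)
        assert len(out) == 1
        assert out["p"].iloc[0] == pytest.approx(0.1)


class TestBindingCorrelation:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(3)
        x = rng.random(20) * 10
        table = pd.DataFrame({"f1": x, "f2": x})
        corr = binding_correlation(table)
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.distance[0, 1] == pytest.approx(0.0)

    def test_perfect_anticorrelation_after_log(self):
        """A pair anti-monotone and linear on the log2(x+1) scale gives
        r = -1 and distance 2."""
        u = np.linspace(0.0, 5.0, 20)
        x = 2.0**u - 1.0
        y = 2.0 ** (5.0 - u) - 1.0
        corr = binding_correlation(pd.DataFrame({"f1": x, "f2": y}))
        assert corr.r[0, 1] == pytest.approx(-1.0)
        assert corr.distance[0, 1] == pytest.approx(2.0)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.random((30, 4)) * 50, columns=list("abcd"))
        perm = rng.permutation(30)
        a = binding_correlation(table)
        b = binding_correlation(table.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(a.r, b.r)

    def test_ward_first_merge_matches_brute_force(self):
        """On 3 factors the first Ward merge is the closest 1-r pair."""
        rng = np.random.default_rng(5)
        base = rng.random(40) * 20
        table = pd.DataFrame(
            {
                "close1": base + rng.normal(0, 0.5, 40),
                "close2": base + rng.normal(0, 0.5, 40),
                "far": rng.random(40) * 20,
            }
        )
        corr = binding_correlation(table)
        d = corr.distance
        pairs = [(0, 1), (0, 2), (1, 2)]
        best = min(pairs, key=lambda ij: d[ij])
        merged = set(corr.linkage_matrix[0, :2].astype(int))
        assert merged == set(best)

    def test_constant_column_dropped_with_warning(self):
        table = pd.DataFrame(
            {"f1": [1.0, 2.0, 3.0], "f2": [4.0, 5.0, 9.0], "flat": [2.0, 2.0, 2.0]}
        )
        with pytest.warns(UserWarning):
            corr = binding_correlation(table)
        assert corr.factors == ["f1", "f2"]

    def test_newick_export_contains_all_factors(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.random((10, 3)), columns=["x", "y", "z"])
        nwk = binding_correlation(table).to_newick()
        assert nwk.endswith(";") and all(f in nwk for f in "xyz")


class TestDeltaCorrelation:
    def _tables(self, coupled=True, n=200, seed=7):
        rng = np.random.default_rng(seed)
        tbp_down = rng.lognormal(0, 0.5, n)
        taf2_c = tbp_down * rng.lognormal(0, 0.1, n) if coupled else rng.lognormal(0, 0.5, n)
        other = rng.lognormal(0, 0.5, n)
        control = pd.DataFrame({"TAF2": taf2_c, "TAF5": other})
        treated = pd.DataFrame(
            {"TAF2": rng.lognormal(0, 0.5, n), "TAF5": rng.lognormal(0, 0.5, n)}
        )
        tbp_c = pd.DataFrame({"downstream": tbp_down})
        tbp_t = pd.DataFrame({"downstream": rng.lognormal(0, 0.5, n)})
        return control, treated, tbp_c, tbp_t

    def test_identical_conditions_give_zero_delta(self):
        control, _, tbp_c, _ = self._tables()
        out = delta_correlation(control, control, tbp_control=tbp_c, tbp_treated=tbp_c)
        np.testing.assert_allclose(out["delta_pcc"], 0.0, atol=1e-12)

    def test_control_only_coupling_detected(self):
        control, treated, tbp_c, tbp_t = self._tables(coupled=True)
        out = delta_correlation(control, treated, tbp_control=tbp_c, tbp_treated=tbp_t)
        out = out.set_index("factor")
        assert out.loc["TAF2", "delta_pcc"] > out.loc["TAF5", "delta_pcc"]
        assert np.all(out["delta_pcc"].abs() <= 2.0)

    def test_mismatched_promoters_raise(self):
        control, treated, tbp_c, tbp_t = self._tables()
        with pytest.raises(ValueError):
            delta_correlation(
                control, treated.iloc[:-1], tbp_control=tbp_c, tbp_treated=tbp_t
            )


def test_tbp_window_sums_defaults():
    m = uniform_matrix(["a", "b"], [101.0, 202.0])
    sums = tbp_window_sums(m)
    assert list(sums.columns) == ["upstream", "downstream"]
    # uniform 0.5/bp per strand over [-50,50]: upstream window is 16 bp wide
    assert sums.loc["a", "upstream"] == pytest.approx(16.0)
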