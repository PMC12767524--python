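"""Rank transform, k-means profile clustering and element enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from nexuskit.clustering import (
    element_enrichment,
    kmeans_profiles,
    rank_transform,
    select_top_signal,
)
from nexuskit.coverage import ProfileMatrix


def make_matrix(totals, w=45):
    """One promoter per requested window total, uniform over the window."""
    n = len(totals)
    width = 2 * w + 1
    pos = np.zeros((n, width))
    sl = slice(w - 40, w + 41)  # [-40, +40]
    for i, t in enumerate(totals):
        pos[i, sl] = t / 81.0 / 2.0
    return ProfileMatrix(
        [f"p{i}" for i in range(n)], w, pos, pos.copy()
    )


class TestSelectTopSignal:
    def test_bottom_decile_dropped(self):
        m = make_matrix(list(range(1, 11)))
        kept = select_top_signal(m)
        assert len(kept.promoter_ids) == 9
        assert "p0" not in kept.promoter_ids  # the total-1 promoter

    def test_ties_at_cut_are_kept(self):
        m = make_matrix([5.0] * 10)
        assert len(select_top_signal(m).promoter_ids) == 10

    def test_kept_totals_dominate_dropped(self):
        rng = np.random.default_rng(0)
        totals = rng.random(37) * 100
        m = make_matrix(list(totals))
        kept = select_top_signal(m)
        kept_ids = set(kept.promoter_ids)
        kept_totals = [t for i, t in enumerate(totals) if f"p{i}" in kept_ids]
        dropped = [t for i, t in enumerate(totals) if f"p{i}" not in kept_ids]
        assert min(kept_totals) >= max(dropped)

    def test_window_exceeding_matrix_raises(self):
        m = make_matrix([1.0] * 5, w=30)
        with pytest.raises(ValueError):
            select_top_signal(m, window=(-40, 40))


class TestRankTransform:
    def test_examples(self):
        out = rank_transform(np.array([[5.0, 1.0, 3.0]]))
        np.testing.assert_allclose(out.values[0], [1.0, 1 / 3, 2 / 3])
        out = rank_transform(np.array([[2.0, 2.0, 5.0]]))
        np.testing.assert_allclose(out.values[0], [0.5, 0.5, 1.0])

    def test_monotone_invariance_on_tie_free_rows(self):
        rng = np.random.default_rng(1)
        x = rng.permutation(20).astype(float)[None, :]
        a = rank_transform(x).values
        b = rank_transform(np.exp(x) + 7).values
        np.testing.assert_allclose(a, b)

    def test_range_and_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 17))
        out = rank_transform(x).values
        assert np.all(out > 0) and np.all(out <= 1)
        n = x.shape[1]
        np.testing.assert_allclose(out.mean(axis=1), (n + 1) / (2 * n))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rank_transform(np.zeros((2, 0)))


def planted_rank_profiles(n_per_class=50, seed=3):
    """Four distinct footprint shapes as rank-transformed feature rows."""
    rng = np.random.default_rng(seed)
    offsets = np.arange(-40, 41)
    shapes = {
        "sharp_up": np.exp(-0.5 * ((offsets + 18) / 2.0) ** 2),
        "downstream": np.exp(-0.5 * ((offsets - 32) / 3.0) ** 2),
        "diffuse": np.exp(-0.5 * (offsets / 20.0) ** 2),
        "flat": np.full(len(offsets), 0.02),
    }
    rows, labels = [], []
    for name, shape in shapes.items():
        for _ in range(n_per_class):
            noisy = shape * rng.lognormal(0, 0.1) + rng.normal(0, 0.01, len(offsets))
            rows.append(np.concatenate([noisy, np.roll(noisy, 4)]))
            labels.append(name)
    return rank_transform(np.vstack(rows)), labels


class TestKmeansProfiles:
    def test_k_one_centroid_is_column_mean(self):
        ranked, _ = planted_rank_profiles(n_per_class=5)
        res = kmeans_profiles(ranked, k=1, n_starts=5, seed=0)
        np.testing.assert_allclose(res.centroids[0], ranked.values.mean(axis=0))
        assert set(res.assignments) == {1}

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import rand_score

        ranked, labels = planted_rank_profiles(n_per_class=100)
        res = kmeans_profiles(ranked, k=4, n_starts=100, max_iter=30, seed=0)
        assert rand_score(labels, res.assignments) >= 0.99

    def test_partition_invariant_to_row_shuffling(self):
        ranked, labels = planted_rank_profiles(n_per_class=30)
        res = kmeans_profiles(ranked, k=4, n_starts=100, seed=0)
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(labels))
        from nexuskit.clustering import RankProfileMatrix

        shuffled = RankProfileMatrix(
            [ranked.promoter_ids[i] for i in perm], ranked.values[perm]
        )
        res2 = kmeans_profiles(shuffled, k=4, n_starts=100, seed=1)
        a = pd.Series(res.assignments, index=res.promoter_ids)
        b = pd.Series(res2.assignments, index=res2.promoter_ids)
        from sklearn.metrics import rand_score

        assert rand_score(a.sort_index(), b.sort_index()) == 1.0

    def test_fewer_rows_than_k_raises(self):
        ranked = rank_transform(np.random.default_rng(0).random((3, 5)))
        with pytest.raises(ValueError):
            kmeans_profiles(ranked, k=4)


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c

    def pmf(k):
        return (
            math.comb(row1, k)
            * math.comb(n - row1, col1 - k)
            / math.comb(n, col1)
        )

    p_obs = pmf(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """From-scratch Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


class TestElementEnrichment:
    def _setup(self, in_hits, in_total, out_hits, out_total):
        ids = [f"p{i}" for i in range(in_total + out_total)]
        assignments = pd.Series(
            [1] * in_total + [2] * out_total, index=ids
        )
        presence = pd.DataFrame(
            {
                "E": [i < in_hits for i in range(in_total)]
                + [i < out_hits for i in range(out_total)]
            },
            index=ids,
        )
        return assignments, presence

    def test_ratio_arithmetic(self):
        assignments, presence = self._setup(10, 100, 5, 100)
        res = [r for r in element_enrichment(assignments, presence) if r.cluster == 1]
        assert res[0].ratio == pytest.approx(2.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            in_total = int(rng.integers(5, 60))
            out_total = int(rng.integers(5, 60))
            in_hits = int(rng.integers(0, in_total + 1))
            out_hits = int(rng.integers(0, out_total + 1))
            assignments, presence = self._setup(in_hits, in_total, out_hits, out_total)
            res = [r for r in element_enrichment(assignments, presence) if r.cluster == 1]
            expected = fisher_two_sided_oracle(
                in_hits, in_total - in_hits, out_hits, out_total - out_hits
            )
            assert res[0].p == pytest.approx(expected, abs=1e-10)

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(6)
        ids = [f"p{i}" for i in range(60)]
        assignments = pd.Series(rng.integers(1, 5, size=60), index=ids)
        presence = pd.DataFrame(
            rng.random((60, 5)) < 0.3, index=ids, columns=list("ABCDE")
        )
        res = element_enrichment(assignments, presence)
        p = np.array([r.p for r in res])
        q = np.array([r.q for r in res])
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)

    def test_absent_element_degenerate(self):
        assignments, presence = self._setup(0, 20, 0, 30)
        res = element_enrichment(assignments, presence)
        assert all(r.p == 1.0 for r in res)
        assert all(math.isnan(r.ratio) for r in res)

    def test_element_only_in_cluster_gives_infinite_ratio(self):
        assignments, presence = self._setup(5, 20, 0, 30)
        res = [r for r in element_enrichment(assignments, presence) if r.cluster == 1]
        assert math.isinf(res[0].ratio)
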