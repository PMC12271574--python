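import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plumedpr import diversity

from conftest import random_counts


def mpd_double_loop(weights, d):
    """Brute-force oracle: explicit sum over ordered taxon pairs."""
    num = den = 0.0
    n = len(weights)
    for i in range(n):
        for j in range(n):
            if i == j or weights[i] == 0 or weights[j] == 0:
                continue
            num += weights[i] * weights[j] * d[i, j]
            den += weights[i] * weights[j]
    return num / den if den else float("nan")


class TestCophenetic:
    def test_hand_path_sums(self, toy_tree):
        d = diversity.cophenetic_distances(toy_tree)
        assert d.loc["A", "B"] == 3
        assert d.loc["A", "C"] == 5
        assert d.loc["B", "C"] == 6

    def test_zero_diagonal_and_symmetry(self, toy_tree):
        d = diversity.cophenetic_distances(toy_tree)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)


class TestRichnessShannon:
    def test_uniform_maximum(self):
        counts = pd.DataFrame([[5, 5, 5, 5]])
        out = diversity.richness_shannon(counts)
        assert out.loc[0, "richness"] == 4
        assert out.loc[0, "shannon"] == pytest.approx(np.log(4))

    def test_single_taxon(self):
        out = diversity.richness_shannon(pd.DataFrame([[7, 0]]))
        assert out.loc[0, "richness"] == 1
        assert out.loc[0, "shannon"] == 0

    def test_hand_entropy(self):
        out = diversity.richness_shannon(pd.DataFrame([[2, 1, 1]]))
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert out.loc[0, "shannon"] == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=50),
                    min_size=1, max_size=12))
    def test_shannon_bounded_by_log_richness(self, row):
        out = diversity.richness_shannon(pd.DataFrame([row]))
        assert out.loc[0, "shannon"] <= np.log(out.loc[0, "richness"]) + 1e-12
        if len(set(row)) == 1:
            assert out.loc[0, "shannon"] == pytest.approx(np.log(len(row)))


class TestWeightedMPD:
    def test_single_pair_weights_cancel(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        assert diversity.weighted_mpd([3.0, 11.0], d) == pytest.approx(0.6)

    def test_hand_triple(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        assert diversity.weighted_mpd([1, 1, 2], d) == pytest.approx(0.44)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.random((5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        w = rng.random(5)
        assert diversity.weighted_mpd(w, d) == pytest.approx(
            diversity.weighted_mpd(10 * w, d), abs=1e-12)

    def test_fewer_than_two_taxa_is_nan(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        assert np.isnan(diversity.weighted_mpd([1.0, 0.0], d))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(3, 10)
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            w = rng.random(n) * (rng.random(n) < 0.8)
            if (w > 0).sum() < 2:
                continue
            assert diversity.weighted_mpd(w, d) == pytest.approx(
                mpd_double_loop(w, d), abs=1e-12)


class TestIndependentSwap:
    def test_unique_checkerboard_is_swapped(self):
        out = diversity.independent_swap(pd.DataFrame([[1, 0], [0, 1]]),
                                         n_swaps=1, seed=0)
        assert out.to_numpy().tolist() == [[0, 1], [1, 0]]

    def test_no_checkerboard_is_identity(self):
        mat = pd.DataFrame([[1, 1], [1, 0]])
        out = diversity.independent_swap(mat, n_swaps=5, seed=0)
        assert out.to_numpy().tolist() == mat.to_numpy().tolist()

    def test_abundances_carried_not_binarized(self):
        out = diversity.independent_swap(pd.DataFrame([[7, 0], [0, 3]]),
                                         n_swaps=1, seed=0)
        assert sorted(out.to_numpy().ravel().tolist()) == [0, 0, 3, 7]

    def test_negative_swaps_rejected(self):
        with pytest.raises(ValueError):
            diversity.independent_swap(pd.DataFrame([[1]]), n_swaps=-1, seed=0)

    def test_margins_preserved_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for k in range(25):
            counts = random_counts(rng)
            out = diversity.independent_swap(counts, n_swaps=60, seed=k)
            assert ((counts > 0).sum(0) == (out > 0).sum(0)).all()
            assert ((counts > 0).sum(1) == (out > 0).sum(1)).all()
            assert counts.to_numpy().sum() == out.to_numpy().sum()


def ses_mpd_brute_force(counts, dists, n_null, n_swaps, seed):
    """Independent SES re-implementation: per-sample python loops over the
    same replicate-seed protocol."""
    d = dists.to_numpy()
    obs = np.array([diversity.weighted_mpd(row, d)
                    for row in counts.to_numpy(dtype=float)])
    children = np.random.SeedSequence(seed).spawn(n_null)
    nulls = np.empty((n_null, counts.shape[0]))
    for k, child in enumerate(children):
        # same replicate-seed protocol as the library path
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        mat = counts.to_numpy().astype(np.int64).copy()
        diversity._swap_kernel(mat, n_swaps, max(1, n_swaps) * 200, sub_seed)
        nulls[k] = [diversity.weighted_mpd(row, d) for row in mat.astype(float)]
    mean = np.nanmean(nulls, axis=0)
    sd = np.nanstd(nulls, axis=0, ddof=1)
    ses = (obs - mean) / sd
    ses[sd < 1e-12] = np.nan  # degenerate null: SES undefined
    return ses


class TestSesMpd:
    def test_matches_brute_force_reimplementation(self, toy_tree):
        rng = np.random.default_rng(3)
        counts = random_counts(rng, n_samples=4, n_taxa=4, fill=0.7)
        counts = counts.loc[(counts.sum(1) > 0)]
        d = rng.random((4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dists = pd.DataFrame(d, index=counts.columns, columns=counts.columns)
        table, _ = diversity.ses_mpd(counts, dists, n_null=199, n_swaps=50,
                                     seed=99)
        expected = ses_mpd_brute_force(counts, dists, n_null=199, n_swaps=50,
                                       seed=99)
        got = table["ses_mpd"].to_numpy()
        assert np.isnan(expected).tolist() == np.isnan(got).tolist()
        ok = np.isfinite(expected)
        assert np.allclose(got[ok], expected[ok], atol=1e-12)

    def test_degenerate_null_gives_nan(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], columns=["A", "B"])
        dists = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["A", "B"],
                             columns=["A", "B"])
        table, _ = diversity.ses_mpd(counts, dists, n_null=10, seed=0)
        assert table["ses_mpd"].isna().all()

    def test_dispersed_community_scores_positive(self, two_clade_tree):
        # a community of tips drawn from both deep clades is more dispersed
        # than its swap null built from within-clade communities
        d = diversity.cophenetic_distances(two_clade_tree)
        taxa = ["A", "B", "C", "D", "E", "F"]
        rows = {"focal": {"A": 5, "D": 5},
                "s1": {"A": 5, "B": 5}, "s2": {"B": 5, "C": 5},
                "s3": {"D": 5, "E": 5}, "s4": {"E": 5, "F": 5},
                "s5": {"A": 5, "C": 5}, "s6": {"D": 5, "F": 5}}
        counts = pd.DataFrame(0, index=list(rows), columns=taxa)
        for s, tt in rows.items():
            for t, v in tt.items():
                counts.loc[s, t] = v
        table, _ = diversity.ses_mpd(counts, d.loc[taxa, taxa],
                                     n_null=199, seed=11)
        assert table.loc["focal", "ses_mpd"] > 0
        assert (table.drop("focal")["ses_mpd"] < 0).all()
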