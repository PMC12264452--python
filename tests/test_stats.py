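"""Cluster permutation engine and the classical statistics layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats as sps

import cerebwm as c
from cerebwm import stats as st


class TestChannelAdjacency:
    def test_two_channels_within_radius_are_adjacent(self):
        m = c.Montage(("a", "b"), np.array([[0, 0, 0], [0.01, 0, 0]]))
        adj = st.channel_adjacency(m, radius=0.02)
        assert adj.matrix[0, 1] and adj.matrix[1, 0]

    def test_radius_below_min_distance_rejected(self):
        m = c.Montage(("a", "b"), np.array([[0, 0, 0], [0.05, 0, 0]]))
        with pytest.raises(ValueError, match="radius"):
            st.channel_adjacency(m, radius=0.01)

    def test_default_radius_connects_default_montage(self, adjacency16):
        counts = adjacency16.neighbour_counts()
        assert counts.min() >= 1


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self, adjacency16, rng):
        a = rng.standard_normal((10, 16, 20))
        res = st.cluster_permutation_test(a, a.copy(), adjacency16,
                                          paired=True, n_permutations=200,
                                          seed=0)
        assert res.clusters == []
        assert np.allclose(res.t_obs, 0.0)

    def test_constant_offset_gives_floor_pvalue(self, adjacency16, rng):
        """When the effect dwarfs noise, a single all-points cluster reaches
        the permutation floor p = 1/(n_perm+1)."""
        a = rng.standard_normal((20, 16, 20))
        res = st.cluster_permutation_test(a + 5.0, a, adjacency16,
                                          paired=True, n_permutations=500,
                                          seed=0)
        assert len(res.clusters) == 1
        cl = res.clusters[0]
        assert len(cl.points) == 16 * 20
        assert cl.pvalue == pytest.approx(1 / 501)
        assert cl.tail == "pos"

    def test_single_electrode_clusters_discarded(self, rng):
        """A suprathreshold blob confined to one electrode never forms an
        admissible cluster."""
        m = c.generate_montage(8)
        adj = st.channel_adjacency(m)
        a = rng.standard_normal((12, 8, 20)) * 0.01
        b = a.copy()
        a[:, 0, 5:10] += 5.0  # strong effect on one channel only
        res = st.cluster_permutation_test(a, b, adj, paired=True,
                                          n_permutations=200, seed=0)
        for cl in res.clusters:
            assert len(cl.channels) >= 2

    def test_injected_effect_recovered_in_space_and_time(self, rng):
        m = c.generate_montage(16)
        adj = st.channel_adjacency(m)
        i1, i2 = m.index(["FC1", "FCz"])
        a = rng.standard_normal((15, 16, 40))
        b = a + 0.0
        a = a.copy()
        a[:, [i1, i2], 10:20] += 1.5
        res = st.cluster_permutation_test(a, b, adj, paired=True,
                                          n_permutations=500, seed=3)
        sig = res.significant()
        assert sig
        pts = set(sig[0].points)
        injected = {(ch, t) for ch in (i1, i2) for t in range(10, 20)}
        overlap = len(pts & injected) / len(injected)
        assert overlap >= 0.5

    def test_seed_reproducibility(self, adjacency16, rng):
        a = rng.standard_normal((10, 16, 15))
        b = rng.standard_normal((10, 16, 15)) + 0.4
        r1 = st.cluster_permutation_test(a, b, adjacency16, paired=False,
                                         n_permutations=300, seed=42)
        r2 = st.cluster_permutation_test(a, b, adjacency16, paired=False,
                                         n_permutations=300, seed=42)
        assert [cl.pvalue for cl in r1.clusters] == \
               [cl.pvalue for cl in r2.clusters]

    def test_axis_mismatch_rejected(self, adjacency16, rng):
        a = rng.standard_normal((10, 16, 15))
        with pytest.raises(ValueError):
            st.cluster_permutation_test(a, a[:, :8], adjacency16, paired=True)

    def test_low_permutation_count_warns(self, adjacency16, rng):
        a = rng.standard_normal((6, 16, 5))
        with pytest.warns(UserWarning):
            st.cluster_permutation_test(a, a + 0.1, adjacency16, paired=True,
                                        n_permutations=50, seed=0)


def test_observed_clusters_match_mne_reference(rng):
    """Cluster formation and masses agree with the independent
    implementation in mne.stats on the same threshold and adjacency
    (minimum-channel rule disabled, which mne does not apply)."""
    from scipy import sparse
    from mne.stats import permutation_cluster_1samp_test

    m = c.generate_montage(8)
    adj = st.channel_adjacency(m)
    d = rng.standard_normal((12, 8, 25))
    d[:, 2:5, 5:12] += 0.9
    res = st.cluster_permutation_test(d, np.zeros_like(d), adj, paired=True,
                                      n_permutations=100, min_channels=1,
                                      seed=0)
    ours = sorted(round(cl.mass, 6) for cl in res.clusters)

    thresh = float(sps.t.ppf(1 - 0.05 / 2, d.shape[0] - 1))
    t_obs, clusters, _, _ = permutation_cluster_1samp_test(
        d.transpose(0, 2, 1), threshold=thresh, tail=0,
        adjacency=sparse.csr_matrix(adj.matrix), n_permutations=100,
        seed=0, out_type="mask", verbose="error")
    theirs = sorted(round(float(t_obs[cl].sum()), 6) for cl in clusters)
    assert ours == theirs


class TestFdrBh:
    def test_textbook_example_all_rejected(self):
        mask = st.fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert mask.all()

    def test_all_ones_rejects_nothing(self):
        assert not st.fdr_bh([1.0, 1.0, 1.0]).any()

    def test_single_pvalue_reduces_to_raw_threshold(self):
        assert st.fdr_bh([0.04], q=0.05)[0]
        assert not st.fdr_bh([0.06], q=0.05)[0]

    def test_empty_input(self):
        assert st.fdr_bh([]).size == 0

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = st.fdr_bh(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    @given(st_h.lists(st_h.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bh_rejections_contain_bonferroni(self, pvals):
        bh = st.fdr_bh(pvals, q=0.05)
        bonf = st.bonferroni(pvals, alpha=0.05)
        assert np.all(bh[bonf])  # every Bonferroni rejection is a BH rejection


class TestNormalityGate:
    def test_normal_samples_stay_parametric(self):
        routes = [st.normality_gate(
            {"a": np.random.default_rng(s).normal(size=30)})
            for s in range(40)]
        frac = np.mean([r == "parametric" for r in routes])
        assert frac >= 0.85  # Shapiro-Wilk at alpha=0.05 keeps ~95%

    def test_exponential_samples_route_nonparametric(self):
        routes = [st.normality_gate(
            {"a": np.random.default_rng(s).exponential(size=30)})
            for s in range(40)]
        frac = np.mean([r == "nonparametric" for r in routes])
        assert frac >= 0.8

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            st.normality_gate({"a": [1.0, 2.0]})


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = st.pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_reflection(self):
        x = np.arange(10.0)
        r, _ = st.pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = st.pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.pearson_corr([1, 1, 1], [1, 2, 3])


def test_null_cluster_pvalues_stochastically_valid(adjacency16):
    """Under the null, the smallest cluster p-value is rarely below alpha:
    the family-wise rejection rate stays near the nominal level."""
    rejections = 0
    n_sim = 60
    for s in range(n_sim):
        r = np.random.default_rng(10_000 + s)
        a = r.standard_normal((12, 16, 15))
        b = r.standard_normal((12, 16, 15))
        res = st.cluster_permutation_test(a, b, adjacency16, paired=True,
                                          n_permutations=250, seed=s)
        rejections += bool(res.significant())
    assert rejections / n_sim <= 0.15
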