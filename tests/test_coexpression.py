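"""Spearman matrix, sign-blind correlation distance, complete-linkage tree."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from tissuescreen import (
    CorrelationMatrix,
    DistanceMatrix,
    SynthBlockConfig,
    cophenetic_correlation,
    correlation_distance,
    cut,
    generate_correlated_blocks,
    hcluster,
    select_k,
    spearman_matrix,
    to_newick,
)


def random_distance_matrix(rng, n):
    d = rng.uniform(0.01, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"g{i}" for i in range(n)], d)


class TestSpearmanMatrix:
    def test_monotone_pair_is_one(self, rng):
        a = rng.normal(size=10)
        m = np.vstack([a, 2 * a])
        corr = spearman_matrix(m, ["a", "b"])
        assert corr.rho[0, 1] == pytest.approx(1.0)

    def test_anti_monotone_pair_is_minus_one(self, rng):
        a = rng.normal(size=10)
        corr = spearman_matrix(np.vstack([a, -a]), ["a", "b"])
        assert corr.rho[0, 1] == pytest.approx(-1.0)

    def test_matches_pairwise_scipy_oracle(self, rng):
        x = rng.normal(size=(4, 6))
        corr = spearman_matrix(x)
        for i, j in itertools.combinations(range(4), 2):
            expected = spearmanr(x[i], x[j]).statistic
            assert corr.rho[i, j] == pytest.approx(expected, abs=1e-12)

    def test_midranks_on_ties_match_scipy(self, rng):
        x = rng.integers(0, 3, size=(3, 12)).astype(float)  # many ties
        corr = spearman_matrix(x)
        for i, j in itertools.combinations(range(3), 2):
            expected = spearmanr(x[i], x[j]).statistic
            if np.isnan(expected):
                continue
            assert corr.rho[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_flagged_and_zeroed(self, rng):
        x = np.vstack([np.full(8, 3.0), rng.normal(size=8)])
        corr = spearman_matrix(x, ["const", "var"])
        assert corr.constant_genes == ["const"]
        assert corr.rho[0, 1] == 0.0
        assert corr.rho[0, 0] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            spearman_matrix(np.zeros((2, 2)))


class TestCorrelationDistance:
    def test_anchor_points(self):
        rho = np.array([[1.0, 1.0, -1.0, 0.0],
                        [1.0, 1.0, 0.5, 0.0],
                        [-1.0, 0.5, 1.0, 0.0],
                        [0.0, 0.0, 0.0, 1.0]])
        d = correlation_distance(CorrelationMatrix(list("abcd"), rho)).d
        assert d[0, 1] == 0.0   # rho = 1
        assert d[0, 2] == 0.0   # rho = -1: anti-correlated genes are close
        assert d[0, 3] == 1.0   # rho = 0
        assert d[1, 2] == 0.5

    def test_sign_blindness(self, rng):
        """d(rho) = d(-rho): the distance ignores the correlation sign."""
        n = 5
        r = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, size=(n, n))), -1, 1)
        np.fill_diagonal(r, 1.0)
        d_pos = correlation_distance(CorrelationMatrix([f"g{i}" for i in range(n)], r)).d
        flipped = -r
        np.fill_diagonal(flipped, 1.0)
        d_neg = correlation_distance(
            CorrelationMatrix([f"g{i}" for i in range(n)], flipped)
        ).d
        assert np.allclose(d_pos, d_neg)

    def test_elementwise_oracle(self, rng):
        n = 6
        r = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, size=(n, n))), -1, 1)
        np.fill_diagonal(r, 1.0)
        d = correlation_distance(CorrelationMatrix([f"g{i}" for i in range(n)], r)).d
        for i in range(n):
            for j in range(n):
                expected = 0.0 if i == j else 1 - abs(r[i, j])
                assert d[i, j] == pytest.approx(expected)


class TestHcluster:
    def test_hand_computed_three_points(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        dendro = hcluster(DistanceMatrix(["a", "b", "c"], d))
        assert dendro.merges[0][:2] == (0, 1)
        assert dendro.merges[0][2] == pytest.approx(0.1)
        # complete linkage: c joins at max(0.9, 0.8)
        assert dendro.merges[1][2] == pytest.approx(0.9)

    def test_two_leaves(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        dendro = hcluster(DistanceMatrix(["a", "b"], d))
        assert len(dendro.merges) == 1
        assert dendro.merges[0][2] == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(20))
    def test_merge_heights_match_scipy_linkage(self, seed):
        rng = np.random.default_rng(seed)
        dist = random_distance_matrix(rng, 8)
        dendro = hcluster(dist)
        z = linkage(dist.condensed(), method="complete")
        assert np.allclose(sorted(dendro.heights), sorted(z[:, 2]))

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            dist = random_distance_matrix(rng, 10)
            h = hcluster(dist).heights
            assert all(h2 >= h1 for h1, h2 in zip(h, h[1:]))

    def test_deterministic_tie_break_smallest_index(self):
        # equilateral: all pairs at 0.5; smallest indices merge first
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        dendro = hcluster(DistanceMatrix(["a", "b", "c"], d))
        assert dendro.merges[0][:2] == (0, 1)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            hcluster(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestCophenetic:
    def test_ultrametric_input_is_fixed_point(self):
        # two tight pairs at 0.1 joined at 0.9: already an ultrametric
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        dist = DistanceMatrix(list("abcd"), d)
        c, degenerate = cophenetic_correlation(dist, hcluster(dist))
        assert not degenerate
        assert c == pytest.approx(1.0)

    def test_two_block_planted_distances_high(self, rng):
        base = np.where(
            (np.arange(6)[:, None] < 3) == (np.arange(6)[None, :] < 3), 0.1, 0.9
        ).astype(float)
        noise = rng.uniform(-0.05, 0.05, size=(6, 6))
        d = np.clip(base + (noise + noise.T) / 2, 0.0, 1.0)
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix([f"g{i}" for i in range(6)], d)
        c, _ = cophenetic_correlation(dist, hcluster(dist))
        assert c > 0.8

    def test_matches_explicit_pairwise_extraction(self, rng):
        dist = random_distance_matrix(rng, 7)
        dendro = hcluster(dist)
        # oracle: replay merges, record the height at which each pair joins
        n = 7
        members = {i: {i} for i in range(n)}
        coph = np.zeros((n, n))
        for idx, (a, b, h) in enumerate(dendro.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
            members[n + idx] = members.pop(a) | members.pop(b)
        expected = np.corrcoef(dist.condensed(), squareform(coph, checks=False))[0, 1]
        c, _ = cophenetic_correlation(dist, dendro)
        assert c == pytest.approx(expected)

    def test_degenerate_all_equal_flagged(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix(list("abc"), d)
        c, degenerate = cophenetic_correlation(dist, hcluster(dist))
        assert degenerate


def planted_block_distance(sizes, within=0.1, between=0.9):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"g{i}" for i in range(n)], d), labels


class TestCutAndSelectK:
    def test_cut_extremes(self, rng):
        dist = random_distance_matrix(rng, 6)
        dendro = hcluster(dist)
        assert cut(dendro, 1) == [0] * 6
        assert sorted(cut(dendro, 6)) == list(range(6))
        with pytest.raises(ValueError):
            cut(dendro, 0)
        with pytest.raises(ValueError):
            cut(dendro, 7)

    def test_planted_blocks_recovered(self):
        dist, truth = planted_block_distance([4, 5])
        dendro = hcluster(dist)
        assert adjusted_rand_score(truth, cut(dendro, 2)) == 1.0

    def test_select_k_two_blocks(self):
        dist, _ = planted_block_distance([4, 5])
        dendro = hcluster(dist)
        k, scores = select_k(dist, dendro)
        assert k == 2

    def test_select_k_three_blocks(self):
        dist, truth = planted_block_distance([4, 4, 4])
        dendro = hcluster(dist)
        k, _ = select_k(dist, dendro)
        assert k == 3
        assert adjusted_rand_score(truth, cut(dendro, 3)) == 1.0

    def test_tie_breaks_to_smallest_k(self):
        # three equidistant points: every cut is equally (un)structured
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix(list("abc"), d)
        k, _ = select_k(dist, hcluster(dist), range(2, 3))
        assert k == 2


class TestBlocksEndToEnd:
    def test_noise_free_blocks_have_unit_correlation(self):
        cfg = SynthBlockConfig(block_sizes=(4, 4), n_samples=20, noise_sd=0.0, seed=1)
        x, labels, _ = generate_correlated_blocks(cfg)
        corr = spearman_matrix(x, labels)
        assert corr.rho[0, 1] == pytest.approx(1.0)
        assert corr.rho[0, 2] == pytest.approx(1.0)

    def test_two_block_pipeline_recovers_membership(self):
        cfg = SynthBlockConfig(
            block_sizes=(8, 8), n_samples=60, within_block_rho=0.9,
            noise_sd=0.4, seed=2,
        )
        x, labels, truth = generate_correlated_blocks(cfg)
        dist = correlation_distance(spearman_matrix(x, labels))
        dendro = hcluster(dist)
        k, _ = select_k(dist, dendro)
        assert k == 2
        assert adjusted_rand_score(truth, cut(dendro, 2)) == 1.0

    def test_sign_flipped_members_stay_in_block(self):
        cfg = SynthBlockConfig(
            block_sizes=(6, 6), n_samples=80, within_block_rho=0.95,
            noise_sd=0.2, sign_flip_fraction=0.5, seed=3,
        )
        x, labels, truth = generate_correlated_blocks(cfg)
        dist = correlation_distance(spearman_matrix(x, labels))
        assert adjusted_rand_score(truth, cut(hcluster(dist), 2)) == 1.0


class TestNewick:
    def test_topology_and_branch_lengths(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        nwk = to_newick(hcluster(DistanceMatrix(["a", "b", "c"], d)))
        assert nwk == "(c:0.9,(a:0.1,b:0.1):0.8);"
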