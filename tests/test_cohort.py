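"""Rank tests against enumeration oracles; cohort orchestration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from tissuescreen import (
    CohortSample,
    SynthCohortConfig,
    generate_qpcr_cohort,
    mann_whitney,
    median_fold_change,
    quantify_plate,
    run_cohort_analysis,
    wilcoxon_paired,
)
from tissuescreen.cohort import results_to_frame, round_sig
from tissuescreen.qpcr import levels_to_frame


def mw_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    dist = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        dist.append(u)
    dist = np.asarray(dist)
    p = 2 * min((dist <= u_obs).mean(), (dist >= u_obs).mean())
    return u_obs, min(p, 1.0)


def wilcoxon_enumeration_p(a, b):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist)
    p = 2 * min((dist <= w_plus).mean(), (dist >= w_plus).mean())
    return min(p, 1.0)


class TestMannWhitney:
    def test_fully_separated_pairs(self):
        u, p, exact = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert exact
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_null(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        _, p, exact = mann_whitney(vals, vals)
        assert not exact  # ties force the approximation
        assert p >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_groups_use_approximation(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p, exact = mann_whitney(a, b)
        assert not exact and 0 <= p <= 1

    @given(
        n_a=st.integers(1, 6),
        n_b=st.integers(1, 6),
        data=st.data(),
    )
    @settings(max_examples=60)
    def test_exact_path_matches_enumeration_all_shapes(self, n_a, n_b, data):
        """Exact p equals full enumeration for every group shape with
        combined n <= 8 (tie-free inputs)."""
        if n_a + n_b > 8:
            n_b = max(1, 8 - n_a)
        n = n_a + n_b
        values = data.draw(
            st.lists(st.floats(-100, 100), min_size=n, max_size=n, unique=True)
        )
        a, b = values[:n_a], values[n_a:]
        u, p, exact = mann_whitney(a, b)
        assert exact
        u_oracle, p_oracle = mw_enumeration_p(a, b)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle)

    @given(vals=st.lists(st.floats(0.1, 100), min_size=8, max_size=8, unique=True))
    def test_monotone_transform_invariance(self, vals):
        a, b = vals[:4], vals[4:]
        _, p1, _ = mann_whitney(a, b)
        _, p2, _ = mann_whitney([math.log(v) for v in a], [math.log(v) for v in b])
        assert p1 == pytest.approx(p2)

    def test_null_type_one_error_near_nominal(self):
        """Rejection rate at alpha=0.05 over simulated null cohorts (n=8 vs 8)
        stays in [0.03, 0.07]."""
        rng = np.random.default_rng(20)
        n_sim = 2000
        rejections = 0
        for _ in range(n_sim):
            _, p, _ = mann_whitney(rng.normal(size=8), rng.normal(size=8))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestWilcoxonPaired:
    def test_all_positive_differences_n5(self):
        # W = min(W+, W-) convention: all-positive differences give W = 0
        a = [10, 11, 12, 13, 14]
        b = [1, 2, 3, 4, 5]
        w, p, exact, degenerate = wilcoxon_paired(a, b)
        assert (w, exact, degenerate) == (0.0, True, False)
        assert p == pytest.approx(2 / 32)

    def test_symmetric_differences_not_significant(self):
        a = [5.0, 1.0, 6.0, 2.0]
        b = [1.0, 5.0, 2.0, 6.0]  # differences +4, -4, +4, -4
        _, p, _, _ = wilcoxon_paired(a, b)
        assert p > 0.5

    def test_all_zero_differences_degenerate(self):
        w, p, exact, degenerate = wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
        assert degenerate and p == 1.0

    def test_zero_differences_discarded(self):
        # one informative pair among zeros
        w, p, exact, degenerate = wilcoxon_paired([1.0, 2.0, 9.0], [1.0, 2.0, 3.0])
        assert not degenerate
        assert p == 1.0  # single informative pair cannot be significant

    @given(
        n=st.integers(2, 8),
        data=st.data(),
    )
    @settings(max_examples=60)
    def test_exact_path_matches_sign_flip_enumeration(self, n, data):
        diffs = data.draw(
            st.lists(
                st.floats(0.1, 50).map(lambda x: round(x, 1)),
                min_size=n, max_size=n,
            )
        )
        signs = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n))
        b = [0.0] * n
        a = [s * d for s, d in zip(signs, diffs)]
        w, p, exact, _ = wilcoxon_paired(a, b)
        assert exact
        assert p == pytest.approx(wilcoxon_enumeration_p(a, b))


class TestMedianFold:
    @pytest.mark.parametrize(
        "med_a, med_b, expected",
        [
            (93.0, 0.93, 100.0),   # strong tumor suppression
            (4.52, 0.05, 90.4),
            (2.54, 43.0, 0.06),    # tumor-elevated gene, ratio < 1
            (5.0, 5.0, 1.0),
        ],
    )
    def test_reported_ratios(self, med_a, med_b, expected):
        # groups constructed to have the stated medians
        a = [med_a / 2, med_a, med_a * 2]
        b = [med_b / 2, med_b, med_b * 2]
        fold, flagged = median_fold_change(a, b)
        assert not flagged
        assert round_sig(fold, 3) == pytest.approx(expected, abs=0.005)

    def test_tumor_over_normal_direction(self):
        # the same pair read in the tumor/normal direction: ~17-fold increase
        fold, _ = median_fold_change([43.0], [2.54])
        assert round_sig(fold, 2) == pytest.approx(17.0)

    def test_zero_denominator_flagged_infinite(self):
        fold, flagged = median_fold_change([1.0], [0.0])
        assert flagged and math.isinf(fold)


class TestRunCohortAnalysis:
    def _frame(self, cfg):
        measurements, metadata, _ = generate_qpcr_cohort(cfg)
        return levels_to_frame(quantify_plate(measurements)), metadata

    def test_planted_suppression_detected_null_not(self):
        cfg = SynthCohortConfig(
            seed=3,
            genes=("TSG1", "NULLG"),
            suppression_fold={"TSG1": 50.0},
            n_tumor_germ=10, n_adjacent_germ=10,
            n_tumor_nongerm=0, n_adjacent_nongerm=0,
            n_paired_germ=0, n_paired_nongerm=0,
        )
        frame, metadata = self._frame(cfg)
        results = results_to_frame(run_cohort_analysis(frame, metadata))
        germ = results[results["stratum"] == "germ"].set_index("gene")
        assert germ.loc["TSG1", "p_value"] < 0.01
        assert germ.loc["TSG1", "median_fold"] > 10
        assert germ.loc["NULLG", "p_value"] > 0.05

    def test_null_genes_lose_significance_at_null_rate(self):
        """With shuffled group labels the planted gene behaves like a null."""
        cfg = SynthCohortConfig(
            seed=5, genes=("TSG1",), suppression_fold={"TSG1": 50.0},
            n_tumor_germ=10, n_adjacent_germ=10,
            n_tumor_nongerm=0, n_adjacent_nongerm=0,
            n_paired_germ=0, n_paired_nongerm=0, n_control=0,
        )
        frame, metadata = self._frame(cfg)
        rng = np.random.default_rng(6)
        rejections = 0
        n_shuffles = 100
        states = [s.state for s in metadata]
        for _ in range(n_shuffles):
            perm = rng.permutation(len(states))
            shuffled = [
                CohortSample(s.sample_id, states[perm[i]], s.histology, None)
                for i, s in enumerate(metadata)
            ]
            res = results_to_frame(run_cohort_analysis(frame, shuffled))
            p = res[res["stratum"] == "germ"]["p_value"].iloc[0]
            rejections += p < 0.05
        assert rejections / n_shuffles <= 0.12

    def test_single_tumor_sample_skipped_no_crash(self):
        cfg = SynthCohortConfig(
            seed=8, n_tumor_germ=1, n_adjacent_germ=4,
            n_tumor_nongerm=0, n_adjacent_nongerm=0,
            n_paired_germ=0, n_paired_nongerm=0,
        )
        frame, metadata = self._frame(cfg)
        results = results_to_frame(run_cohort_analysis(frame, metadata))
        assert results.empty or (results["n_b"] >= 2).all()

    def test_paired_comparison_present(self):
        cfg = SynthCohortConfig(seed=9)
        frame, metadata = self._frame(cfg)
        results = results_to_frame(run_cohort_analysis(frame, metadata))
        paired = results[results["stratum"] == "paired"]
        assert set(paired["test"]) == {"wilcoxon-paired"}
        assert (paired["n_a"] == 9).all()  # 6 germ + 3 non-germ pairs

    def test_controls_only_grouping_supported(self):
        cfg = SynthCohortConfig(seed=10)
        frame, metadata = self._frame(cfg)
        results = run_cohort_analysis(frame, metadata, normal_states=("control",))
        df = results_to_frame(results)
        assert (df[df["stratum"] == "all"]["n_a"] == 2).all()

    def test_unknown_sample_rejected(self):
        cfg = SynthCohortConfig(seed=11)
        frame, metadata = self._frame(cfg)
        with pytest.raises(ValueError, match="without metadata"):
            run_cohort_analysis(frame, metadata[:-5])
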