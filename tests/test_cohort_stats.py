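"""Genomic matrix, clustering, PCA, survival and small statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from cnaloh.cohort_stats import (
    build_matrix,
    chi_square,
    fisher_exact,
    hierarchical_cluster,
    kaplan_meier,
    logrank,
    one_way_anova,
    pca,
    pearson,
    relative_expression,
    t_test,
)
from cnaloh.genome import GenomeMap
from cnaloh.segmentation import Segment


def toy_genome():
    pos = np.arange(5_000, 4_000_001, 5_000, dtype=np.int64)
    return GenomeMap(("1", "5"), {"1": 4_000_000, "5": 4_000_000},
                     {"1": pos.copy(), "5": pos.copy()})


def seg(chrom, start, end, mean, state, sample="s"):
    return Segment(sample, chrom, start, end, 10, mean, state=state)


class TestBuildMatrix:
    def test_all_neutral_sample_gives_zero_row(self):
        g = toy_genome()
        segs = {"s": [seg("1", 1, 4_000_000, 0.0, "neutral"),
                      seg("5", 1, 4_000_000, 0.0, "neutral")]}
        x, ids, bins = build_matrix(segs, g, bin_size=1_000_000)
        assert x.shape == (1, 8)
        assert np.all(x == 0.0)

    def test_whole_chr5_gain_with_chr5_restriction(self):
        g = toy_genome()
        segs = {"s": [seg("1", 1, 4_000_000, 0.0, "neutral"),
                      seg("5", 1, 4_000_000, 0.7, "gain")]}
        x, _, bins = build_matrix(segs, g, chromosomes=("5",))
        assert (bins["chrom"] == "5").all()
        assert np.all(x == 1.0)

    def test_mixed_segments_match_length_weighted_oracle(self):
        g = toy_genome()
        segs = {"s": [
            seg("1", 1, 1_500_000, 0.7, "gain"),
            seg("1", 1_500_001, 2_400_000, 0.0, "neutral"),
            seg("1", 2_400_001, 4_000_000, -0.9, "loss"),
        ]}
        x, _, bins = build_matrix(segs, g, bin_size=1_000_000, chromosomes=("1",))
        value = {"gain": 1.0, "neutral": 0.0, "loss": -1.0}
        for j, b in bins.iterrows():
            acc = 0.0
            for base_lo in range(int(b["start"]), int(b["end"]) + 1, 1_000):
                for s in segs["s"]:
                    nxt_start = {1: 1_500_001, 1_500_001: 2_400_001}.get(s.start)
                    eff_end = (nxt_start - 1) if nxt_start else 4_000_000
                    if s.start <= base_lo <= eff_end:
                        acc += value[s.state]
                        break
            assert x[0, j] == pytest.approx(acc / 1_000, abs=1e-9)

    def test_invalid_bin_size_rejected(self):
        with pytest.raises(ValueError, match="bin_size"):
            build_matrix({}, toy_genome(), bin_size=0)


class TestClustering:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (10, 5)), rng.normal(5, 0.1, (8, 5))])
        labels, order = hierarchical_cluster(x, 2)
        truth = [0] * 10 + [1] * 8
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(order) == 18

    def test_duplicate_rows_share_cluster(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        labels, _ = hierarchical_cluster(x, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="k="):
            hierarchical_cluster(np.zeros((3, 2)), 4)

    def test_deterministic_given_input_order(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 6))
        a, _ = hierarchical_cluster(x, 3)
        b, _ = hierarchical_cluster(x, 3)
        assert np.array_equal(a, b)


class TestPCA:
    def test_identical_rows_have_zero_scores(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        scores = pca(x, 2)
        assert np.allclose(scores, 0.0)

    def test_two_samples_project_on_difference_vector(self):
        x = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        scores = pca(x, 1)
        assert np.allclose(np.abs(scores[:, 0]), 1.0)
        assert scores[1, 0] > 0  # largest loading positive -> sample 2 positive

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 8))
        xc = x - x.mean(0)
        total = np.sum(xc**2)
        errors = []
        for k in range(1, 7):
            scores = pca(x, k)
            errors.append(total - np.sum(scores**2))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


class TestSurvival:
    def test_product_limit_hand_computed(self):
        sf, median = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        lookup = dict(zip(sf["time"], sf["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert median == 2.0

    def test_all_censored_median_undefined(self):
        _, median = kaplan_meier(np.array([5.0, 8.0]), np.array([0, 0]))
        assert median is None

    def test_single_event_median(self):
        _, median = kaplan_meier(np.array([5.0]), np.array([1]))
        assert median == 5.0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier(np.array([-1.0]), np.array([1]))

    def test_identical_groups_give_null_statistic(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_computed_observed_minus_expected(self):
        """A: events at 1, 2; B: events at 10, 11 (no censoring)."""
        ta, tb = np.array([1.0, 2.0]), np.array([10.0, 11.0])
        ea = eb = np.array([1, 1])
        stat, p = logrank(ta, ea, tb, eb)
        # hand computation over the four event times
        o_minus_e = (1 - 2 / 4) + (1 - 1 / 3) + (0 - 0) + (0 - 0)
        var = (2 * 2 * 1 * 3) / (4 * 4 * 3) + (1 * 2 * 1 * 2) / (3 * 3 * 2)
        assert stat == pytest.approx(o_minus_e**2 / var, rel=1e-6)

    def test_statistic_invariant_under_group_swap(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.exponential(50, 10), rng.exponential(20, 12)
        ea, eb = np.ones(10), np.ones(12)
        s1, _ = logrank(ta, ea, tb, eb)
        s2, _ = logrank(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_no_events_anywhere_gives_zero(self):
        stat, p = logrank(np.array([1.0]), np.array([0]), np.array([2.0]), np.array([0]))
        assert (stat, p) == (0.0, 1.0)


class TestSmallStats:
    def test_fisher_detects_fish_style_contrast(self):
        """10/10 vs 3/12 positives (the FISH validation contrast)."""
        _, p = fisher_exact([[10, 0], [3, 9]])
        assert p < 0.05

    @pytest.mark.parametrize("table", [[[10, 0], [3, 9]], [[5, 5], [4, 6]], [[2, 8], [7, 1]]])
    def test_fisher_matches_hypergeometric_enumeration(self, table):
        (a, b), (c, d) = table
        n = a + b + c + d
        dist = hypergeom(n, a + b, a + c)
        p_obs = dist.pmf(a)
        p_enum = sum(
            dist.pmf(k)
            for k in range(max(0, a + c - (c + d)), min(a + b, a + c) + 1)
            if dist.pmf(k) <= p_obs * (1 + 1e-9)
        )
        _, p = fisher_exact(table)
        assert p == pytest.approx(p_enum, rel=1e-9)

    def test_chi_square_and_anova_and_t_run_sensibly(self):
        _, p_chi = chi_square([[20, 5], [6, 19]])
        assert p_chi < 0.01
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        _, p_t = t_test(a, b)
        _, p_f = one_way_anova(a, b)
        assert p_t < 1e-6
        assert p_f == pytest.approx(p_t, rel=1e-6)  # 2-group ANOVA == t-test

    def test_pearson_perfectly_linear(self):
        r, _ = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)


class TestRelativeExpression:
    def test_closed_form_single_well(self):
        assert relative_expression(25.0, 20.0) == pytest.approx(2**-5)

    def test_equal_cts_give_unity(self):
        assert relative_expression(21.4, 21.4) == 1.0

    def test_duplicate_wells_geometric_mean(self):
        target, ref = np.array([25.0, 26.0]), np.array([20.0, 20.0])
        per_well = [2 ** -(t - r) for t, r in zip(target, ref)]
        expected = float(np.sqrt(per_well[0] * per_well[1]))
        assert relative_expression(target, ref) == pytest.approx(expected)

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            relative_expression(-1.0, 20.0)


class TestGenomicClusteringEndToEnd:
    def test_chr5_matrix_separates_clear_samples(self, default_cohort, default_calls):
        """Chromosome-5 clustering reproduces the benign/malignant split for
        every sample whose true chr-5 gain fraction is clearly above 0.6 or
        below 0.1."""
        x, ids, _ = build_matrix(
            default_calls["segments"], default_cohort.genome, chromosomes=("5",)
        )
        labels, _ = hierarchical_cluster(x, 2)
        flags = default_cohort.truth.flags.set_index("sample_id")
        clear_pos = {
            labels[i] for i, sid in enumerate(ids)
            if flags.loc[sid, "chr5_gain_fraction"] > 0.60
        }
        clear_neg = {
            labels[i] for i, sid in enumerate(ids)
            if flags.loc[sid, "chr5_gain_fraction"] < 0.10
        }
        assert len(clear_pos) == 1 and len(clear_neg) == 1
        assert clear_pos != clear_neg
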