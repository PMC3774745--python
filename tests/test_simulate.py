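"""Synthetic-cohort generator: signal model, determinism, architecture."""

import numpy as np
import pandas as pd
import pytest

from cnaloh.genome import default_genome
from cnaloh.io import read_events, read_phenotypes, write_events, write_phenotypes
from cnaloh.loh import AB
from cnaloh.simulate import (
    CohortConfig,
    EventSpec,
    NoiseModel,
    draw_cohort_truth,
    simulate_cohort,
    simulate_pair,
    validate_events,
)

SILENT = NoiseModel(lrr_sd=0.0, baf_sd=0.0, genotype_error=0.0, no_call_rate=0.0)


class TestSimulatePair:
    def test_zero_events_noise_free_is_identity(self, small_genome):
        prof, truth = simulate_pair(small_genome, [], SILENT, seed=3)
        assert np.all(prof.tumor_lrr == 0.0)
        assert np.all(prof.normal_lrr == 0.0)
        assert np.array_equal(truth.tumor_genotypes, truth.normal_genotypes)
        assert np.array_equal(prof.tumor_baf, prof.normal_baf)

    def test_cnloh_forces_homozygosity_with_neutral_lrr(self, small_genome):
        ev = EventSpec("1", 500_001, 1_500_000, "cnLOH", 2)
        prof, truth = simulate_pair(small_genome, [ev], SILENT, seed=4)
        idx = small_genome.marker_index("1", ev.start, ev.end)
        het = truth.normal_genotypes[idx] == AB
        assert het.any()
        assert np.all(truth.tumor_genotypes[idx][het] != AB)
        assert np.all(prof.tumor_lrr[idx] == 0.0)
        assert np.all(np.isin(prof.tumor_baf[idx][het], [0.0, 1.0]))

    def test_gain_lrr_closed_form(self, small_genome):
        ev = EventSpec("2", 1_000_001, 2_000_000, "gain", 3)
        prof, truth = simulate_pair(small_genome, [ev], SILENT, seed=5)
        idx = small_genome.marker_index("2", ev.start, ev.end)
        assert np.allclose(prof.tumor_lrr[idx], np.log2(1.5))
        het = truth.normal_genotypes[idx] == AB
        assert np.all(np.isin(np.round(prof.tumor_baf[idx][het], 6),
                              np.round([1 / 3, 2 / 3], 6)))
        outside = np.setdiff1d(np.arange(small_genome.n_markers), idx)
        assert np.all(prof.tumor_lrr[outside] == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noise_free_signal_is_piecewise_constant_means(self, small_genome, seed):
        rng = np.random.default_rng(seed)
        events = [
            EventSpec("1", 100_001, 600_000, "gain", 3),
            EventSpec("1", 1_000_001, 1_400_000, "loss", 1),
            EventSpec("5", 2_000_001, 2_900_000, "cnLOH", 2),
        ]
        prof, truth = simulate_pair(
            small_genome, events, SILENT, seed=int(rng.integers(1 << 30))
        )
        expected = np.zeros(small_genome.n_markers)
        for ev in events:
            idx = small_genome.marker_index(ev.chrom, ev.start, ev.end)
            expected[idx] = np.log2(ev.cn / 2.0) if ev.cn > 0 else -3.0
        assert np.array_equal(prof.tumor_lrr, expected)

    def test_overlapping_events_rejected_with_hint(self, small_genome):
        events = [
            EventSpec("1", 1, 500_000, "gain", 3),
            EventSpec("1", 400_000, 900_000, "loss", 1),
        ]
        with pytest.raises(ValueError, match="normalize"):
            validate_events(events, small_genome)

    def test_event_beyond_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError, match="exceeds"):
            validate_events([EventSpec("1", 1, 4_000_000, "gain", 3)], small_genome)

    def test_event_class_invariants(self):
        with pytest.raises(ValueError):
            EventSpec("1", 1, 10, "gain", 2)
        with pytest.raises(ValueError):
            EventSpec("1", 1, 10, "cnLOH", 3)
        with pytest.raises(ValueError):
            EventSpec("1", 10, 1, "gain", 3)


class TestCohort:
    def test_truth_tables_identical_across_runs(self):
        genome = default_genome(2_000_000)
        config = CohortConfig(n_aca=5, n_acc=5)
        a = draw_cohort_truth(config, genome, seed=11)
        b = draw_cohort_truth(config, genome, seed=11)
        assert a.events.to_csv() == b.events.to_csv()
        assert a.phenotypes.to_csv() == b.phenotypes.to_csv()
        assert a.flags.to_csv() == b.flags.to_csv()

    def test_chr5_probability_one_forces_large_gain(self):
        genome = default_genome(2_000_000)
        config = CohortConfig(n_aca=0, n_acc=12, chr5_gain_prob=1.0)
        truth = draw_cohort_truth(config, genome, seed=2)
        assert (truth.flags["chr5_gain_fraction"] > 0.60).all()

    def test_chr5_positive_fraction_converges(self):
        """Across seeds the chr5-positive ACC share approaches 17/22."""
        genome = default_genome(2_000_000)
        config = CohortConfig(n_aca=0, n_acc=22)
        hits = total = 0
        for seed in range(10):
            flags = draw_cohort_truth(config, genome, seed=seed).flags
            hits += int(flags["chr5_positive"].sum())
            total += len(flags)
        p = 17 / 22
        se = np.sqrt(p * (1 - p) / total)
        assert abs(hits / total - p) < 4 * se

    def test_loh_size_correlation_in_observed_band(self):
        """Mean ground-truth Pearson r(LOH count, size) lies in [0.25, 0.55]."""
        genome = default_genome()
        config = CohortConfig()
        rs = []
        for seed in range(1, 13):
            truth = draw_cohort_truth(config, genome, seed=seed)
            merged = truth.phenotypes.set_index("sample_id").join(
                truth.flags.set_index("sample_id")["n_loh"]
            )
            rs.append(np.corrcoef(merged["n_loh"], merged["size_cm"])[0, 1])
        assert 0.25 <= float(np.mean(rs)) <= 0.55

    def test_ground_truth_roundtrip(self, tmp_path):
        genome = default_genome(2_000_000)
        truth = draw_cohort_truth(CohortConfig(n_aca=3, n_acc=3), genome, seed=8)
        write_events(tmp_path / "ev.tsv", truth.events)
        write_phenotypes(tmp_path / "ph.tsv", truth.phenotypes)
        ev2 = read_events(tmp_path / "ev.tsv")
        ph2 = read_phenotypes(tmp_path / "ph.tsv")
        pd.testing.assert_frame_equal(
            truth.events.reset_index(drop=True), ev2, check_dtype=False
        )
        pd.testing.assert_frame_equal(
            truth.phenotypes.reset_index(drop=True), ph2, check_dtype=False
        )

    def test_profiles_reproducible_under_fixed_seed(self):
        genome = default_genome(2_000_000)
        config = CohortConfig(n_aca=2, n_acc=2)
        a = simulate_cohort(config, genome, seed=5)
        b = simulate_cohort(config, genome, seed=5)
        for sid in a.profiles:
            assert np.array_equal(a.profiles[sid].tumor_lrr, b.profiles[sid].tumor_lrr)
            assert np.array_equal(a.profiles[sid].tumor_baf, b.profiles[sid].tumor_baf)

    def test_group_architecture(self, default_cohort):
        """ACC carry heavier aberration load than ACA, with excess losses."""
        flags = default_cohort.truth.flags
        ev = default_cohort.truth.events
        by_group = ev.merge(flags[["sample_id", "group"]], on="sample_id")
        losses = by_group[by_group["class"] == "loss"].groupby("group").size()
        assert losses.get("ACC", 0) > losses.get("ACA", 0)
        acc_loh = flags[flags.group == "ACC"]["loh_positive"].mean()
        aca_loh = flags[flags.group == "ACA"]["loh_positive"].mean()
        assert acc_loh > aca_loh
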