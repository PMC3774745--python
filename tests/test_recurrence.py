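"""Minimal overlapping regions, group intersections, gene annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaloh.recurrence import (
    annotate_genes,
    intersect_group_regions,
    minimal_overlapping_regions,
)


def intervals_df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])


def per_base_support(rows, chrom, lo, hi):
    """Brute-force per-base distinct-sample coverage counts."""
    counts = np.zeros(hi - lo + 1, dtype=int)
    for base in range(lo, hi + 1):
        covering = {s for s, c, a, b in rows if c == chrom and a <= base <= b}
        counts[base - lo] = len(covering)
    return counts


class TestMOR:
    def test_four_identical_intervals_give_one_mor(self):
        rows = [(f"s{i}", "1", 100, 400) for i in range(4)]
        mor = minimal_overlapping_regions(intervals_df(rows), min_samples=4)
        assert len(mor) == 1
        r = mor.iloc[0]
        assert (r["start"], r["end"], r["support"]) == (100, 400, 4)
        assert r["frequency"] == 1.0

    def test_three_samples_below_minimum_give_none(self):
        rows = [(f"s{i}", "1", 100, 400) for i in range(3)]
        assert minimal_overlapping_regions(intervals_df(rows), min_samples=4).empty

    def test_staggered_intervals_match_per_base_counting(self):
        rows = [
            ("A", "1", 1, 300),
            ("B", "1", 100, 400),
            ("C", "1", 150, 350),
            ("D", "1", 200, 500),
        ]
        mor = minimal_overlapping_regions(intervals_df(rows), min_samples=3)
        oracle = per_base_support(rows, "1", 1, 500)
        kept = np.zeros(500, dtype=bool)
        for _, r in mor.iterrows():
            assert r["support"] >= 3
            kept[r["start"] - 1 : r["end"]] = True
        assert np.array_equal(kept, oracle >= 3)
        # kept length equals brute-force count (exact)
        assert kept.sum() == int((oracle >= 3).sum())

    def test_output_invariant_to_sample_order(self):
        rows = [
            ("A", "1", 1, 300),
            ("B", "1", 100, 400),
            ("C", "1", 150, 350),
            ("D", "1", 200, 500),
        ]
        a = minimal_overlapping_regions(intervals_df(rows), 3)
        b = minimal_overlapping_regions(intervals_df(rows[::-1]), 3)
        pd.testing.assert_frame_equal(a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.sampled_from(["A", "B", "C", "D", "E"]),
            st.integers(1, 80),
            st.integers(1, 80),
        ),
        min_size=1, max_size=12,
    ))
    def test_kept_length_matches_per_base_oracle(self, raw):
        rows = [(s, "1", min(a, b), max(a, b)) for s, a, b in raw]
        mor = minimal_overlapping_regions(intervals_df(rows), min_samples=2)
        oracle = per_base_support(rows, "1", 1, 160)
        kept_len = int(sum(r["end"] - r["start"] + 1 for _, r in mor.iterrows()))
        assert kept_len == int((oracle >= 2).sum())

    def test_identical_support_sets_merge_but_different_do_not(self):
        rows = [
            ("A", "1", 1, 200),
            ("B", "1", 1, 200),
            ("C", "1", 101, 200),  # support jumps from {A,B} to {A,B,C}
        ]
        mor = minimal_overlapping_regions(intervals_df(rows), min_samples=2)
        assert [(r["start"], r["end"], r["support"]) for _, r in mor.iterrows()] == [
            (1, 100, 2),
            (101, 200, 3),
        ]

    def test_min_samples_below_one_rejected(self):
        with pytest.raises(ValueError, match="min_samples"):
            minimal_overlapping_regions(intervals_df([("A", "1", 1, 2)]), 0)


def mor_df(rows):
    return pd.DataFrame(
        [
            {
                "chrom": c, "start": s, "end": e, "type": t,
                "support": 4, "frequency": 0.2, "samples": "",
            }
            for c, s, e, t in rows
        ]
    )


class TestIntersect:
    def test_identical_lists_overlap_fully(self):
        a = mor_df([("1", 100, 200, "gain"), ("2", 50, 80, "gain")])
        table, frac = intersect_group_regions(a, a.copy())
        assert frac == 1.0
        assert (table["overlap_fraction"] == 1.0).all()

    def test_disjoint_lists_do_not_intersect(self):
        a = mor_df([("1", 100, 200, "gain")])
        b = mor_df([("1", 300, 400, "gain"), ("1", 100, 200, "loss")])
        table, frac = intersect_group_regions(a, b)
        assert table.empty and frac == 0.0

    def test_intersection_lengths_match_per_base_oracle(self):
        rng = np.random.default_rng(5)
        a_rows = [("1", int(s), int(s + w), "gain")
                  for s, w in zip(rng.integers(1, 500, 6), rng.integers(10, 200, 6))]
        b_rows = [("1", int(s), int(s + w), "gain")
                  for s, w in zip(rng.integers(1, 500, 6), rng.integers(10, 200, 6))]
        table, _ = intersect_group_regions(mor_df(a_rows), mor_df(b_rows))
        for _, row in table.iterrows():
            bases = sum(
                1
                for base in range(row["a_start"], row["a_end"] + 1)
                if row["b_start"] <= base <= row["b_end"]
            )
            assert bases == row["intersection_len"]


class TestAnnotate:
    def genes(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [100, 500, 100],
                "end": [200, 600, 300],
                "name": ["GENE_A", "GENE_B", "GENE_C"],
            }
        )

    def test_containment_and_gap_cases(self):
        regions = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [50, 250], "end": [250, 400]}
        )
        out = annotate_genes(regions, self.genes())
        assert out["genes"].tolist() == ["GENE_A", ""]
        assert out["n_genes"].tolist() == [1, 0]

    def test_single_base_overlap_counts(self):
        regions = pd.DataFrame({"chrom": ["1"], "start": [200], "end": [210]})
        assert annotate_genes(regions, self.genes())["genes"].tolist() == ["GENE_A"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(9)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], 30),
                "start": rng.integers(1, 900, 30),
                "name": [f"g{i}" for i in range(30)],
            }
        )
        genes["end"] = genes["start"] + rng.integers(5, 120, 30)
        regions = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 15), "start": rng.integers(1, 900, 15)}
        )
        regions["end"] = regions["start"] + rng.integers(5, 200, 15)
        out = annotate_genes(regions, genes)
        for i, region in regions.iterrows():
            expected = sorted(
                g["name"]
                for _, g in genes.iterrows()
                if g["chrom"] == region["chrom"]
                and g["start"] <= region["end"]
                and g["end"] >= region["start"]
            )
            got = sorted(x for x in out.loc[i, "genes"].split(",") if x)
            assert got == expected
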