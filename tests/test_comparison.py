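"""Overlap rule and concordance decomposition against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from cnvscatter.comparison import (
    ConcordanceRecord,
    classify_concordance,
    matches_region,
    venn_summary,
)
from cnvscatter.datatypes import PennCNVCall, RegionDefinition


def region(ts, te, chrom="1"):
    """Region with flanks immediately adjacent to a [ts, te] target."""
    return RegionDefinition("R", chrom, ts, te, ts - 10, ts - 1, te + 1, te + 10)


def call(s, e, cn=1, sample="s1", chrom="1"):
    return PennCNVCall(sample, chrom, s, e, cn, max(1, (e - s) // 10))


def brute_force_match(cs, ce, ts, te):
    """Literal evaluation of the two printed conditions (1-based inclusive)."""
    overlap = max(0, min(ce, te) - max(cs, ts) + 1)
    target_len = te - ts + 1
    call_len = ce - cs + 1
    return overlap >= 0.5 * target_len and call_len <= 2 * target_len


class TestMatchesRegion:
    def test_identical_interval(self):
        assert matches_region(call(1000, 1999), region(1000, 1999))

    def test_half_overlap_boundary_inclusive(self):
        # call covers exactly half the 1000-bp target: overlap = 500 = 50%
        assert matches_region(call(500, 1499), region(1000, 1999))

    def test_oversized_call_rejected(self):
        # 2.5x the target length, centered on the target
        r = region(1000, 1999)
        assert not matches_region(call(250, 2749), r)

    def test_different_chromosome(self):
        assert not matches_region(call(1000, 1999, chrom="2"), region(1000, 1999))

    def test_exhaustive_grid_matches_brute_force(self):
        """All integer call intervals on a 200-bp toy axis against the literal
        two-condition oracle (~2x10^4 cases)."""
        r = region(80, 119)  # 40-bp target
        for cs in range(1, 201):
            for ce in range(cs, 201):
                got = matches_region(call(cs, ce), r)
                assert got == brute_force_match(cs, ce, 80, 119), (cs, ce)

    def test_monotone_in_overlap_for_fixed_length(self):
        """Sliding a fixed-length call toward the target never turns a match
        into a non-match while overlap increases."""
        r = region(100, 199)
        length = 100
        overlaps, matches = [], []
        for cs in range(1, 200):
            ce = cs + length - 1
            overlaps.append(max(0, min(ce, 199) - max(cs, 100) + 1))
            matches.append(matches_region(call(cs, ce), r))
        # matched starts form one contiguous block around maximal overlap
        idx = [i for i, m in enumerate(matches) if m]
        assert idx == list(range(idx[0], idx[-1] + 1))
        assert all(overlaps[i] >= 0.5 * 100 for i in idx)


def genotype_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "region_id", "cn",
                                       "baf_confirmed"])


class TestClassifyConcordance:
    @pytest.fixture
    def regions(self):
        return [RegionDefinition("R1", "1", 10_000, 19_999, 1, 9_999,
                                 20_000, 30_000)]

    def test_engineered_class_counts(self, regions):
        """10 concordant + 3 scatterplot-only + 2 penncnv-only events."""
        rows, calls = [], []
        for i in range(10):  # concordant deletions
            rows.append((f"c{i}", "R1", 1, "confirmed"))
            calls.append(call(10_000, 19_999, cn=1, sample=f"c{i}"))
        for i in range(3):  # scatterplot-only
            rows.append((f"s{i}", "R1", 1, "confirmed"))
        for i in range(2):  # penncnv-only (scatterplot diploid)
            rows.append((f"p{i}", "R1", 2, "confirmed"))
            calls.append(call(10_000, 19_999, cn=1, sample=f"p{i}"))
        records = classify_concordance(genotype_frame(rows), calls, regions)
        counts = pd.Series([r.klass for r in records]).value_counts()
        assert counts["concordant"] == 10
        assert counts["scatterplot_only"] == 3
        assert counts["penncnv_only"] == 2
        assert len(records) == 15

    def test_no_penncnv_file(self, regions):
        rows = [("a", "R1", 1, "confirmed"), ("b", "R1", 3, "confirmed"),
                ("c", "R1", 2, "confirmed")]
        records = classify_concordance(genotype_frame(rows), [], regions)
        assert all(r.klass == "scatterplot_only" for r in records)
        assert len(records) == 2

    def test_concordant_deletion_direction(self, regions):
        rows = [("a", "R1", 1, "confirmed")]
        records = classify_concordance(
            genotype_frame(rows), [call(10_000, 19_999, cn=1, sample="a")], regions)
        (rec,) = records
        assert rec.klass == "concordant" and rec.direction == "deletion"

    def test_direction_conflict_yields_two_discordant(self, regions):
        rows = [("a", "R1", 1, "confirmed")]
        records = classify_concordance(
            genotype_frame(rows), [call(10_000, 19_999, cn=3, sample="a")], regions)
        assert sorted(r.klass for r in records) == ["penncnv_only", "scatterplot_only"]

    def test_contradicted_call_not_scatterplot_positive(self, regions):
        rows = [("a", "R1", 3, "contradicted")]
        records = classify_concordance(genotype_frame(rows), [], regions)
        assert records == []
        # opting out of BAF screening restores the literal rule
        records = classify_concordance(genotype_frame(rows), [], regions,
                                       require_baf_confirmation=False)
        assert len(records) == 1

    def test_largest_overlap_call_kept(self, regions):
        rows = [("a", "R1", 1, "confirmed")]
        small = call(10_000, 15_000, cn=1, sample="a")
        big = call(10_000, 19_999, cn=1, sample="a")
        records = classify_concordance(genotype_frame(rows), [small, big], regions)
        (rec,) = records
        assert rec.penncnv_cn == 1 and rec.klass == "concordant"

    def test_calls_for_samples_missing_from_genotypes(self, regions):
        records = classify_concordance(
            genotype_frame([]), [call(10_000, 19_999, cn=1, sample="ghost")], regions)
        (rec,) = records
        assert rec.klass == "penncnv_only" and rec.sample_id == "ghost"


class TestVennSummary:
    def test_published_arithmetic_self_consistency(self):
        """1019 concordant + 108 discordant findings partition a total of
        1127 (the Venn bookkeeping must add up)."""
        records = (
            [ConcordanceRecord(f"c{i}", "R1", 1, 1, "concordant", "deletion")
             for i in range(1019)]
            + [ConcordanceRecord(f"s{i}", "R1", 1, None, "scatterplot_only",
                                 "deletion") for i in range(21)]
            + [ConcordanceRecord(f"p{i}", "R1", None, 1, "penncnv_only",
                                 "deletion") for i in range(87)]
        )
        table = venn_summary(records)
        overall = table[table["region_id"] == "ALL"].iloc[0]
        assert overall["concordant"] == 1019
        assert overall["scatterplot_only"] + overall["penncnv_only"] == 108
        assert overall["total"] == 1127

    def test_empty_records(self):
        table = venn_summary([])
        assert (table["total"] == 0).all()

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        classes = ["concordant", "scatterplot_only", "penncnv_only"]
        records = [ConcordanceRecord(f"s{i}", f"R{rng.integers(3)}",
                                     1, 1, classes[rng.integers(3)],
                                     ["deletion", "duplication"][rng.integers(2)])
                   for i in range(200)]
        table = venn_summary(records)
        overall = table[table["region_id"] == "ALL"].iloc[0]
        assert overall["total"] == 200
        per_region = table[table["region_id"] != "ALL"]
        assert per_region["total"].sum() == 200
        for _, row in table.iterrows():
            assert row["total"] == (row["concordant"] + row["scatterplot_only"]
                                    + row["penncnv_only"])
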