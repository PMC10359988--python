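"""Concordance analysis between scatterplot genotypes and PennCNV calls.

A PennCNV call is matched to a predefined CNV region when it overlaps the
target interval by at least 50% of the target's length and is itself no
larger than twice the target. Positive findings of the two methods at each
(sample, region) are then decomposed into three classes: concordant (both
methods, same direction), scatterplot-only, and PennCNV-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PennCNVCall, RegionDefinition

__all__ = ["ConcordanceRecord", "matches_region", "classify_concordance",
           "venn_summary"]


@dataclass
class ConcordanceRecord:
    """One positive CNV finding at a (sample, region), classed by agreement."""

    sample_id: str
    region_id: str
    scatterplot_cn: int | None  # None when the scatterplot method saw CN=2/no-call
    penncnv_cn: int | None  # None when no PennCNV call matched the region
    klass: str  # 'concordant' | 'scatterplot_only' | 'penncnv_only'
    direction: str  # 'deletion' | 'duplication'


def _overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length of two 1-based inclusive intervals, in bp."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def matches_region(call: PennCNVCall, region: RegionDefinition) -> bool:
    """True iff the call overlaps the target by >= 50% of the target length
    and the call itself is no larger than twice the target length."""
    if call.chromosome != region.chromosome:
        return False
    overlap = _overlap_bp(call.start, call.end,
                          region.target_start, region.target_end)
    return (2 * overlap >= region.target_length
            and call.length <= 2 * region.target_length)


def _direction(cn: int) -> str:
    return "deletion" if cn < 2 else "duplication"


def classify_concordance(genotypes: pd.DataFrame, calls: list[PennCNVCall],
                         regions: list[RegionDefinition],
                         require_baf_confirmation: bool = True
                         ) -> list[ConcordanceRecord]:
    """Decompose the union of positive findings into concordance classes.

    Parameters
    ----------
    genotypes : DataFrame with sample_id, region_id, cn columns
        (the ``genotype_cohort`` output layout).
    calls : parsed rawcnv records.
    regions : the region definitions the genotypes refer to.
    require_baf_confirmation : bool
        When True (default) and the genotype table carries a
        ``baf_confirmed`` column, calls contradicted by the BAF pattern do
        not count as scatterplot-positive — the programmatic stand-in for
        per-call review ('uninformative' calls remain positive).

    A (sample, region) is scatterplot-positive when its called cn differs
    from 2; PennCNV-positive when at least one call matches the region (the
    call with the largest overlap is kept). Direction conflicts produce two
    discordant records, one per method.
    """
    region_by_id = {r.region_id: r for r in regions}
    calls_by_sample: dict[str, list[PennCNVCall]] = {}
    for c in calls:
        calls_by_sample.setdefault(c.sample_id, []).append(c)

    records: list[ConcordanceRecord] = []
    seen: set[tuple[str, str]] = set()

    for row in genotypes.itertuples(index=False):
        region = region_by_id[row.region_id]
        seen.add((row.sample_id, row.region_id))
        scn = None if pd.isna(row.cn) else int(row.cn)
        scatter_pos = scn is not None and scn != 2
        if (scatter_pos and require_baf_confirmation
                and getattr(row, "baf_confirmed", None) == "contradicted"):
            scatter_pos = False

        best, best_ov = None, -1
        for c in calls_by_sample.get(row.sample_id, ()):
            if matches_region(c, region):
                ov = _overlap_bp(c.start, c.end, region.target_start, region.target_end)
                if ov > best_ov:
                    best, best_ov = c, ov
        penn_pos = best is not None

        if scatter_pos and penn_pos:
            if _direction(scn) == _direction(best.cn):
                records.append(ConcordanceRecord(
                    row.sample_id, row.region_id, scn, best.cn,
                    "concordant", _direction(scn)))
            else:
                # opposite directions: not consistently identified
                records.append(ConcordanceRecord(
                    row.sample_id, row.region_id, scn, None,
                    "scatterplot_only", _direction(scn)))
                records.append(ConcordanceRecord(
                    row.sample_id, row.region_id, None, best.cn,
                    "penncnv_only", _direction(best.cn)))
        elif scatter_pos:
            records.append(ConcordanceRecord(
                row.sample_id, row.region_id, scn, None,
                "scatterplot_only", _direction(scn)))
        elif penn_pos:
            records.append(ConcordanceRecord(
                row.sample_id, row.region_id, None, best.cn,
                "penncnv_only", _direction(best.cn)))

    # PennCNV calls at regions absent from the genotype table still count
    for c in calls:
        for region in regions:
            if (c.sample_id, region.region_id) in seen:
                continue
            if matches_region(c, region):
                records.append(ConcordanceRecord(
                    c.sample_id, region.region_id, None, c.cn,
                    "penncnv_only", _direction(c.cn)))
    return records


def venn_summary(records: list[ConcordanceRecord]) -> pd.DataFrame:
    """Counts per region and overall, per class and per direction.

    The total of each row equals concordant + scatterplot_only +
    penncnv_only (every finding sits in exactly one class)."""
    classes = ("concordant", "scatterplot_only", "penncnv_only")
    directions = ("deletion", "duplication")

    def count_block(recs) -> dict:
        out: dict = {k: 0 for k in classes}
        for d in directions:
            for k in classes:
                out[f"{k}_{d}"] = 0
        for r in recs:
            out[r.klass] += 1
            out[f"{r.klass}_{r.direction}"] += 1
        out["total"] = sum(out[k] for k in classes)
        return out

    rows = []
    for region_id in sorted({r.region_id for r in records}):
        row = {"region_id": region_id}
        row.update(count_block([r for r in records if r.region_id == region_id]))
        rows.append(row)
    overall = {"region_id": "ALL"}
    overall.update(count_block(records))
    rows.append(overall)
    return pd.DataFrame(rows)
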