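"""Per-(sample, region) summary statistics.

For each sample and CNV region three quantities drive the downstream calling:

* the median LRR of probes inside the target and each flanking interval,
* the delta statistic per flank (target median minus flank median), and
* counts of homozygous, di-allelic heterozygous and tri-allelic heterozygous
  SNPs within the target, judged from BAF with the fixed windows
  hom: BAF < 0.01 or BAF > 0.99; di-het: 0.47 < BAF < 0.53;
  tri-het: 0.3 < BAF < 0.36 or 0.63 < BAF < 0.69 (all strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ProbeMap, RegionDefinition, RegionSummary, SampleSignal

__all__ = [
    "median_lrr",
    "classify_baf",
    "count_baf_categories",
    "summarize_region",
    "summarize_cohort",
    "BAF_CATEGORIES",
]

BAF_CATEGORIES = ("homozygous", "di_het", "tri_het", "other", "missing")


def median_lrr(signal: SampleSignal, interval: tuple[int, int],
               chromosome: str, probe_map: ProbeMap) -> float:
    """Median of non-missing LRR values of probes inside a 1-based inclusive
    interval; nan when no usable probe exists (flagged, not raised).

    For an even count the median is the arithmetic mean of the two central
    order statistics."""
    idx = probe_map.in_interval(chromosome, *interval)
    values = signal.lrr[idx]
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    return float(np.median(values))


def classify_baf(baf: float) -> str:
    """Assign one BAF value to its genotype category.

    Boundary values (0.01, 0.99, 0.47, 0.53, 0.3, 0.36, 0.63, 0.69) fall in
    'other' because all windows are open intervals."""
    if baf is None or (isinstance(baf, float) and np.isnan(baf)):
        return "missing"
    baf = float(baf)
    if baf < 0 or baf > 1:
        raise ValueError(f"BAF {baf} outside [0, 1]")
    if baf < 0.01 or baf > 0.99:
        return "homozygous"
    if 0.47 < baf < 0.53:
        return "di_het"
    if 0.3 < baf < 0.36 or 0.63 < baf < 0.69:
        return "tri_het"
    return "other"


def count_baf_categories(baf: np.ndarray) -> dict[str, int]:
    """Vectorized category counts over a BAF vector (nan = missing)."""
    baf = np.asarray(baf, dtype=float)
    finite = baf[np.isfinite(baf)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("BAF values outside [0, 1]")
    hom = (finite < 0.01) | (finite > 0.99)
    di = (finite > 0.47) & (finite < 0.53)
    tri = ((finite > 0.3) & (finite < 0.36)) | ((finite > 0.63) & (finite < 0.69))
    n_hom, n_di, n_tri = int(hom.sum()), int(di.sum()), int(tri.sum())
    return {
        "homozygous": n_hom,
        "di_het": n_di,
        "tri_het": n_tri,
        "other": int(finite.size - n_hom - n_di - n_tri),
        "missing": int(baf.size - finite.size),
    }


def summarize_region(signal: SampleSignal, region: RegionDefinition,
                     probe_map: ProbeMap) -> RegionSummary:
    """All medians, deltas and BAF counts for one sample at one region."""
    m_t = median_lrr(signal, region.interval("target"), region.chromosome, probe_map)
    m_5 = median_lrr(signal, region.interval("flank5"), region.chromosome, probe_map)
    m_3 = median_lrr(signal, region.interval("flank3"), region.chromosome, probe_map)
    target_idx = probe_map.in_interval(region.chromosome, *region.interval("target"))
    counts = count_baf_categories(signal.baf[target_idx])
    n_used = int(np.isfinite(signal.lrr[target_idx]).sum())
    return RegionSummary(
        sample_id=signal.sample_id,
        region_id=region.region_id,
        median_target=m_t,
        median_flank5=m_5,
        median_flank3=m_3,
        delta5=m_t - m_5,
        delta3=m_t - m_3,
        n_hom=counts["homozygous"],
        n_di_het=counts["di_het"],
        n_tri_het=counts["tri_het"],
        n_probes_used=n_used,
    )


def summarize_cohort(signals: list[SampleSignal],
                     regions: list[RegionDefinition],
                     probe_map: ProbeMap) -> pd.DataFrame:
    """One row per (sample, region); column layout of the summaries table."""
    rows = [vars(summarize_region(sig, reg, probe_map))
            for sig in signals for reg in regions]
    return pd.DataFrame(rows)
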