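"""Pairwise wave subtraction for visual validation of individual CNV calls.

SNP arrays show sample-specific, megabase-scale baseline undulations of the
LRR ("genomic waves") that can mimic deletions or duplications. A candidate
CNV in one sample can be exposed, or refuted, by subtracting the LRR profile
of a second sample that shares a similar wave but is diploid at the target:
the wave cancels while a genuine copy-number shift survives.

Wave similarity is quantified here as the Pearson correlation of per-bin
median LRR profiles (default bin size 1 Mb) computed with the candidate
target interval masked out, so a reference sharing the same CNV is not
preferentially selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ProbeMap, SampleSignal, normalize_chrom

__all__ = ["WaveProfile", "wave_profile", "select_reference", "subtract_reference",
           "DEFAULT_BIN_SIZE"]

DEFAULT_BIN_SIZE = 1_000_000  # bp; genomic waves are megabase-scale


@dataclass
class WaveProfile:
    """Binned median-LRR profile of one sample over one chromosome."""

    sample_id: str
    chromosome: str
    binned_lrr: np.ndarray  # per-bin median, nan for empty bins
    bin_size: int
    bin_start: int  # position (1-based) where bin 0 begins


def wave_profile(signal: SampleSignal, chromosome: str, probe_map: ProbeMap,
                 bin_size: int = DEFAULT_BIN_SIZE,
                 exclude: tuple[int, int] | None = None) -> WaveProfile:
    """Per-bin median LRR over a chromosome, the candidate interval masked.

    ``exclude`` is a 1-based inclusive (start, end) interval — typically the
    candidate CNV target — whose probes are ignored so that the profile
    reflects only the background wave."""
    chromosome = normalize_chrom(chromosome)
    idx = np.flatnonzero(probe_map.chromosome == chromosome)
    if idx.size == 0:
        raise ValueError(f"chromosome {chromosome} not present in the probe map")
    pos = probe_map.position[idx]
    lrr = signal.lrr[idx]
    if exclude is not None:
        s, e = exclude
        keep = (pos < s) | (pos > e)
        pos, lrr = pos[keep], lrr[keep]
    start = 1
    n_bins = int((pos.max() - start) // bin_size) + 1 if pos.size else 0
    binned = np.full(n_bins, np.nan)
    which = (pos - start) // bin_size
    for b in range(n_bins):
        v = lrr[which == b]
        v = v[np.isfinite(v)]
        if v.size:
            binned[b] = np.median(v)
    return WaveProfile(sample_id=signal.sample_id, chromosome=chromosome,
                       binned_lrr=binned, bin_size=bin_size, bin_start=start)


def _pairwise_complete(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def select_reference(query: WaveProfile, candidates: list[WaveProfile],
                     min_shared_bins: int = 10) -> str:
    """Pick the candidate whose wave profile best matches the query's.

    Maximizes the Pearson correlation of pairwise-complete bins; ties break
    by smaller mean absolute profile difference, then lexicographic sample
    id. Candidates sharing fewer than ``min_shared_bins`` usable bins with
    the query are skipped."""
    if not candidates:
        raise ValueError("no candidate reference samples supplied")
    scored = []
    for cand in candidates:
        if cand.sample_id == query.sample_id:
            continue
        a, b = _pairwise_complete(query.binned_lrr, cand.binned_lrr)
        if a.size < min_shared_bins:
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            corr = 0.0  # flat profile: correlation undefined, treated as null
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
        mad = float(np.mean(np.abs(a - b)))
        scored.append((-corr, mad, cand.sample_id))
    if not scored:
        raise ValueError(
            f"no candidate shares >= {min_shared_bins} non-missing bins with "
            f"{query.sample_id}")
    scored.sort()
    return scored[0][2]


def subtract_reference(query: SampleSignal, reference: SampleSignal,
                       chromosome: str, probe_map: ProbeMap) -> np.ndarray:
    """Per-probe LRR difference query - reference on one chromosome.

    Returns one value per chromosome probe in map order; missing in either
    sample propagates to nan. Antisymmetric:
    ``subtract(A, B) == -subtract(B, A)``."""
    chromosome = normalize_chrom(chromosome)
    idx = np.flatnonzero(probe_map.chromosome == chromosome)
    return query.lrr[idx] - reference.lrr[idx]
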