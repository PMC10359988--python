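"""Shared data model for region-targeted CNV genotyping from SNP-array signals.

All genomic coordinates are 1-based and inclusive on both ends (hg19-style
breakpoint convention); interval length is ``end - start + 1`` bp.
Chromosome names are normalized to the unprefixed form ("2", not "chr2").
Missing LRR/BAF values are represented as ``numpy.nan``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeMap",
    "SampleSignal",
    "RegionDefinition",
    "RegionSummary",
    "PennCNVCall",
    "CNVGenotype",
    "SampleQC",
    "normalize_chrom",
    "RegionValidationError",
]

AUTOSOMES = {str(i) for i in range(1, 23)}

#: minimum probe count per interval recommended for stable medians
MIN_PROBES_PER_INTERVAL = 30


class RegionValidationError(ValueError):
    """A region definition violates the interval-layout invariants."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix: both '2' and 'chr2' map to '2'."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class ProbeMap:
    """Probe coordinate frame shared by all samples of a cohort.

    Probes are stored sorted by (chromosome, position); positions are
    strictly increasing within each chromosome and probe ids are unique.
    """

    probe_id: np.ndarray  # dtype object/str
    chromosome: np.ndarray  # dtype object/str, normalized
    position: np.ndarray  # dtype int64, 1-based

    def __post_init__(self) -> None:
        pid = np.asarray(self.probe_id, dtype=object)
        chrom = np.asarray([normalize_chrom(c) for c in self.chromosome], dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ValueError("probe_id, chromosome and position must have equal length")
        order = np.lexsort((pos, chrom))
        pid, chrom, pos = pid[order], chrom[order], pos[order]
        if len(set(pid)) != len(pid):
            raise ValueError("probe ids are not unique")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"probe positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "probe_id", pid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "_index", {p: i for i, p in enumerate(pid)})

    def __len__(self) -> int:
        return len(self.probe_id)

    def index_of(self, probe_ids) -> np.ndarray:
        """Row indices of the given probe ids; -1 where unknown."""
        idx = self._index
        return np.array([idx.get(p, -1) for p in probe_ids], dtype=np.int64)

    def in_interval(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Indices of probes with ``start <= position <= end`` on a chromosome."""
        chromosome = normalize_chrom(chromosome)
        mask = self.chromosome == chromosome
        mask &= (self.position >= int(start)) & (self.position <= int(end))
        return np.flatnonzero(mask)

    def chromosomes(self) -> list[str]:
        return sorted(set(self.chromosome))


@dataclass
class SampleSignal:
    """One sample's per-probe Log R Ratio and B-allele frequency vectors.

    Both vectors are aligned to a :class:`ProbeMap`; nan marks missing.
    """

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        if self.lrr.shape != self.baf.shape:
            raise ValueError("lrr and baf must have the same length")
        finite = self.baf[np.isfinite(self.baf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("BAF values must lie in [0, 1]")


@dataclass(frozen=True)
class RegionDefinition:
    """A named CNV target interval with its 5' and 3' flanking intervals."""

    region_id: str
    chromosome: str
    target_start: int
    target_end: int
    flank5_start: int
    flank5_end: int
    flank3_start: int
    flank3_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        f5s, f5e = self.flank5_start, self.flank5_end
        ts, te = self.target_start, self.target_end
        f3s, f3e = self.flank3_start, self.flank3_end
        for name, (s, e) in {
            "flank5": (f5s, f5e), "target": (ts, te), "flank3": (f3s, f3e),
        }.items():
            if s > e:
                raise RegionValidationError(
                    f"{self.region_id}: {name} start {s} > end {e}")
        if not (f5e < ts and te < f3s):
            raise RegionValidationError(
                f"{self.region_id}: intervals must be ordered and non-overlapping "
                f"(flank5 < target < flank3)")

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start + 1

    def interval(self, which: str) -> tuple[int, int]:
        """(start, end) of 'target', 'flank5' or 'flank3'."""
        return {
            "target": (self.target_start, self.target_end),
            "flank5": (self.flank5_start, self.flank5_end),
            "flank3": (self.flank3_start, self.flank3_end),
        }[which]

    def check_probe_support(self, probe_map: ProbeMap) -> None:
        """Warn when any interval covers fewer than 30 probes."""
        for which in ("flank5", "target", "flank3"):
            s, e = self.interval(which)
            n = len(probe_map.in_interval(self.chromosome, s, e))
            if n < MIN_PROBES_PER_INTERVAL:
                warnings.warn(
                    f"region {self.region_id}: {which} contains only {n} probes "
                    f"(< {MIN_PROBES_PER_INTERVAL})",
                    UserWarning,
                    stacklevel=2,
                )


@dataclass
class RegionSummary:
    """Per-(sample, region) medians, delta statistics and BAF category counts.

    ``delta5``/``delta3`` are the target-median minus flank-median LRR
    differences; the three counts cover target-interval probes only.
    """

    sample_id: str
    region_id: str
    median_target: float
    median_flank5: float
    median_flank3: float
    delta5: float
    delta3: float
    n_hom: int
    n_di_het: int
    n_tri_het: int
    n_probes_used: int


@dataclass(frozen=True)
class PennCNVCall:
    """One parsed rawcnv record."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    cn: int
    numsnp: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if self.start > self.end:
            raise ValueError(f"call start {self.start} > end {self.end}")
        if self.cn == 2 or self.cn < 0:
            raise ValueError(f"invalid PennCNV copy number {self.cn}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CNVGenotype:
    """Copy-number genotype of one sample at one region.

    ``cn`` is None for a no-call. ``baf_confirmed`` is one of
    'confirmed', 'contradicted', 'uninformative' or 'not_assessed'.
    """

    sample_id: str
    region_id: str
    cn: int | None
    delta_used: float
    baf_confirmed: str = "not_assessed"
    flank_agreement: bool | None = None
    membership_prob: float = float("nan")


@dataclass
class SampleQC:
    """Per-sample quality metrics used to rank and exclude samples."""

    sample_id: str
    n_penncnv_calls: int
    lrr_variance: float
    call_rate: float
    rank_percentile: dict = field(default_factory=dict)
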