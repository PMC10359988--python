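"""Synthetic SNP-array cohorts with known copy-number truth.

The generator emulates the statistical structure the scatterplot method
assumes: per-region diploid copy number composed of two independently drawn
alleles (deletion allele = 0 copies, normal = 1, duplication allele = 2, so
CN ranges 0-4 under Hardy-Weinberg), per-CN LRR shifts at the target probes,
BAF drawn from the CN-appropriate support, per-sample sinusoidal genomic
waves, Gaussian LRR noise, call-rate degradation, a low-quality sample
stratum with inflated noise/waves/missingness, and a matched PennCNV-style
call file with configurable false-positive and false-negative rates.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ProbeMap, RegionDefinition, SampleSignal, PennCNVCall
from .genotyping import CANONICAL_SHIFTS

__all__ = ["SimulationConfig", "TruthTable", "default_regions",
           "simulate_cohort", "simulate_penncnv_calls", "write_cohort"]


def default_regions(chrom_span: int = 30_000_000) -> list[RegionDefinition]:
    """Two CNV regions, each mid-way on its own synthetic chromosome, with
    0.5-Mb target and flank intervals (100 probes each at 5-kb spacing)."""
    regions = []
    for i, chrom in enumerate(("1", "2"), start=1):
        mid = chrom_span // 2
        regions.append(RegionDefinition(
            region_id=f"R{i}", chromosome=chrom,
            flank5_start=mid - 1_100_000, flank5_end=mid - 600_001,
            target_start=mid - 250_000, target_end=mid + 249_999,
            flank3_start=mid + 600_000, flank3_end=mid + 1_099_999,
        ))
    return regions


@dataclass
class SimulationConfig:
    """Study conditions of a simulated cohort.

    Defaults: 500 samples, deletion-allele frequency 0.08 and
    duplication-allele frequency 0.04 per region, per-CN delta shifts at the
    canonical values (CN1 -0.5, CN3 +0.25 as observed in real clusters),
    per-probe LRR noise SD 0.08, BAF jitter SD 0.02, modest genomic waves,
    and a 10% low-quality stratum with 3x noise/waves and elevated
    missingness. PennCNV emulation: 5% false-negative rate; false positives
    at a low base rate, strongly enriched in the low-quality stratum.
    """

    n_samples: int = 500
    probe_spacing: int = 5_000  # bp between consecutive probes
    chrom_span: int = 30_000_000  # bp per synthetic chromosome
    regions: list[RegionDefinition] | None = None  # None: default_regions(chrom_span)
    deletion_freq: float = 0.08  # per-region deletion allele frequency
    duplication_freq: float = 0.04
    cn_shifts: dict = field(default_factory=lambda: dict(CANONICAL_SHIFTS))
    lrr_noise_sd: float = 0.08
    baf_noise_sd: float = 0.02
    wave_amplitude_sd: float = 0.02  # half-normal scale of per-sample wave amplitude
    wave_wavelength_range: tuple = (1_000_000.0, 10_000_000.0)
    low_quality_fraction: float = 0.10
    low_quality_noise_factor: float = 3.0
    low_quality_wave_factor: float = 3.0
    baseline_missing_rate: float = 0.005
    low_quality_missing_rate: float = 0.05
    n_shared_wave_pairs: int = 0  # leading sample pairs share one wave
    shared_wave_amplitude: float = 0.3
    penncnv_fp_rate: float = 0.002  # per (sample, region) with true CN=2
    penncnv_fp_rate_low_quality: float = 0.10
    penncnv_fn_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions is None:
            self.regions = default_regions(self.chrom_span)
        for name in ("deletion_freq", "duplication_freq", "low_quality_fraction",
                     "baseline_missing_rate", "low_quality_missing_rate",
                     "penncnv_fp_rate", "penncnv_fp_rate_low_quality",
                     "penncnv_fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("lrr_noise_sd", "baf_noise_sd", "wave_amplitude_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort.

    ``cn``: one row per (sample, region) with the true copy number.
    ``low_quality``: sample ids of the degraded stratum.
    ``wave_pairs``: sample-id pairs sharing an identical genomic wave.
    ``calls``: emitted PennCNV-style calls with an ``is_true`` flag
    (filled by :func:`simulate_penncnv_calls`).
    ``suppressed``: true carriers whose call was withheld (false negatives).
    """

    cn: pd.DataFrame
    low_quality: set
    wave_pairs: list
    calls: pd.DataFrame | None = None
    suppressed: pd.DataFrame | None = None

    def true_cn(self, sample_id: str, region_id: str) -> int:
        sel = self.cn[(self.cn["sample_id"] == sample_id)
                      & (self.cn["region_id"] == region_id)]
        return int(sel["true_cn"].iloc[0])


_BAF_SUPPORT = {
    1: (np.array([0.0, 1.0]), np.array([0.5, 0.5])),
    2: (np.array([0.0, 0.5, 1.0]), np.array([0.25, 0.5, 0.25])),
    3: (np.array([0.0, 1 / 3, 2 / 3, 1.0]), np.array([1, 3, 3, 1]) / 8),
    4: (np.array([0.0, 0.25, 0.5, 0.75, 1.0]), np.array([1, 4, 6, 4, 1]) / 16),
}


def _build_probe_map(config: SimulationConfig) -> ProbeMap:
    chroms = sorted({r.chromosome for r in config.regions})
    ids, cs, ps = [], [], []
    for chrom in chroms:
        positions = np.arange(1, config.chrom_span + 1, config.probe_spacing,
                              dtype=np.int64)
        ids.extend(f"rs{chrom}_{i}" for i in range(len(positions)))
        cs.extend([chrom] * len(positions))
        ps.append(positions)
    return ProbeMap(np.array(ids, dtype=object), np.array(cs, dtype=object),
                    np.concatenate(ps))


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[ProbeMap, list[SampleSignal], TruthTable]:
    """Generate a cohort of per-sample signals plus its truth table."""
    for r in config.regions:
        if r.flank5_start < 1 or r.flank3_end > config.chrom_span:
            raise ValueError(
                f"region {r.region_id} lies outside the simulated chromosome span")
    rng = np.random.default_rng(config.seed)
    probe_map = _build_probe_map(config)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # quality strata: the worst floor(f*n) samples, chosen at random
    n_low = math.floor(config.low_quality_fraction * n)
    low_idx = set(rng.choice(n, size=n_low, replace=False).tolist()) if n_low else set()

    # per-sample wave parameters; leading pairs may share one wave
    lo, hi = config.wave_wavelength_range
    amp = np.abs(rng.normal(0.0, config.wave_amplitude_sd, size=n))
    wavelength = rng.uniform(lo, hi, size=n)
    phase = rng.uniform(0.0, 2 * np.pi, size=n)
    for i in range(n):
        if i in low_idx:
            amp[i] *= config.low_quality_wave_factor
    wave_pairs = []
    for p in range(config.n_shared_wave_pairs):
        a, b = 2 * p, 2 * p + 1
        if b >= n:
            break
        amp[a] = amp[b] = config.shared_wave_amplitude
        wavelength[b] = wavelength[a]
        phase[b] = phase[a]
        wave_pairs.append((sample_ids[a], sample_ids[b]))

    # true CN per (sample, region): two independent alleles in {0,1,2}
    allele_p = np.array([config.deletion_freq,
                         1 - config.deletion_freq - config.duplication_freq,
                         config.duplication_freq])
    if allele_p[1] < 0:
        raise ValueError("deletion_freq + duplication_freq exceeds 1")
    true_cn = {}
    cn_rows = []
    for r in config.regions:
        alleles = rng.choice(3, size=(n, 2), p=allele_p)
        cns = alleles.sum(axis=1)
        true_cn[r.region_id] = cns
        cn_rows.extend({"sample_id": sample_ids[i], "region_id": r.region_id,
                        "true_cn": int(cns[i])} for i in range(n))

    region_target_idx = {
        r.region_id: probe_map.in_interval(r.chromosome, r.target_start, r.target_end)
        for r in config.regions}
    n_probes = len(probe_map)
    pos = probe_map.position.astype(float)

    signals = []
    for i in range(n):
        low = i in low_idx
        noise_sd = config.lrr_noise_sd * (config.low_quality_noise_factor if low else 1.0)
        miss = config.low_quality_missing_rate if low else config.baseline_missing_rate

        lrr = amp[i] * np.sin(2 * np.pi * pos / wavelength[i] + phase[i])
        lrr += rng.normal(0.0, noise_sd, size=n_probes)

        # flank/background BAF: diploid support everywhere, then override targets
        vals, probs = _BAF_SUPPORT[2]
        baf = vals[rng.choice(len(vals), size=n_probes, p=probs)]
        for r in config.regions:
            cn = int(true_cn[r.region_id][i])
            tidx = region_target_idx[r.region_id]
            lrr[tidx] += config.cn_shifts[cn]
            if cn == 0:
                baf[tidx] = rng.uniform(0.0, 1.0, size=len(tidx))
            elif cn != 2:
                v, p = _BAF_SUPPORT[cn]
                baf[tidx] = v[rng.choice(len(v), size=len(tidx), p=p)]
        if config.baf_noise_sd > 0:
            baf = np.clip(baf + rng.normal(0.0, config.baf_noise_sd, size=n_probes),
                          0.0, 1.0)
        baf[rng.random(n_probes) < miss] = np.nan
        lrr[rng.random(n_probes) < miss / 4] = np.nan
        signals.append(SampleSignal(sample_id=sample_ids[i], lrr=lrr, baf=baf))

    truth = TruthTable(cn=pd.DataFrame(cn_rows),
                       low_quality={sample_ids[i] for i in low_idx},
                       wave_pairs=wave_pairs)
    return probe_map, signals, truth


def simulate_penncnv_calls(truth: TruthTable, config: SimulationConfig
                           ) -> tuple[list[PennCNVCall], TruthTable]:
    """Emit PennCNV-style calls matched to the simulated truth.

    True carriers produce a call with probability 1 - penncnv_fn_rate, with
    boundaries jittered within the region-matching tolerance (overlap stays
    >= 50% of the target, length <= 2x the target). False positives are
    injected at diploid (sample, region) pairs, at a higher rate in the
    low-quality stratum. Every emitted call and every suppressed carrier is
    recorded in the returned truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    region_by_id = {r.region_id: r for r in config.regions}

    calls: list[PennCNVCall] = []
    call_rows, suppressed_rows = [], []
    for row in truth.cn.itertuples(index=False):
        region = region_by_id[row.region_id]
        L = region.target_length
        low = row.sample_id in truth.low_quality
        if row.true_cn != 2:
            if rng.random() < config.penncnv_fn_rate:
                suppressed_rows.append({"sample_id": row.sample_id,
                                        "region_id": row.region_id,
                                        "true_cn": row.true_cn})
                continue
            cn, is_true = int(row.true_cn), True
        else:
            fp_rate = (config.penncnv_fp_rate_low_quality if low
                       else config.penncnv_fp_rate)
            if rng.random() >= fp_rate:
                continue
            cn, is_true = int(rng.choice([1, 3])), False
        start = region.target_start + int(rng.uniform(-0.15, 0.15) * L)
        end = region.target_end + int(rng.uniform(-0.15, 0.15) * L)
        numsnp = max(1, (end - start + 1) // config.probe_spacing)
        call = PennCNVCall(sample_id=row.sample_id, chromosome=region.chromosome,
                           start=start, end=end, cn=cn, numsnp=numsnp)
        calls.append(call)
        call_rows.append({"sample_id": row.sample_id, "region_id": row.region_id,
                          "chrom": region.chromosome, "start": start, "end": end,
                          "cn": cn, "is_true": is_true})

    truth.calls = pd.DataFrame(
        call_rows, columns=["sample_id", "region_id", "chrom", "start", "end",
                            "cn", "is_true"])
    truth.suppressed = pd.DataFrame(
        suppressed_rows, columns=["sample_id", "region_id", "true_cn"])
    return calls, truth


def write_cohort(outdir, probe_map: ProbeMap, signals: list[SampleSignal],
                 truth: TruthTable, regions: list[RegionDefinition],
                 calls: list[PennCNVCall] | None = None) -> None:
    """Write a simulated cohort in the formats the readers consume:
    probe map TSV, region table, one signal file per sample, a rawcnv file
    (when calls are given) and the truth tables."""
    from pathlib import Path

    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_probe_map(probe_map, outdir / "probes.tsv")
    io_formats.write_region_table(regions, outdir / "regions.tsv")
    sigdir = outdir / "signals"
    sigdir.mkdir(exist_ok=True)
    for s in signals:
        io_formats.write_signal_file(s, probe_map, sigdir / f"{s.sample_id}.txt")
    truth.cn.to_csv(outdir / "truth_cn.tsv", sep="\t", index=False)
    pd.DataFrame({"sample_id": sorted(truth.low_quality)}).to_csv(
        outdir / "truth_low_quality.tsv", sep="\t", index=False)
    if calls is not None:
        io_formats.write_rawcnv(calls, outdir / "penncnv.rawcnv")
        truth.calls.to_csv(outdir / "truth_calls.tsv", sep="\t", index=False)
        truth.suppressed.to_csv(outdir / "truth_suppressed.tsv", sep="\t", index=False)
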