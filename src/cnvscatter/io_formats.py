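"""Readers and writers for the external text formats.

Supported dialects:

* PennCNV split-signal files — tab-delimited, one row per probe, with
  ``SNP Name``/``Chr``/``Position`` columns plus per-sample
  ``<sample>.Log R Ratio`` and ``<sample>.B Allele Freq`` columns.
* Probe-map TSV: ``probe_id  chrom  position``.
* Region table TSV: ``region_id chrom flank5_start flank5_end target_start
  target_end flank3_start flank3_end`` (1-based inclusive coordinates).
* PennCNV ``rawcnv`` call lines, e.g.
  ``chr2:110852875-110942946 numsnp=97 length=90072 state2,cn=1 s1.txt
  startsnp=rsA endsnp=rsB``.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    PennCNVCall,
    ProbeMap,
    RegionDefinition,
    SampleSignal,
    normalize_chrom,
)

__all__ = [
    "read_probe_map",
    "write_probe_map",
    "read_signal_file",
    "write_signal_file",
    "read_region_table",
    "write_region_table",
    "read_rawcnv",
    "write_rawcnv",
    "SignalFormatError",
    "ManifestMismatchError",
]

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA", "NaN", "nan")


class SignalFormatError(ValueError):
    """A signal file lacks a required column or is otherwise malformed."""


class ManifestMismatchError(ValueError):
    """A signal file does not match the probe map (different manifest)."""


def read_probe_map(path: str | Path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str},
                     comment="#")
    for col in ("probe_id", "chrom", "position"):
        if col not in df.columns:
            raise SignalFormatError(f"probe map is missing column '{col}'")
    return ProbeMap(df["probe_id"].to_numpy(object),
                    df["chrom"].to_numpy(object),
                    df["position"].to_numpy(np.int64))


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    pd.DataFrame({
        "probe_id": probe_map.probe_id,
        "chrom": probe_map.chromosome,
        "position": probe_map.position,
    }).to_csv(path, sep="\t", index=False)


def _find_column(columns, suffix: str) -> str:
    hits = [c for c in columns if c.endswith(suffix)]
    if not hits:
        raise SignalFormatError(f"signal file is missing a '{suffix}' column")
    return hits[0]


def read_signal_file(path: str | Path, probe_map: ProbeMap) -> SampleSignal:
    """Parse one PennCNV split-signal file aligned to ``probe_map``.

    Probes absent from the file become nan; non-numeric LRR/BAF tokens
    ("NA", "NaN", empty) become nan. Raises :class:`ManifestMismatchError`
    when more than half of the map's probes are absent from the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    name_col = next((c for c in ("SNP Name", "Name", "probe_id") if c in df.columns), None)
    if name_col is None:
        raise SignalFormatError("signal file is missing a 'SNP Name' column")
    lrr_col = _find_column(df.columns, ".Log R Ratio")
    baf_col = _find_column(df.columns, ".B Allele Freq")
    sample_id = lrr_col[: -len(".Log R Ratio")]

    def to_float(series: pd.Series) -> np.ndarray:
        s = series.str.strip()
        s = s.where(~s.isin(MISSING_TOKENS), other=np.nan)
        return pd.to_numeric(s, errors="coerce").to_numpy(float)

    idx = probe_map.index_of(df[name_col].to_numpy(object))
    known = idx >= 0
    n = len(probe_map)
    lrr = np.full(n, np.nan)
    baf = np.full(n, np.nan)
    lrr[idx[known]] = to_float(df[lrr_col])[known]
    baf[idx[known]] = to_float(df[baf_col])[known]
    matched_probes = len(set(idx[known]))
    if matched_probes < 0.5 * n:
        raise ManifestMismatchError(
            f"{path}: only {matched_probes}/{n} probes of the map are present; "
            "the file appears to come from a different manifest")
    return SampleSignal(sample_id=sample_id, lrr=lrr, baf=baf)


def write_signal_file(signal: SampleSignal, probe_map: ProbeMap,
                      path: str | Path) -> None:
    sid = signal.sample_id
    df = pd.DataFrame({
        "SNP Name": probe_map.probe_id,
        "Chr": probe_map.chromosome,
        "Position": probe_map.position,
        f"{sid}.Log R Ratio": signal.lrr,
        f"{sid}.B Allele Freq": signal.baf,
    })
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.4f")


REGION_COLUMNS = [
    "region_id", "chrom",
    "flank5_start", "flank5_end",
    "target_start", "target_end",
    "flank3_start", "flank3_end",
]


def read_region_table(path: str | Path) -> list[RegionDefinition]:
    """Read region definitions; coordinates are 1-based inclusive hg19."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "chrom": str},
                     comment="#")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise SignalFormatError(f"region table is missing columns {missing}")
    regions = []
    for row in df.itertuples(index=False):
        regions.append(RegionDefinition(
            region_id=row.region_id,
            chromosome=row.chrom,
            target_start=int(row.target_start), target_end=int(row.target_end),
            flank5_start=int(row.flank5_start), flank5_end=int(row.flank5_end),
            flank3_start=int(row.flank3_start), flank3_end=int(row.flank3_end),
        ))
    return regions


def write_region_table(regions: list[RegionDefinition], path: str | Path) -> None:
    pd.DataFrame([{
        "region_id": r.region_id, "chrom": r.chromosome,
        "flank5_start": r.flank5_start, "flank5_end": r.flank5_end,
        "target_start": r.target_start, "target_end": r.target_end,
        "flank3_start": r.flank3_start, "flank3_end": r.flank3_end,
    } for r in regions]).to_csv(path, sep="\t", index=False)


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+"
    r"length=\S+\s+"
    r"state\d+,cn=(?P<cn>\d+)\s+"
    r"(?P<samplefile>\S+)"
)


def read_rawcnv(path: str | Path) -> list[PennCNVCall]:
    """Parse a PennCNV rawcnv call file; malformed lines are skipped with a
    logged warning. The sample id is the call's sample-file basename with the
    extension stripped."""
    calls: list[PennCNVCall] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _RAWCNV_RE.match(line)
            if m is None:
                n_bad += 1
                logger.warning("%s:%d: unparseable rawcnv line skipped", path, lineno)
                continue
            sample_id = os.path.splitext(os.path.basename(m["samplefile"]))[0]
            try:
                calls.append(PennCNVCall(
                    sample_id=sample_id,
                    chromosome=normalize_chrom(m["chrom"]),
                    start=int(m["start"]), end=int(m["end"]),
                    cn=int(m["cn"]), numsnp=int(m["numsnp"]),
                ))
            except ValueError:
                n_bad += 1
                logger.warning("%s:%d: invalid rawcnv record skipped", path, lineno)
    if n_bad:
        logger.warning("%s: %d malformed line(s) skipped", path, n_bad)
    return calls


def write_rawcnv(calls: list[PennCNVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            state = {0: 1, 1: 2, 3: 5, 4: 6}.get(c.cn, 2)
            fh.write(
                f"chr{c.chromosome}:{c.start}-{c.end} numsnp={c.numsnp} "
                f"length={c.length} state{state},cn={c.cn} {c.sample_id}.txt "
                f"startsnp=. endsnp=.\n")
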