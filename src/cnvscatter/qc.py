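"""Sample-level quality control and false-to-true ratio curves.

Three per-sample metrics rank array quality: the total number of PennCNV
calls (more = worse), the variance of all autosomal LRR values (higher =
worse), and the SNP call rate (lower = worse). Excluding the worst x% of
samples by one of these metrics and recomputing the ratio of false to true
CNV findings per method yields the QC-filtering curves.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import AUTOSOMES, PennCNVCall, ProbeMap, SampleQC, SampleSignal
from .comparison import ConcordanceRecord

__all__ = [
    "compute_qc",
    "qc_table",
    "filter_by_quality",
    "findings_from_records",
    "false_rate_curve",
    "QC_METRICS",
    "DEFAULT_EXCLUDE_FRACTIONS",
]

QC_METRICS = ("penncnv_calls", "lrr_variance", "call_rate")

#: exclusion stringencies of the standard filtering sweep
DEFAULT_EXCLUDE_FRACTIONS = (0.0, 0.01, 0.05, 0.10, 0.15, 0.25, 0.50)


def compute_qc(signal: SampleSignal, calls: list[PennCNVCall],
               probe_map: ProbeMap) -> SampleQC:
    """Quality metrics for one sample.

    The LRR variance is the population variance (n denominator) over
    non-missing autosomal probes; the call rate is the fraction of probes
    with a non-missing BAF (the closest proxy for a successful genotype
    available in signal files)."""
    autosomal = np.isin(probe_map.chromosome.astype(str), list(AUTOSOMES))
    if not autosomal.any():
        raise ValueError("probe map contains no autosomal probes")
    lrr = signal.lrr[autosomal]
    lrr = lrr[np.isfinite(lrr)]
    variance = float(np.var(lrr)) if lrr.size else float("nan")
    call_rate = float(np.isfinite(signal.baf).mean())
    n_calls = sum(1 for c in calls if c.sample_id == signal.sample_id)
    return SampleQC(sample_id=signal.sample_id, n_penncnv_calls=n_calls,
                    lrr_variance=variance, call_rate=call_rate)


def qc_table(signals: list[SampleSignal], calls: list[PennCNVCall],
             probe_map: ProbeMap) -> pd.DataFrame:
    """One QC row per sample, with per-metric rank percentiles attached
    (percentile 0 = best quality)."""
    rows = [compute_qc(s, calls, probe_map) for s in signals]
    df = pd.DataFrame([{
        "sample_id": q.sample_id,
        "n_penncnv_calls": q.n_penncnv_calls,
        "lrr_variance": q.lrr_variance,
        "call_rate": q.call_rate,
    } for q in rows])
    n = len(df)
    # worst = highest call count / highest variance / lowest call rate
    df["pct_penncnv_calls"] = df["n_penncnv_calls"].rank(method="average") / n
    df["pct_lrr_variance"] = df["lrr_variance"].rank(method="average") / n
    df["pct_call_rate"] = df["call_rate"].rank(ascending=False, method="average") / n
    return df


_WORST_KEY = {
    # (column, ascending=False means highest first)
    "penncnv_calls": ("n_penncnv_calls", False),
    "lrr_variance": ("lrr_variance", False),
    "call_rate": ("call_rate", True),
}


def filter_by_quality(qc: pd.DataFrame, metric: str,
                      exclude_fraction: float) -> set[str]:
    """Sample ids retained after removing the worst ``floor(f * n)`` samples.

    'Worst' is the highest PennCNV call count, the highest LRR variance or
    the lowest call rate; ties break lexicographically by sample id so the
    retained set is deterministic and nested across fractions."""
    if not 0.0 <= exclude_fraction <= 1.0:
        raise ValueError(f"exclude_fraction {exclude_fraction} outside [0, 1]")
    if metric not in _WORST_KEY:
        raise ValueError(f"unknown QC metric '{metric}'; one of {QC_METRICS}")
    col, ascending = _WORST_KEY[metric]
    n = len(qc)
    n_drop = math.floor(exclude_fraction * n)
    ordered = qc.sort_values([col, "sample_id"],
                             ascending=[ascending, True])
    dropped = set(ordered["sample_id"].iloc[:n_drop]) if n_drop else set()
    return set(qc["sample_id"]) - dropped


def findings_from_records(records: list[ConcordanceRecord],
                          truth: pd.DataFrame) -> pd.DataFrame:
    """Expand concordance records into per-method findings with truth labels.

    ``truth`` carries sample_id, region_id and true_cn columns (the
    simulator's truth table or a user-supplied review result); a finding is
    true when the sample genuinely carries a non-diploid state there."""
    truth_cn = {(r.sample_id, r.region_id): int(r.true_cn)
                for r in truth.itertuples(index=False)}
    rows = []
    for rec in records:
        is_true = truth_cn.get((rec.sample_id, rec.region_id), 2) != 2
        if rec.scatterplot_cn is not None:
            rows.append({"sample_id": rec.sample_id, "region_id": rec.region_id,
                         "method": "scatterplot", "is_true": is_true})
        if rec.penncnv_cn is not None:
            rows.append({"sample_id": rec.sample_id, "region_id": rec.region_id,
                         "method": "penncnv", "is_true": is_true})
    return pd.DataFrame(rows, columns=["sample_id", "region_id", "method", "is_true"])


def false_rate_curve(findings: pd.DataFrame, qc: pd.DataFrame, metric: str,
                     fractions=DEFAULT_EXCLUDE_FRACTIONS) -> pd.DataFrame:
    """False-to-true finding ratio per method across exclusion fractions.

    Returns one row per (fraction, method) with the counts and the ratio;
    strata with zero true findings get a nan ratio (flagged undefined rather
    than infinite)."""
    rows = []
    for frac in fractions:
        retained = filter_by_quality(qc, metric, frac)
        sub = findings[findings["sample_id"].isin(retained)]
        for method in ("scatterplot", "penncnv"):
            f = sub[sub["method"] == method]
            n_true = int(f["is_true"].sum())
            n_false = int((~f["is_true"]).sum())
            rows.append({
                "exclude_fraction": frac, "metric": metric, "method": method,
                "n_true": n_true, "n_false": n_false,
                "false_to_true": (n_false / n_true) if n_true else float("nan"),
            })
    return pd.DataFrame(rows)
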