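"""Shared fixtures: small probe maps and session-scoped simulated cohorts."""

import numpy as np
import pytest

from cnvscatter.datatypes import ProbeMap, RegionDefinition
from cnvscatter.region_metrics import summarize_cohort
from cnvscatter.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_probe_map() -> ProbeMap:
    """9 probes on chr1: three per interval of ``tiny_region``."""
    positions = [100, 200, 300, 1100, 1200, 1300, 2100, 2200, 2300]
    return ProbeMap(
        probe_id=np.array([f"rs{i}" for i in range(9)], dtype=object),
        chromosome=np.array(["1"] * 9, dtype=object),
        position=np.array(positions, dtype=np.int64),
    )


@pytest.fixture
def tiny_region() -> RegionDefinition:
    return RegionDefinition(
        region_id="T", chromosome="1",
        flank5_start=1, flank5_end=999,
        target_start=1000, target_end=1999,
        flank3_start=2000, flank3_end=3000,
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """n=500 cohort without waves or quality strata: the calibration
    conditions for cluster recovery (deletion allele 0.08, duplication
    allele 0.04, LRR noise SD 0.08)."""
    cfg = SimulationConfig(n_samples=500, seed=11, wave_amplitude_sd=0.0,
                           low_quality_fraction=0.0, lrr_noise_sd=0.08)
    probe_map, signals, truth = simulate_cohort(cfg)
    summaries = summarize_cohort(signals, cfg.regions, probe_map)
    return cfg, probe_map, signals, truth, summaries


@pytest.fixture(scope="session")
def default_cohort():
    """n=300 cohort under the full default conditions (waves, low-quality
    stratum, missingness) for end-to-end and QC tests."""
    cfg = SimulationConfig(n_samples=300, seed=5)
    probe_map, signals, truth = simulate_cohort(cfg)
    summaries = summarize_cohort(signals, cfg.regions, probe_map)
    return cfg, probe_map, signals, truth, summaries
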