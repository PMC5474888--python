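import numpy as np
import pandas as pd
import pytest

from metaphylo.simulate import (SimulationConfig, emit_cna_profiles,
                                emit_read_counts, simulate_patient)


@pytest.fixture(scope="session")
def clean_patient():
    """A noise-free, deep-coverage patient: truth should be recovered exactly."""
    cfg = SimulationConfig(n_samples=4, seed=42, depth_mean=5000,
                           error_rate=0.0, ccf_range=(0.9, 1.0))
    truth = simulate_patient(cfg)
    counts = emit_read_counts(truth, cfg)
    return cfg, truth, counts


@pytest.fixture(scope="session")
def reversion_patient():
    """A patient with planted LOH reversions at moderate CNA background."""
    cfg = SimulationConfig(n_samples=4, seed=5, depth_mean=3000,
                           loh_probability=0.4, n_segments=40,
                           n_truncal_snvs=40, n_branch_snvs=12.0,
                           n_branch_cnas=0.5, ccf_range=(0.8, 1.0))
    truth = simulate_patient(cfg)
    counts = emit_read_counts(truth, cfg)
    return cfg, truth, counts


def diploid_profile(samples, n_segments=4, **overrides):
    """Uniform 2/1 segment table, with per-sample (chrom -> (major, minor))
    overrides."""
    rows = []
    for s in samples:
        for seg in range(n_segments):
            chrom = str(seg + 1)
            major, minor = overrides.get(s, {}).get(chrom, (1, 1))
            rows.append(dict(sample=s, chrom=chrom, start=1, end=1000,
                             total=major + minor, major=major, minor=minor))
    return pd.DataFrame(rows)
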