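"""Shared fixtures: small synthetic cohorts and WFDB fixture writing."""

from pathlib import Path

import numpy as np
import pytest

from vcgmi import SyntheticConfig, generate_cohort


def write_wfdb_pair(directory: Path, name: str, fs: float, leads: dict,
                    gain: float = 2000.0, baseline: int = 0) -> Path:
    """Write a minimal format-16 WFDB header/signal fixture pair.

    ``leads`` maps lead names to equal-length mV arrays. Returns the
    record path (without extension).
    """
    names = list(leads)
    arrays = [np.asarray(leads[n], dtype=float) for n in names]
    n_samples = len(arrays[0])
    lines = [f"{name} {len(names)} {fs:g} {n_samples}"]
    for lead_name in names:
        lines.append(f"{name}.dat 16 {gain:g}({baseline})/mV 16 0 0 0 0 {lead_name}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    digital = np.column_stack([np.round(a * gain).astype("<i2") + baseline
                               for a in arrays])
    digital.astype("<i2").tofile(directory / f"{name}.dat")
    return directory / name


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6 record cohort at default noise/wander (shared, read-only)."""
    config = SyntheticConfig(n_mi=6, n_hc=6, duration_s=8.0, seed=42)
    records, truths = generate_cohort(config)
    return config, records, truths


@pytest.fixture(scope="session")
def clean_cohort():
    """A noiseless, wander-free 4+4 cohort for geometric ground truth."""
    config = SyntheticConfig(n_mi=4, n_hc=4, duration_s=8.0,
                             noise_sd_mv=0.0, wander_amp_mv=0.0, seed=99)
    records, truths = generate_cohort(config)
    return config, records, truths
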