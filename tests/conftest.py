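"""Shared fixtures: a small synthetic cohort and an EDF fixture writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from eegstates.simulate import default_two_state_spec, generate_cohort
from eegstates.spectral import collect_peaks


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-subject two-state cohort at desk scale (250 Hz, 20 s / 10 s).

    Durations are even integer seconds so the default 2 s transient
    discard leaves windows with integer periods of the generator's
    0.5 Hz-grid sinusoids. Group sizes follow the default fractions:
    G = 7 (G* = 3), B = 3.
    """
    spec = default_two_state_spec(
        n_subjects=10, seed=7, rate=250.0, duration_R=20.0, duration_T=10.0)
    dataset, truth = generate_cohort(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def small_peaks(small_cohort):
    _, dataset, _ = small_cohort
    return collect_peaks(dataset)


def write_minimal_edf(path, data_uv: np.ndarray, rate: int,
                      labels: list[str]) -> None:
    """Write a minimal valid EDF file (synthetic test fixture).

    One data record per second, 16-bit samples, physical units uV.
    Only used to create fixtures for exercising the EDF reader.
    """
    n_sig, n_samp = data_uv.shape
    assert n_samp % rate == 0
    n_records = n_samp // rate
    phys_max = max(1.0, float(np.abs(data_uv).max()) * 1.1)

    def pad(s: str, width: int) -> bytes:
        return s.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_sig + 1)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(n_sig), 4),
    ])
    fields = [
        (16, labels), (80, [""] * n_sig), (8, ["uV"] * n_sig),
        (8, [f"{-phys_max:.6g}"] * n_sig), (8, [f"{phys_max:.6g}"] * n_sig),
        (8, ["-32768"] * n_sig), (8, ["32767"] * n_sig),
        (80, [""] * n_sig), (8, [str(rate)] * n_sig), (32, [""] * n_sig),
    ]
    for width, values in fields:
        header += b"".join(pad(str(v), width) for v in values)

    scale = 32767.0 / phys_max
    digital = np.clip(np.round(data_uv * scale), -32768, 32767).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * rate:(rec + 1) * rate]
            f.write(chunk.tobytes())
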