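"""Amplitude spectra and per-band spectral peak extraction.

The estimator is a single full-length DFT with rectangular window and
amplitude normalization 2/N on one-sided bins, so the value at an
exactly resolved sinusoid's bin equals the sinusoid's amplitude. The
normalization makes spectra of the 180 s resting and 60 s task
recordings directly comparable on one axis, which the range-limit
classifier requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CompletenessError, Recording, StudyDataset
from .filtering import (
    CANONICAL_BANDS,
    DEFAULT_SETTLE_S,
    BandDefinition,
    apply_bandpass,
    design_bandpass,
)

__all__ = [
    "Spectrum",
    "SpectralPeak",
    "ResolutionError",
    "amplitude_spectrum",
    "band_peak",
    "collect_peaks",
]


class ResolutionError(ValueError):
    """The spectrum has no bins inside the requested band."""


@dataclass
class Spectrum:
    """One-sided amplitude spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    magnitude: np.ndarray
    resolution: float  # Hz, = rate / n_samples

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


@dataclass(frozen=True)
class SpectralPeak:
    """Peak magnitude and frequency for one (subject, channel, band, state)."""

    subject_id: str
    channel: str
    band: str
    state: str
    peak_magnitude: float
    peak_freq: float


def amplitude_spectrum(series: np.ndarray, rate: float) -> Spectrum:
    """One-sided amplitude spectrum of a real series.

    Interior bins are scaled by 2/N, the DC bin (and Nyquist bin for even
    N) by 1/N, so a unit-amplitude sinusoid with an integer number of
    periods yields magnitude 1.0 at its bin regardless of series length.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    n = series.size
    mag = np.abs(np.fft.rfft(series)) / n
    mag[1:] *= 2.0
    if n % 2 == 0:
        mag[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return Spectrum(freqs=freqs, magnitude=mag, resolution=rate / n)


def band_peak(spectrum: Spectrum, band: BandDefinition) -> tuple[float, float]:
    """Maximum magnitude over bins with f_low <= f < f_high, and its frequency.

    Ties are broken toward the lowest frequency (argmax returns the first
    maximal bin on the increasing grid).
    """
    mask = band.contains(spectrum.freqs)
    if not np.any(mask):
        raise ResolutionError(
            f"no spectral bins inside {band.name} "
            f"[{band.f_low}, {band.f_high}) at resolution {spectrum.resolution} Hz"
        )
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(spectrum.magnitude[idx])]
    return float(spectrum.magnitude[best]), float(spectrum.freqs[best])


def peaks_for_recording(
    recording: Recording,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    settle_s: float = DEFAULT_SETTLE_S,
) -> list[SpectralPeak]:
    """Filter one raw recording into each band and extract channel peaks."""
    out: list[SpectralPeak] = []
    for band in bands:
        spec = design_bandpass(band, recording.rate)
        filtered = apply_bandpass(recording, spec, settle_s=settle_s)
        settled = filtered.settled()
        for ci, channel in enumerate(recording.channels):
            spectrum = amplitude_spectrum(settled[ci], recording.rate)
            mag, freq = band_peak(spectrum, band)
            out.append(SpectralPeak(
                subject_id=recording.subject_id, channel=channel,
                band=band.name, state=recording.state,
                peak_magnitude=mag, peak_freq=freq,
            ))
    return out


def collect_peaks(
    dataset: StudyDataset,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    settle_s: float = DEFAULT_SETTLE_S,
) -> pd.DataFrame:
    """Peak table for a whole cohort: one row per (subject, channel, band, state).

    For an n-subject cohort over the 19-channel montage and three bands
    this yields n x 19 x 3 rows per state (1938 per state at n = 34,
    3876 in total).

    Raises
    ------
    CompletenessError
        If a non-excluded subject is missing a state recording.
    """
    rows: list[SpectralPeak] = []
    for sid in dataset.subjects():
        for state in ("R", "T"):
            if (sid, state) not in dataset.recordings:
                raise CompletenessError(
                    f"missing {state} recording for subject {sid}"
                )
            rows.extend(
                peaks_for_recording(dataset.recordings[(sid, state)],
                                    bands=bands, settle_s=settle_s)
            )
    return pd.DataFrame([r.__dict__ for r in rows])
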