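"""Synthetic two-state EEG cohorts with known ground truth.

The generator emulates the structure the analysis assumes: per subject,
one long resting (R) and one short task (T) multichannel recording in
which

* the in-band spectral peak of designated channels is controlled by a
  single sinusoid at a fixed in-band frequency whose amplitude is drawn
  from a state-dependent range (task peaks exceeding resting peaks in
  the discriminating bands), and
* the pairwise Pearson correlation of designated channel pairs is
  controlled by mixing band-limited unit-variance noises through the
  Cholesky factor of a per-(band, state) target correlation matrix
  (resting correlation high, task correlation low at designated pairs,
  a uniform baseline elsewhere).

Sinusoid frequencies snap to a 0.5 Hz grid near each band's geometric
center (theta 5.5, alpha 10.0, beta 19.5 Hz) so that analysis windows
spanning an even integer number of seconds contain an integer number of
periods and the closed-form peak magnitude (peak = amplitude) is exact.

Only second-order structure is modelled: no 1/f background, artifacts,
or nonstationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    CANONICAL_CHANNELS,
    PerformanceRecord,
    Recording,
    StudyDataset,
    assign_groups,
)
from .filtering import BAND_BY_NAME, BandDefinition, band_limited_noise

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "correlated_band_noise",
    "generate_subject_pair",
    "generate_cohort",
    "default_two_state_spec",
]

#: Score intervals (mean +/- sd of operations per minute) per group,
#: matching the reference cohort's reported group statistics.
GROUP_SCORE_INTERVALS = {"G": (13.6, 28.4), "B": (3.4, 10.6)}
GSTAR_SCORE_INTERVAL = (26.0, 28.4)


def snapped_center(band: BandDefinition) -> float:
    """Band geometric-center frequency snapped to the 0.5 Hz grid."""
    f = round(2.0 * band.center) / 2.0
    # stay strictly inside the half-open band interval
    f = min(max(f, band.f_low), band.f_high - 0.5)
    return f


@dataclass
class SynthSpec:
    """Parameters of a synthetic two-state cohort.

    Attributes
    ----------
    n_subjects : int
    rate : float
        Samples/s (default 500, the study's acquisition rate).
    duration_R, duration_T : float
        Recording lengths in seconds (defaults 180 and 60).
    band_peak_amplitude : dict
        (channel, band name, state) -> (lo, hi) sinusoid amplitude range
        in microvolts. Channels/bands/states not listed use
        ``default_amplitude``.
    pair_correlation : dict
        (channel_a, channel_b, band name, state) -> target Pearson value
        in [-1, 1]. Unlisted pairs use ``baseline_correlation``.
    default_amplitude : (float, float)
        Amplitude range for non-designated entries.
    baseline_correlation : float
        Band-noise correlation between non-designated channel pairs.
    band_noise_sd : float
        Standard deviation (uV) of each channel's band-limited noise
        component, per band.
    noise_sd : float
        White measurement-noise standard deviation in microvolts.
    g_fraction, gstar_fraction : float
        Fraction of subjects assigned to group G, and fraction of G
        drawn with scores in the G* interval (score >= 26).
    seed : int
    """

    n_subjects: int
    rate: float = 500.0
    duration_R: float = 180.0
    duration_T: float = 60.0
    band_peak_amplitude: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=dict)
    pair_correlation: dict[tuple[str, str, str, str], float] = field(
        default_factory=dict)
    default_amplitude: tuple[float, float] = (1.0, 2.0)
    baseline_correlation: float = 0.3
    band_noise_sd: float = 3.0
    noise_sd: float = 1.0
    g_fraction: float = 25 / 34
    gstar_fraction: float = 11 / 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_R <= 0 or self.duration_T <= 0:
            raise ValueError("durations must be positive")
        for key, (lo, hi) in self.band_peak_amplitude.items():
            if lo > hi or lo < 0:
                raise ValueError(f"invalid amplitude range {key}: ({lo}, {hi})")
            self._check_key(key[0], key[1], key[2])
        for key, rho in self.pair_correlation.items():
            if abs(rho) > 1:
                raise ValueError(f"|target correlation| > 1 for {key}")
            a, b, band, state = key
            self._check_key(a, band, state)
            self._check_key(b, band, state)
            if a == b:
                raise ValueError(f"self-pair in pair_correlation: {key}")
        if abs(self.baseline_correlation) > 1:
            raise ValueError("|baseline_correlation| > 1")

    @staticmethod
    def _check_key(channel: str, band: str, state: str) -> None:
        if channel not in CANONICAL_CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        if band not in BAND_BY_NAME:
            raise ValueError(f"unknown band {band!r}")
        if state not in ("R", "T"):
            raise ValueError(f"state must be 'R' or 'T', got {state!r}")

    def amplitude_range(self, channel: str, band: str, state: str) -> tuple[float, float]:
        return self.band_peak_amplitude.get((channel, band, state),
                                            self.default_amplitude)


@dataclass
class GroundTruth:
    """Realized generator state for downstream verification."""

    amplitudes: dict[tuple[str, str, str, str], float]  # (sid, ch, band, state)
    sinusoid_freqs: dict[str, float]  # band -> Hz
    correlation_targets: dict[tuple[str, str], np.ndarray]  # (band, state) -> 19x19
    designated_channels: tuple[tuple[str, str], ...]  # (channel, band)
    designated_pairs: tuple[tuple[str, str, str], ...]  # (a, b, band)
    scores: dict[str, float]


def correlated_band_noise(
    n: int,
    rate: float,
    band: BandDefinition,
    target_rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two band-limited unit-variance series with expected Pearson ``target_rho``.

    Built as x1 = a z + b e1, x2 = sign(rho) a z + b e2 with z, e1, e2
    independent band-limited unit-variance noises and
    a^2 / (a^2 + b^2) = |target_rho|.
    """
    if abs(target_rho) > 1:
        raise ValueError(f"|target_rho| must be <= 1, got {target_rho}")
    z, e1, e2 = band_limited_noise(n, rate, band, rng, size=3)
    a = np.sqrt(abs(target_rho))
    b = np.sqrt(1.0 - abs(target_rho))
    x1 = a * z + b * e1
    x2 = np.copysign(1.0, target_rho) * a * z + b * e2
    return x1, x2


def _target_matrix(spec: SynthSpec, band: str, state: str) -> np.ndarray:
    """Per-(band, state) 19x19 target correlation matrix."""
    n = len(CANONICAL_CHANNELS)
    c = np.full((n, n), spec.baseline_correlation, dtype=float)
    np.fill_diagonal(c, 1.0)
    idx = {ch: i for i, ch in enumerate(CANONICAL_CHANNELS)}
    for (a, b, bnd, st), rho in spec.pair_correlation.items():
        if bnd == band and st == state:
            c[idx[a], idx[b]] = c[idx[b], idx[a]] = rho
    return c


def _mixing_factor(c: np.ndarray) -> np.ndarray:
    """Lower-triangular mixing matrix for a target correlation matrix.

    Eigenvalues are clipped at a small positive floor so that nearly- or
    non-positive-definite targets (possible when designations overlap)
    still yield a valid factor; the result is renormalized to unit
    diagonal before the Cholesky decomposition.
    """
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-9, None)
    c_pd = (v * w) @ v.T
    d = np.sqrt(np.diag(c_pd))
    c_pd = c_pd / np.outer(d, d)
    c_pd = (c_pd + c_pd.T) / 2 + 1e-12 * np.eye(c.shape[0])
    return np.linalg.cholesky(c_pd)


def generate_subject_pair(
    spec: SynthSpec,
    subject_id: str,
    rng: np.random.Generator,
    ground_truth: GroundTruth | None = None,
) -> tuple[Recording, Recording]:
    """Generate one subject's (R, T) recording pair.

    Each channel is the sum over bands of a sinusoid with the drawn
    in-band amplitude and a correlated band-limited noise component,
    plus white measurement noise. Bit-identical output for the same
    spec, subject and generator state.
    """
    recordings = {}
    for state, duration in (("R", spec.duration_R), ("T", spec.duration_T)):
        n = int(round(duration * spec.rate))
        t = np.arange(n) / spec.rate
        data = np.zeros((len(CANONICAL_CHANNELS), n))
        for band_name, band in BAND_BY_NAME.items():
            f = snapped_center(band)
            # sinusoidal spectral-peak components
            for ci, channel in enumerate(CANONICAL_CHANNELS):
                lo, hi = spec.amplitude_range(channel, band_name, state)
                amp = rng.uniform(lo, hi)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                data[ci] += amp * np.sin(2.0 * np.pi * f * t + phase)
                if ground_truth is not None:
                    ground_truth.amplitudes[
                        (subject_id, channel, band_name, state)] = amp
            # correlated band-limited noise
            if spec.band_noise_sd > 0:
                c = _target_matrix(spec, band_name, state)
                mix = _mixing_factor(c)
                z = band_limited_noise(n, spec.rate, band, rng,
                                       size=len(CANONICAL_CHANNELS))
                data += spec.band_noise_sd * (mix @ z)
        if spec.noise_sd > 0:
            data += spec.noise_sd * rng.standard_normal(data.shape)
        recordings[state] = Recording(
            subject_id=subject_id, state=state, rate=spec.rate, data=data,
        )
    return recordings["R"], recordings["T"]


def _synthetic_manifest(spec: SynthSpec, rng: np.random.Generator) -> list[PerformanceRecord]:
    """Draw per-subject scores uniformly within group-specific intervals."""
    n_g = int(round(spec.g_fraction * spec.n_subjects))
    n_gstar = int(round(spec.gstar_fraction * n_g))
    records = []
    for i in range(spec.n_subjects):
        sid = f"S{i + 1}"
        if i < n_g:
            if i < n_gstar:
                lo, hi = GSTAR_SCORE_INTERVAL
            else:
                lo, hi = GROUP_SCORE_INTERVALS["G"][0], 26.0
            group = "G"
        else:
            lo, hi = GROUP_SCORE_INTERVALS["B"]
            group = "B"
        records.append(PerformanceRecord(
            subject_id=sid, score=float(rng.uniform(lo, hi)), group=group,
        ))
    records.sort(key=lambda r: -r.score)
    return assign_groups(records)


def generate_cohort(spec: SynthSpec) -> tuple[StudyDataset, GroundTruth]:
    """Generate a full cohort and its ground truth, seeded by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    manifest = _synthetic_manifest(spec, rng)
    truth = GroundTruth(
        amplitudes={},
        sinusoid_freqs={name: snapped_center(b)
                        for name, b in BAND_BY_NAME.items()},
        correlation_targets={
            (band, state): _target_matrix(spec, band, state)
            for band in BAND_BY_NAME for state in ("R", "T")
        },
        designated_channels=tuple(sorted({(ch, band) for ch, band, _
                                          in spec.band_peak_amplitude})),
        designated_pairs=tuple(sorted({(a, b, band) for a, b, band, _
                                       in spec.pair_correlation})),
        scores={r.subject_id: r.score for r in manifest},
    )
    recordings: dict[tuple[str, str], Recording] = {}
    for rec in manifest:
        r, t = generate_subject_pair(spec, rec.subject_id, rng, truth)
        recordings[(rec.subject_id, "R")] = r
        recordings[(rec.subject_id, "T")] = t
    return StudyDataset(recordings=recordings, manifest=manifest), truth


def default_two_state_spec(n_subjects: int = 34, seed: int = 0, **overrides) -> SynthSpec:
    """A cohort spec with the discriminative structure of the study design.

    Designated spectral-peak channels: F7 and Fz in theta and F7 in beta
    carry task amplitudes in [8, 10] uV against resting [1, 2] uV (all
    other channel/band amplitudes stay at the [1, 2] uV default in both
    states). Designated correlation pairs: F4-F7 and F3-F8 in beta with
    resting correlation 0.9 dropping to 0.1 under task, against a 0.3
    baseline.
    """
    band_peak_amplitude = {}
    for channel, band in (("F7", "theta"), ("Fz", "theta"), ("F7", "beta")):
        band_peak_amplitude[(channel, band, "T")] = (8.0, 10.0)
        band_peak_amplitude[(channel, band, "R")] = (1.0, 2.0)
    pair_correlation = {}
    for a, b in (("F4", "F7"), ("F3", "F8")):
        pair_correlation[(a, b, "beta", "R")] = 0.9
        pair_correlation[(a, b, "beta", "T")] = 0.1
    kwargs = dict(
        n_subjects=n_subjects,
        band_peak_amplitude=band_peak_amplitude,
        pair_correlation=pair_correlation,
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthSpec(**kwargs)
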