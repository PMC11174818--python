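"""Core data types and I/O for two-state (rest vs. mental-arithmetic) EEG cohorts.

The study layout this module targets is one resting ("R", 180 s) and one
task ("T", 60 s) recording per subject over the 19 monopolar channels of
the 10-20 system, sampled at 500 Hz, together with a performance manifest
that scores each subject by mean correct serial subtractions per minute
and splits the cohort into a good-performance group G, a bad-performance
group B, and the high-scoring subset G* (score >= 26).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_CHANNELS",
    "ChannelSet",
    "Recording",
    "PerformanceRecord",
    "StudyDataset",
    "FormatError",
    "RateError",
    "ManifestError",
    "CompletenessError",
    "read_edf_recording",
    "load_manifest",
    "load_packaged_manifest",
    "assign_groups",
    "save_dataset",
    "load_dataset",
]

#: Canonical 10-20 montage order used for all matrix indexing.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "T3", "T4", "T5", "T6", "O1", "O2",
)

#: Default scoring cutoff defining G* membership within group G.
GSTAR_MIN_SCORE = 26.0


class FormatError(ValueError):
    """Input file does not match the expected recording layout."""


class RateError(ValueError):
    """Sampling rate differs from the expected rate."""


class ManifestError(ValueError):
    """Malformed performance manifest."""


class CompletenessError(ValueError):
    """A subject is missing one of its two state recordings."""


def normalize_label(label: str) -> str:
    """Normalize an electrode label: strip non-alphanumerics, lowercase.

    Database labels may carry prefixes ("EEG Fp1-A1A2") or case variants;
    matching is done on the normalized form without altering the canonical
    set itself.
    """
    s = re.sub(r"[^A-Za-z0-9]", " ", label)
    for token in s.split():
        t = token.lower()
        if t in _CANON_BY_NORM:
            return t
    return s.replace(" ", "").lower()


_CANON_BY_NORM = {c.lower(): c for c in CANONICAL_CHANNELS}


@dataclass(frozen=True)
class ChannelSet:
    """Ordered set of the 19 canonical 10-20 electrode labels."""

    names: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        if len(self.names) != 19:
            raise ValueError(f"expected 19 channels, got {len(self.names)}")
        if len(set(self.names)) != 19:
            raise ValueError("duplicate channel labels")

    def index(self, label: str) -> int:
        return self.names.index(label)

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Recording:
    """One subject/state multichannel EEG time series.

    Parameters
    ----------
    subject_id : str
        Subject identifier, e.g. ``"S27"``.
    state : {"R", "T"}
        Resting or task condition.
    rate : float
        Sampling rate in samples/s.
    data : ndarray of shape (n_channels, n_samples)
        Sample values in microvolts, one row per channel in the order of
        ``channels``.
    channels : ChannelSet
        Channel labels; defaults to the canonical 19-channel montage.
    transient_samples : int
        Leading samples flagged as filter transient, to be excluded from
        correlation and spectral computations. Zero for unfiltered data.
    band : str or None
        Name of the band this recording was filtered to, or None for the
        raw (acquisition-band) signal.
    """

    subject_id: str
    state: str
    rate: float
    data: np.ndarray
    channels: ChannelSet = field(default_factory=ChannelSet)
    transient_samples: int = 0
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.state not in ("R", "T"):
            raise ValueError(f"state must be 'R' or 'T', got {self.state!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be ({len(self.channels)}, n_samples), got {self.data.shape}"
            )
        if self.rate <= 60.0:  # must resolve the beta band (edge 30 Hz)
            raise RateError(f"rate {self.rate} too low for 0.5-30 Hz content")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]

    def settled(self) -> np.ndarray:
        """Data with the leading transient-flagged samples removed."""
        return self.data[:, self.transient_samples:]


@dataclass
class PerformanceRecord:
    """Per-subject arithmetic performance entry of the manifest."""

    subject_id: str
    score: float
    group: str
    in_gstar: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative score for {self.subject_id}")
        if self.group not in ("G", "B"):
            raise ValueError(f"group must be 'G' or 'B', got {self.group!r}")
        if self.in_gstar and self.group != "G":
            raise ValueError("in_gstar requires group 'G'")


@dataclass
class StudyDataset:
    """A cohort: recordings keyed by (subject_id, state) plus the manifest."""

    recordings: dict[tuple[str, str], Recording]
    manifest: list[PerformanceRecord]

    def get(self, subject_id: str, state: str) -> Recording:
        try:
            return self.recordings[(subject_id, state)]
        except KeyError:
            raise CompletenessError(
                f"missing {state} recording for subject {subject_id}"
            ) from None

    def subjects(self, group: str | None = None) -> list[str]:
        """Non-excluded subject ids, optionally restricted to G, B or G*."""
        out = []
        for rec in self.manifest:
            if rec.excluded:
                continue
            if group is None:
                out.append(rec.subject_id)
            elif group == "G*":
                if rec.in_gstar:
                    out.append(rec.subject_id)
            elif rec.group == group:
                out.append(rec.subject_id)
        return out

    @property
    def n_subjects(self) -> int:
        return len(self.subjects())

    def validate_complete(self) -> None:
        """Every non-excluded subject must have exactly one R and one T."""
        for sid in self.subjects():
            for state in ("R", "T"):
                if (sid, state) not in self.recordings:
                    raise CompletenessError(
                        f"missing {state} recording for subject {sid}"
                    )


def read_edf_recording(
    path: str | Path,
    expected_rate: float = 500.0,
    subject_id: str | None = None,
    state: str | None = None,
) -> Recording:
    """Read an EDF file and project it onto the canonical 19-channel montage.

    Reference (A1/A2) and ECG channels are dropped; labels are matched
    case-insensitively after stripping non-alphanumeric characters.
    Values are returned in microvolts.

    Raises
    ------
    FormatError
        If a canonical channel is absent.
    RateError
        If the stored rate differs from ``expected_rate``.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if abs(raw.info["sfreq"] - expected_rate) > 1e-6:
        raise RateError(
            f"{path.name}: rate {raw.info['sfreq']} != expected {expected_rate}"
        )
    by_norm: dict[str, int] = {}
    for i, name in enumerate(raw.ch_names):
        by_norm.setdefault(normalize_label(name), i)
    rows = []
    for canon in CANONICAL_CHANNELS:
        idx = by_norm.get(canon.lower())
        if idx is None:
            raise FormatError(f"{path.name}: missing canonical channel {canon}")
        rows.append(raw.get_data(picks=[idx])[0])
    data = np.vstack(rows) * 1e6  # mne loads EEG in volts
    if subject_id is None:
        subject_id = _subject_id_from_name(path.stem)
    if state is None:
        state = _state_from_name(path.stem)
    return Recording(subject_id=subject_id, state=state,
                     rate=expected_rate, data=data)


def _subject_id_from_name(stem: str) -> str:
    m = re.search(r"(\d+)", stem)
    if not m:
        raise FormatError(f"cannot infer subject id from {stem!r}")
    return f"S{int(m.group(1))}"


def _state_from_name(stem: str) -> str:
    # PhysioNet layout: Subject00_1.edf is rest, Subject00_2.edf is task.
    if stem.endswith("_1"):
        return "R"
    if stem.endswith("_2"):
        return "T"
    raise FormatError(f"cannot infer state (R/T) from {stem!r}")


def load_manifest(path: str | Path) -> list[PerformanceRecord]:
    """Load a performance manifest CSV.

    Expected header: ``subject_id,score,group,excluded``. Records are
    returned sorted by descending score with G* flags assigned at the
    default cutoff.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "score", "group", "excluded"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ManifestError(f"duplicate subject_id {dup!r}")
    records = [
        PerformanceRecord(
            subject_id=str(r.subject_id),
            score=float(r.score),
            group=str(r.group),
            excluded=bool(r.excluded),
        )
        for r in df.itertuples()
    ]
    records.sort(key=lambda r: -r.score)
    return assign_groups(records)


def load_packaged_manifest() -> list[PerformanceRecord]:
    """The packaged 36-subject performance manifest of the reference study."""
    ref = importlib.resources.files("eegstates") / "resources" / "performance_manifest.csv"
    with importlib.resources.as_file(ref) as p:
        return load_manifest(p)


def assign_groups(
    records: list[PerformanceRecord],
    gstar_min_score: float = GSTAR_MIN_SCORE,
) -> list[PerformanceRecord]:
    """Set ``in_gstar`` flags: group G membership with score >= cutoff.

    The cutoff (default 26) rather than a rank count defines G*, so the
    rule transfers unchanged to synthetic cohorts.
    """
    return [
        replace(r, in_gstar=(r.group == "G" and r.score >= gstar_min_score))
        for r in records
    ]


def save_dataset(dataset: StudyDataset, out_dir: str | Path) -> None:
    """Persist a cohort as one .npz per recording plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sid, state), rec in dataset.recordings.items():
        np.savez_compressed(
            out / f"{sid}_{state}.npz",
            data=rec.data, rate=rec.rate,
            channels=np.array(rec.channels.names),
        )
    rows = [
        {"subject_id": r.subject_id, "score": r.score,
         "group": r.group, "excluded": r.excluded}
        for r in dataset.manifest
    ]
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def load_dataset(in_dir: str | Path) -> StudyDataset:
    """Load a cohort saved by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    manifest = load_manifest(in_dir / "manifest.csv")
    recordings: dict[tuple[str, str], Recording] = {}
    for npz in sorted(in_dir.glob("*_[RT].npz")):
        sid, state = npz.stem.rsplit("_", 1)
        with np.load(npz) as f:
            recordings[(sid, state)] = Recording(
                subject_id=sid, state=state, rate=float(f["rate"]),
                data=f["data"],
                channels=ChannelSet(tuple(str(c) for c in f["channels"])),
            )
    return StudyDataset(recordings=recordings, manifest=manifest)
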