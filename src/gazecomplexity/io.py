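"""Reading, writing and validating the eye-tracker CSV dialect.

The dialect mirrors a desktop-tracker export: one row per sample at a fixed
sampling rate, with fixation position/duration, pupil diameter in pixels and
millimetres for both eyes, pupil-centre coordinates, blink duration and rate,
saccade magnitude and direction, and a 0/1 validity flag.  One file holds one
participant x activity task; the filename convention is
``<participant>_<activity>.csv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Channel columns, in canonical serialization order.
CHANNELS: tuple[str, ...] = (
    "FPOGX", "FPOGY", "FPOGD",
    "LPD", "LPMM", "RPD", "RPMM",
    "LPCX", "LPCY",
    "BKDUR", "BKPMIN",
    "SAC_MAG", "SAC_DIR",
    "VALID",
)

#: The three computer-activity labels.
ACTIVITIES: tuple[str, ...] = ("reading", "watching", "typing")

#: Channels whose values must be non-negative (durations, sizes, rates).
_NONNEG_CHANNELS = ("FPOGD", "LPD", "LPMM", "RPD", "RPMM", "BKDUR", "BKPMIN", "SAC_MAG")

#: Default eligibility threshold on the fraction of valid samples.
DEFAULT_VALIDITY_THRESHOLD = 0.85


class GazeFormatError(ValueError):
    """A gaze CSV file violates the dialect (missing column, bad cell)."""


class EligibilityError(ValueError):
    """A recording fails the validity eligibility gate."""


@dataclass
class GazeRecording:
    """A labelled multichannel eye-tracking time series for one task.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant; stable across that participant's tasks.
    activity_label : str
        One of ``reading``, ``watching``, ``typing``.
    sampling_rate : float
        Samples per second (Hz).
    data : pandas.DataFrame
        One row per sample with exactly the columns in :data:`CHANNELS`.
    """

    participant_id: str
    activity_label: str
    sampling_rate: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.participant_id = str(self.participant_id)
        if self.activity_label not in ACTIVITIES:
            raise ValueError(
                f"activity_label must be one of {ACTIVITIES}, got {self.activity_label!r}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise GazeFormatError(f"recording is missing channel(s): {', '.join(missing)}")
        self.data = self.data.loc[:, list(CHANNELS)].reset_index(drop=True)
        self._check_values()

    def _check_values(self) -> None:
        valid = self.data["VALID"].to_numpy()
        if not np.isin(valid, (0, 1)).all():
            raise ValueError("VALID channel must contain only 0 and 1")
        for ch in _NONNEG_CHANNELS:
            col = self.data[ch].to_numpy(dtype=float)
            if np.nanmin(col, initial=0.0) < 0:
                raise ValueError(f"channel {ch} contains negative values")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        """Task duration in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a float array."""
        return self.data[name].to_numpy(dtype=float)

    def valid_mask(self) -> np.ndarray:
        return self.data["VALID"].to_numpy() == 1

    def default_filename(self) -> str:
        return f"{self.participant_id}_{self.activity_label}.csv"


def read_gaze_csv(
    path: str | Path,
    participant_id: str | None = None,
    activity_label: str | None = None,
    sampling_rate: float = 150.0,
) -> GazeRecording:
    """Parse one gaze CSV file into a :class:`GazeRecording`.

    ``participant_id`` and ``activity_label`` default to the two tokens of the
    ``<participant>_<activity>.csv`` filename convention.  Unknown extra
    columns are ignored.  A missing required channel raises
    :class:`GazeFormatError` naming the column; a non-numeric cell raises
    :class:`GazeFormatError` with its row number.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise GazeFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    numeric = {}
    for ch in CHANNELS:
        col = pd.to_numeric(frame[ch], errors="coerce")
        bad = col.isna() & (frame[ch].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GazeFormatError(
                f"{path.name}: non-numeric value {frame[ch].iloc[row]!r} "
                f"in column {ch}, data row {row + 1}"
            )
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise GazeFormatError(
                f"{path.name}: empty cell in column {ch}, data row {row + 1}"
            )
        numeric[ch] = col.astype(float)
    if participant_id is None or activity_label is None:
        stem = path.stem
        pid, _, act = stem.rpartition("_")
        participant_id = participant_id if participant_id is not None else (pid or stem)
        if activity_label is None:
            if act not in ACTIVITIES:
                raise GazeFormatError(
                    f"{path.name}: cannot infer activity from filename "
                    f"(expected <participant>_<activity>.csv); pass activity_label="
                )
            activity_label = act
    return GazeRecording(
        participant_id=participant_id,
        activity_label=activity_label,
        sampling_rate=sampling_rate,
        data=pd.DataFrame(numeric),
    )


def write_gaze_csv(recording: GazeRecording, path: str | Path, precision: int = 6) -> Path:
    """Serialize a recording to CSV: header row plus one row per sample.

    Columns appear in the canonical :data:`CHANNELS` order; floats use fixed
    ``precision`` decimal digits so that a write/read round trip is the
    identity up to that precision.
    """
    path = Path(path)
    recording.data.to_csv(path, index=False, float_format=f"%.{precision}f")
    return path


def validity_summary(recording: GazeRecording) -> float:
    """Fraction of samples flagged valid, in [0, 1]."""
    if recording.n_samples == 0:
        raise ValueError("cannot summarize validity of an empty recording")
    return float(recording.data["VALID"].mean())


def check_eligibility(
    recording: GazeRecording,
    threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> bool:
    """Gate a recording on its validity fraction.

    Returns True when the fraction of valid samples is at least ``threshold``;
    otherwise emits a warning and returns False.  Downstream feature builders
    skip ineligible recordings.
    """
    frac = validity_summary(recording)
    if frac < threshold:
        warnings.warn(
            f"recording {recording.participant_id}/{recording.activity_label} "
            f"has validity {frac:.3f} < {threshold:.2f}; marked ineligible",
            stacklevel=2,
        )
        return False
    return True


def read_cohort(directory: str | Path, sampling_rate: float = 150.0) -> list[GazeRecording]:
    """Read every ``*.csv`` in a directory as one recording each."""
    directory = Path(directory)
    return [
        read_gaze_csv(p, sampling_rate=sampling_rate)
        for p in sorted(directory.glob("*.csv"))
    ]


def write_cohort(recordings: list[GazeRecording], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_gaze_csv(rec, directory / rec.default_filename()) for rec in recordings]
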