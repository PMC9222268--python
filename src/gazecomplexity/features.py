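"""Conventional eye-movement features: windowed summary statistics.

Each recording is cut into consecutive non-overlapping 3-second windows and
seven statistics (min, max, median, mean, standard deviation, variance,
skewness) are computed per window for eight derived-event channels —
fixation duration, the four pupil-size channels, blink duration and rate,
and saccade magnitude.  Eight channels x seven statistics gives the
56-column conventional feature table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GazeRecording
from .tables import KEY_COLUMNS, FeatureTable

#: Channels summarized by the conventional statistics (8 x 7 = 56 features).
CONVENTIONAL_CHANNELS: tuple[str, ...] = (
    "FPOGD", "LPD", "LPMM", "RPD", "RPMM", "BKDUR", "BKPMIN", "SAC_MAG",
)

#: The seven window statistics, in reporting order.
STATISTICS: tuple[str, ...] = ("min", "max", "median", "mean", "sd", "variance", "skewness")

DEFAULT_WINDOW_S = 3.0


def window_signal(recording: GazeRecording, window_s: float = DEFAULT_WINDOW_S) -> list[pd.DataFrame]:
    """Cut a recording into consecutive non-overlapping windows.

    Each window holds ``window_s * sampling_rate`` samples; a trailing
    partial window is dropped.  A 60 s task at 150 Hz with the default 3 s
    window yields 20 windows of 450 samples.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if recording.n_samples == 0:
        raise ValueError("recording is empty")
    win = int(round(window_s * recording.sampling_rate))
    if win > recording.n_samples:
        raise ValueError(
            f"window of {win} samples exceeds recording length {recording.n_samples}"
        )
    n_windows = recording.n_samples // win
    return [
        recording.data.iloc[i * win : (i + 1) * win]
        for i in range(n_windows)
    ]


def summarize_window(series: np.ndarray | pd.Series) -> dict[str, float]:
    """The seven summary statistics of one window of one channel.

    Missing (NaN) samples are excluded.  The standard deviation and variance
    use the n-1 denominator; skewness is the adjusted Fisher-Pearson
    coefficient (bias-corrected), reported as missing for fewer than three
    values or zero spread.  With no valid samples all seven are missing.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    out: dict[str, float] = {s: np.nan for s in STATISTICS}
    if x.size == 0:
        return out
    out["min"] = float(np.min(x))
    out["max"] = float(np.max(x))
    out["median"] = float(np.median(x))
    out["mean"] = float(np.mean(x))
    if x.size >= 2:
        out["variance"] = float(np.var(x, ddof=1))
        out["sd"] = float(np.sqrt(out["variance"]))
    if x.size >= 3 and out["sd"] > 0:
        out["skewness"] = float(sstats.skew(x, bias=False))
    return out


class ConventionalFeaturizer(TransformerMixin, BaseEstimator):
    """Windowed summary-statistic features, as a scikit-learn transformer.

    ``transform`` maps a list of :class:`GazeRecording` to the conventional
    feature DataFrame: one row per (participant, activity, window), one
    column per channel x statistic.  Invalid samples (VALID = 0) are
    excluded from every statistic by default.

    Parameters
    ----------
    window_s : float
        Window length in seconds.
    channels : sequence of str
        Channels to summarize; defaults to the eight derived-event channels.
    exclude_invalid : bool
        Drop VALID = 0 samples before computing statistics.
    """

    def __init__(
        self,
        window_s: float = DEFAULT_WINDOW_S,
        channels: tuple[str, ...] = CONVENTIONAL_CHANNELS,
        exclude_invalid: bool = True,
    ):
        self.window_s = window_s
        self.channels = channels
        self.exclude_invalid = exclude_invalid

    def fit(self, X: list[GazeRecording], y=None) -> "ConventionalFeaturizer":
        self.feature_names_ = [
            f"{ch}_{st}" for ch in self.channels for st in STATISTICS
        ]
        return self

    def transform(self, X: list[GazeRecording]) -> pd.DataFrame:
        self.fit(X)
        rows = []
        for rec in X:
            for w, window in enumerate(window_signal(rec, self.window_s)):
                if self.exclude_invalid:
                    window = window[window["VALID"] == 1]
                row: dict[str, object] = {
                    "participant_id": rec.participant_id,
                    "activity_label": rec.activity_label,
                    "window_index": w,
                }
                for ch in self.channels:
                    statvals = summarize_window(window[ch])
                    for st in STATISTICS:
                        row[f"{ch}_{st}"] = statvals[st]
                rows.append(row)
        columns = list(KEY_COLUMNS) + self.feature_names_
        return pd.DataFrame(rows, columns=columns)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)


def build_conventional_table(
    recordings: list[GazeRecording],
    window_s: float = DEFAULT_WINDOW_S,
    channels: tuple[str, ...] = CONVENTIONAL_CHANNELS,
    exclude_invalid: bool = True,
) -> FeatureTable:
    """Conventional feature table for a cohort of recordings.

    Row count is the total window count (20 per 60 s task); column count is
    ``7 * len(channels)`` (56 with the default channel set).
    """
    featurizer = ConventionalFeaturizer(
        window_s=window_s, channels=channels, exclude_invalid=exclude_invalid
    )
    values = featurizer.fit_transform(recordings)
    provenance = {
        f"{ch}_{st}": {"kind": "conventional", "channel": ch, "statistic": st}
        for ch in channels
        for st in STATISTICS
    }
    return FeatureTable(values=values, provenance=provenance)
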