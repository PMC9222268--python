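"""Multiscale sample entropy and the complexity index.

Sample entropy SampEn(N, m, r) is -ln(A/B), where B counts pairs of distinct
m-length templates within Chebyshev distance r of each other and A counts
the same for (m+1)-length templates; self-matches are excluded and both
counts run over the first N - m templates.  Multiscale entropy evaluates
SampEn on coarse-grained versions of the signal — non-overlapping block
means of length tau for tau = 1..tau_max — with the tolerance r held fixed
at ``r_factor`` times the standard deviation of the original
(pre-coarse-graining) series.  The complexity index (CI) is the sum of the
defined per-scale entropies.

Template counting (see :mod:`._counting`) is exactly equivalent to
exhaustive O(N^2) enumeration but runs sub-quadratically, which keeps the
9000-sample task-level signals tractable.

Defaults follow the study parameters m = 2, r = 0.15 * SD, tau_max = 10,
with entropies computed for each of the first six IMFs of nine gaze
channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._counting import count_ab_pairs
from .emd import DEFAULT_MAX_IMF, decompose
from .io import GazeRecording
from .tables import KEY_COLUMNS, FeatureTable

#: Channels decomposed and scored for complexity (9 channels x 6 IMFs).
COMPLEXITY_CHANNELS: tuple[str, ...] = (
    "FPOGD", "FPOGX", "FPOGY", "LPCX", "LPCY", "LPD", "RPD", "LPMM", "RPMM",
)

DEFAULT_M = 2
DEFAULT_R_FACTOR = 0.15
DEFAULT_TAU_MAX = 10


@dataclass
class MSEProfile:
    """Sample entropy across scales plus the complexity index for one series."""

    entropy_by_scale: np.ndarray  # NaN where undefined; index 0 is scale 1
    m: int
    r: float
    tau_max: int
    complexity_index: float = field(init=False)
    n_defined_scales: int = field(init=False)

    def __post_init__(self) -> None:
        defined = ~np.isnan(self.entropy_by_scale)
        self.n_defined_scales = int(defined.sum())
        self.complexity_index = (
            float(self.entropy_by_scale[defined].sum()) if self.n_defined_scales else float("nan")
        )


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``.

    Output element j is the mean of input samples (j-1)*tau+1 .. j*tau; the
    output has floor(N/tau) elements and any trailing partial block is
    dropped.  ``tau = 1`` is the identity.
    """
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"scale tau={tau} exceeds series length {x.size}")
    n_blocks = x.size // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int = DEFAULT_M, r: float | None = None) -> float:
    """SampEn(N, m, r) = -ln(A/B) with Chebyshev template matching.

    ``r`` defaults to 0.15 times the sample standard deviation of the
    series.  Returns NaN ("undefined") when either template count is zero or
    the series is too short (N < m + 2).
    """
    x = np.asarray(series, dtype=float)
    if r is None:
        r = DEFAULT_R_FACTOR * float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if r <= 0:
        raise ValueError("tolerance r must be strictly positive")
    n = x.size
    if n < m + 2:
        return float("nan")
    n_templates = n - m
    a, b = count_ab_pairs(x, m, r, n_templates)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(
    series: np.ndarray,
    m: int = DEFAULT_M,
    r_factor: float = DEFAULT_R_FACTOR,
    tau_max: int = DEFAULT_TAU_MAX,
    r: float | None = None,
) -> MSEProfile:
    """Multiscale entropy profile over scales 1..``tau_max``.

    The tolerance is ``r_factor`` times the SD of the original series unless
    an explicit ``r`` is given (used when an IMF inherits the tolerance of
    its raw source channel).  Scales whose entropy is undefined are recorded
    as NaN; the complexity index sums the defined scales.  A warning is
    emitted when the shortest coarse-grained series drops below 10^m points,
    the guideline for reliable match-probability estimates.
    """
    x = np.asarray(series, dtype=float)
    if x.size < tau_max:
        raise ValueError("series shorter than the largest coarse-graining scale")
    if r is None:
        sd = float(np.std(x, ddof=1))
        if sd == 0:
            return MSEProfile(
                entropy_by_scale=np.full(tau_max, np.nan), m=m, r=0.0, tau_max=tau_max
            )
        r = r_factor * sd
    if x.size // tau_max < 10**m:
        warnings.warn(
            f"coarse-grained length {x.size // tau_max} at scale {tau_max} is below "
            f"the 10^m = {10**m} guideline; entropy estimates may be unreliable",
            stacklevel=2,
        )
    entropies = np.array(
        [sample_entropy(coarse_grain(x, tau), m=m, r=r) for tau in range(1, tau_max + 1)]
    )
    return MSEProfile(entropy_by_scale=entropies, m=m, r=r, tau_max=tau_max)


class ComplexityFeaturizer(TransformerMixin, BaseEstimator):
    """EMD + multiscale-entropy features, as a scikit-learn transformer.

    For each recording (one analysis unit per task by default) and each of
    the nine gaze channels, the channel's valid samples are decomposed into
    up to ``max_imf`` IMFs and every IMF is scored with a full MSE profile
    (``tau_max`` per-scale entropies plus the complexity index), the
    tolerance being ``r_factor`` times the SD of the raw channel.  Columns
    are named ``<channel>_imf<i>_scale<tau>`` and ``<channel>_imf<i>_CI``;
    IMFs the decomposition did not reach are reported missing.
    """

    def __init__(
        self,
        channels: tuple[str, ...] = COMPLEXITY_CHANNELS,
        m: int = DEFAULT_M,
        r_factor: float = DEFAULT_R_FACTOR,
        tau_max: int = DEFAULT_TAU_MAX,
        max_imf: int = DEFAULT_MAX_IMF,
        unit: str = "task",
        window_s: float = 3.0,
        exclude_invalid: bool = True,
    ):
        self.channels = channels
        self.m = m
        self.r_factor = r_factor
        self.tau_max = tau_max
        self.max_imf = max_imf
        self.unit = unit
        self.window_s = window_s
        self.exclude_invalid = exclude_invalid

    def fit(self, X: list[GazeRecording], y=None) -> "ComplexityFeaturizer":
        if self.unit not in ("task", "window"):
            raise ValueError("unit must be 'task' or 'window'")
        self.feature_names_ = []
        for ch in self.channels:
            for i in range(1, self.max_imf + 1):
                self.feature_names_.extend(
                    f"{ch}_imf{i}_scale{tau}" for tau in range(1, self.tau_max + 1)
                )
                self.feature_names_.append(f"{ch}_imf{i}_CI")
        return self

    def _unit_frames(self, rec: GazeRecording):
        if self.unit == "task":
            yield 0, rec.data
        else:
            from .features import window_signal

            for w, frame in enumerate(window_signal(rec, self.window_s)):
                yield w, frame

    def _score_unit(self, frame: pd.DataFrame) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.exclude_invalid:
            frame = frame[frame["VALID"] == 1]
        for ch in self.channels:
            x = frame[ch].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
            if x.size < max(10, self.tau_max) or sd == 0:
                imfs = []
                r_channel = 0.0
            else:
                imfs = decompose(x, max_imf=self.max_imf, source_channel=ch).imfs
                r_channel = self.r_factor * sd
            for i in range(1, self.max_imf + 1):
                cols = [f"{ch}_imf{i}_scale{tau}" for tau in range(1, self.tau_max + 1)]
                if i <= len(imfs) and r_channel > 0 and imfs[i - 1].size >= self.tau_max:
                    profile = mse_profile(
                        imfs[i - 1], m=self.m, tau_max=self.tau_max, r=r_channel
                    )
                    for col, val in zip(cols, profile.entropy_by_scale):
                        out[col] = float(val)
                    out[f"{ch}_imf{i}_CI"] = profile.complexity_index
                else:
                    for col in cols:
                        out[col] = float("nan")
                    out[f"{ch}_imf{i}_CI"] = float("nan")
        return out

    def transform(self, X: list[GazeRecording]) -> pd.DataFrame:
        self.fit(X)
        rows = []
        for rec in X:
            for w, frame in self._unit_frames(rec):
                row: dict[str, object] = {
                    "participant_id": rec.participant_id,
                    "activity_label": rec.activity_label,
                    "window_index": w,
                }
                row.update(self._score_unit(frame))
                rows.append(row)
        columns = list(KEY_COLUMNS) + self.feature_names_
        return pd.DataFrame(rows, columns=columns)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)


def build_complexity_table(
    recordings: list[GazeRecording],
    unit: str = "task",
    m: int = DEFAULT_M,
    r_factor: float = DEFAULT_R_FACTOR,
    tau_max: int = DEFAULT_TAU_MAX,
    max_imf: int = DEFAULT_MAX_IMF,
    exclude_invalid: bool = True,
) -> FeatureTable:
    """Complexity feature table: 9 channels x 6 IMFs x (10 scales + CI).

    One row per analysis unit (the whole task by default), 594 feature
    columns with the default grid.
    """
    featurizer = ComplexityFeaturizer(
        m=m, r_factor=r_factor, tau_max=tau_max, max_imf=max_imf,
        unit=unit, exclude_invalid=exclude_invalid,
    )
    values = featurizer.fit_transform(recordings)
    provenance: dict[str, dict] = {}
    for ch in featurizer.channels:
        for i in range(1, max_imf + 1):
            for tau in range(1, tau_max + 1):
                provenance[f"{ch}_imf{i}_scale{tau}"] = {
                    "kind": "complexity", "channel": ch, "imf": i, "scale": tau,
                }
            provenance[f"{ch}_imf{i}_CI"] = {
                "kind": "complexity", "channel": ch, "imf": i, "scale": "CI",
            }
    return FeatureTable(values=values, provenance=provenance)


def ci_view(table: FeatureTable) -> FeatureTable:
    """Restrict a complexity table to its CI columns (the 9 x 6 grid)."""
    ci_cols = [c for c in table.feature_names if c.endswith("_CI")]
    return table.select(ci_cols)
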