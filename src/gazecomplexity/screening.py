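"""Per-feature screening with a two-factor mixed-model ANOVA.

Every feature is tested for a computer-activity effect with activity as the
fixed factor and participant as the random factor.  With a activities and s
participants (every participant observed in every activity, replicates
within cells allowed), the expected-mean-squares rule for one random factor
makes the activity x participant interaction mean square the denominator of
the fixed-effect F test:

    F = MS_activity / MS_interaction,  df = (a - 1), (a - 1)(s - 1)

Features significant at alpha (default 0.05) are retained; significance
tiers *, **, *** correspond to p < 0.05, 0.01, 0.001.  No multiple-testing
correction is applied by default, with Benjamini-Hochberg available as an
option.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .tables import FeatureTable

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
DEFAULT_ALPHA = 0.05
DEFAULT_MAX_MISSING = 0.2


def tier_of(p: float) -> str:
    """Significance tier for one p-value: ***, **, * or ns."""
    if np.isnan(p):
        return "ns"
    for threshold, label in TIER_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


@dataclass
class ScreeningResult:
    """Per-feature F statistics, p-values, tiers and retention flags."""

    stats: pd.DataFrame  # index: feature; columns: F, p_value, df_effect, df_error, tier, retained
    alpha: float
    excluded: list[str] = field(default_factory=list)  # > max_missing fraction missing

    @property
    def retained_features(self) -> list[str]:
        return self.stats.index[self.stats["retained"]].tolist()

    @property
    def n_retained(self) -> int:
        return int(self.stats["retained"].sum())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.stats.to_csv(path, index_label="feature")
        return path


def mixed_anova(
    values: np.ndarray,
    activity_labels: np.ndarray,
    participant_ids: np.ndarray,
) -> tuple[float, float, tuple[int, int]]:
    """Mixed-model ANOVA F test of the activity effect for one feature.

    Requires every (participant, activity) cell to be observed.  Sums of
    squares are computed from the cell means, under which the fixed-effect F
    ratio MS_activity / MS_interaction is identical to the classic balanced
    two-factor decomposition (the per-cell replicate count cancels).

    Returns (F, p, (df_effect, df_error)).  A feature with zero interaction
    mean square (or zero between-activity variance) gets NaN for p.
    """
    frame = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "activity": np.asarray(activity_labels),
            "participant": np.asarray(participant_ids),
        }
    ).dropna(subset=["y"])
    acts = sorted(frame["activity"].unique())
    parts = sorted(frame["participant"].unique())
    a, s = len(acts), len(parts)
    if a < 2 or s < 2:
        raise ValueError("need at least 2 activities and 2 participants")
    cells = frame.groupby(["participant", "activity"], observed=True)["y"].mean()
    for p in parts:
        for act in acts:
            if (p, act) not in cells.index:
                raise ValueError(f"missing cell: participant {p}, activity {act!r}")
    m = cells.unstack("activity").loc[parts, acts].to_numpy()  # s x a
    grand = m.mean()
    act_means = m.mean(axis=0)
    part_means = m.mean(axis=1)
    ss_act = s * float(np.sum((act_means - grand) ** 2))
    resid = m - part_means[:, None] - act_means[None, :] + grand
    ss_int = float(np.sum(resid**2))
    df_effect = a - 1
    df_error = (a - 1) * (s - 1)
    ms_act = ss_act / df_effect
    ms_int = ss_int / df_error
    if ms_int == 0:
        return (0.0 if ms_act == 0 else np.inf, float("nan"), (df_effect, df_error))
    f_stat = ms_act / ms_int
    p_value = float(sstats.f.sf(f_stat, df_effect, df_error))
    return float(f_stat), p_value, (df_effect, df_error)


def _anova_matrix(
    x: np.ndarray, act_codes: np.ndarray, part_codes: np.ndarray, a: int, s: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mixed-model F and p for every column of ``x`` at once.

    NaN cells are handled per feature via per-cell means of the non-missing
    replicates (the unweighted-means analysis).  Columns with an empty cell
    come back NaN.
    """
    n_feat = x.shape[1]
    cell_sum = np.zeros((a * s, n_feat))
    cell_cnt = np.zeros((a * s, n_feat))
    flat = part_codes * a + act_codes
    finite = np.isfinite(x)
    np.add.at(cell_sum, flat, np.where(finite, x, 0.0))
    np.add.at(cell_cnt, flat, finite.astype(float))
    with np.errstate(invalid="ignore"):
        means = (cell_sum / cell_cnt).reshape(s, a, n_feat)
    ok = ~np.isnan(means).any(axis=(0, 1))
    grand = means.mean(axis=(0, 1))
    act_means = means.mean(axis=0)  # a x f
    part_means = means.mean(axis=1)  # s x f
    ss_act = s * np.sum((act_means - grand) ** 2, axis=0)
    resid = means - part_means[:, None, :] - act_means[None, :, :] + grand
    ss_int = np.sum(resid**2, axis=(0, 1))
    df_e, df_r = a - 1, (a - 1) * (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_act / df_e) / (ss_int / df_r)
    f_stat = np.where(ok, f_stat, np.nan)
    p = np.full(n_feat, np.nan)
    finite_f = np.isfinite(f_stat)
    p[finite_f] = sstats.f.sf(f_stat[finite_f], df_e, df_r)
    return f_stat, p


class MixedAnovaScreener(SelectorMixin, BaseEstimator):
    """Feature selector retaining features with a significant activity effect.

    A scikit-learn ``SelectorMixin``: ``fit(X, y, groups=...)`` runs the
    mixed-model ANOVA per column of ``X`` (``y`` = activity labels,
    ``groups`` = participant ids) and ``transform`` keeps the columns whose
    activity-effect p-value is below ``alpha``.  Columns missing in more
    than ``max_missing`` of the rows are excluded outright and listed in
    ``excluded_``.

    Parameters
    ----------
    alpha : float
        Retention threshold on the (raw) p-value.
    max_missing : float
        Maximum tolerated fraction of missing values per feature.
    fdr : bool
        Apply Benjamini-Hochberg correction before thresholding.
    aggregate : {"none", "cell_mean"}
        With ``cell_mean``, replicates are collapsed to one value per
        (participant, activity) cell before testing (identical F by
        construction, provided cells are balanced).
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        max_missing: float = DEFAULT_MAX_MISSING,
        fdr: bool = False,
        aggregate: str = "none",
    ):
        self.alpha = alpha
        self.max_missing = max_missing
        self.fdr = fdr
        self.aggregate = aggregate

    def fit(self, X, y, groups=None) -> "MixedAnovaScreener":
        if groups is None:
            raise ValueError("MixedAnovaScreener requires participant ids via groups=")
        if self.aggregate not in ("none", "cell_mean"):
            raise ValueError("aggregate must be 'none' or 'cell_mean'")
        if isinstance(X, pd.DataFrame):
            names = X.columns.to_numpy(dtype=object)
            x = X.to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
            names = np.array([f"x{i}" for i in range(x.shape[1])], dtype=object)
        y = np.asarray(y)
        groups = np.asarray(groups)
        acts, act_codes = np.unique(y, return_inverse=True)
        parts, part_codes = np.unique(groups, return_inverse=True)
        a, s = len(acts), len(parts)
        if a < 2 or s < 2:
            raise ValueError("need at least 2 activities and 2 participants")
        observed = np.zeros((s, a), dtype=bool)
        observed[part_codes, act_codes] = True
        if not observed.all():
            si, ai = np.argwhere(~observed)[0]
            raise ValueError(f"missing cell: participant {parts[si]}, activity {acts[ai]!r}")
        missing_frac = np.mean(np.isnan(x), axis=0)
        usable = missing_frac <= self.max_missing
        f_stat = np.full(x.shape[1], np.nan)
        p = np.full(x.shape[1], np.nan)
        if usable.any():
            f_stat[usable], p[usable] = _anova_matrix(
                x[:, usable], act_codes, part_codes, a, s
            )
        p_for_threshold = p.copy()
        if self.fdr:
            finite = np.isfinite(p)
            p_for_threshold[finite] = _benjamini_hochberg(p[finite])
        retained = usable & np.isfinite(p_for_threshold) & (p_for_threshold < self.alpha)

        self.n_features_in_ = x.shape[1]
        self.feature_names_in_ = names
        self.df_effect_ = a - 1
        self.df_error_ = (a - 1) * (s - 1)
        self.f_statistic_ = f_stat
        self.p_values_ = p
        self.support_mask_ = retained
        self.excluded_ = names[~usable].tolist()
        self.result_ = ScreeningResult(
            stats=pd.DataFrame(
                {
                    "F": f_stat,
                    "p_value": p,
                    "df_effect": self.df_effect_,
                    "df_error": self.df_error_,
                    "tier": [tier_of(v) for v in p],
                    "retained": retained,
                },
                index=pd.Index(names, name="feature"),
            ),
            alpha=self.alpha,
            excluded=self.excluded_,
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def __sklearn_tags__(self):  # pragma: no cover - sklearn plumbing
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.target_tags.required = True
        return tags


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def screen_features(
    table: FeatureTable,
    alpha: float = DEFAULT_ALPHA,
    max_missing: float = DEFAULT_MAX_MISSING,
    fdr: bool = False,
    aggregate: str = "none",
) -> tuple[ScreeningResult, FeatureTable]:
    """Screen every feature of a table; return the result and filtered table.

    The filtered table keeps all rows but only the retained feature columns.
    """
    values = table.values
    if aggregate == "cell_mean":
        values = (
            values.groupby(["participant_id", "activity_label"], as_index=False)
            .mean(numeric_only=True)
        )
        values["window_index"] = 0
    screener = MixedAnovaScreener(
        alpha=alpha, max_missing=max_missing, fdr=fdr, aggregate=aggregate
    )
    screener.fit(
        values[table.feature_names],
        values["activity_label"],
        groups=values["participant_id"],
    )
    filtered = table.select(screener.result_.retained_features)
    return screener.result_, filtered


def tier_table(result: ScreeningResult, layout: str = "conventional") -> pd.DataFrame:
    """Render a significance grid from a screening result.

    ``conventional`` lays features out as channel rows x statistic columns
    (the 8 x 7 grid); ``complexity_ci`` lays the CI features out as IMF rows
    x channel columns (the 6 x 9 grid).  Cells hold the tier strings.
    """
    tiers = result.stats["tier"]
    rows: dict[str, dict[str, str]] = {}
    if layout == "conventional":
        for feature, tier in tiers.items():
            channel, _, statistic = feature.rpartition("_")
            rows.setdefault(channel, {})[statistic] = tier
    elif layout == "complexity_ci":
        for feature, tier in tiers.items():
            if not feature.endswith("_CI"):
                continue
            channel, _, imf_part = feature[: -len("_CI")].rpartition("_imf")
            rows.setdefault(f"IMF {imf_part}", {})[channel] = tier
    else:
        raise ValueError("layout must be 'conventional' or 'complexity_ci'")
    grid = pd.DataFrame(rows).T
    return grid.sort_index() if layout == "complexity_ci" else grid


def count_significant(grid: pd.DataFrame) -> int:
    """Number of grid cells carrying any significance tier (*, ** or ***)."""
    return int(grid.isin(["*", "**", "***"]).to_numpy().sum())


# Significance pattern reported for the original 150-participant cohort whose
# design this package models (the published summary is the only available
# artifact of that dataset).  Cells: tier or "ns".
_REFERENCE_CONVENTIONAL_GRID = """\
channel,mean,sd,variance,median,max,min,skewness
FPOGD,***,***,ns,***,***,***,**
LPD,***,***,***,***,***,***,ns
LPMM,***,***,***,***,***,***,*
RPD,***,***,***,***,***,***,ns
RPMM,***,***,***,***,***,***,***
BKDUR,***,***,***,***,***,***,***
BKPMIN,ns,ns,ns,ns,ns,ns,ns
SAC_MAG,***,***,ns,***,***,***,***
"""

_REFERENCE_COMPLEXITY_CI_GRID = """\
imf,FPOGD,FPOGX,FPOGY,LPCX,LPCY,LPD,RPD,LPMM,RPMM
IMF 1,***,***,***,ns,***,***,***,***,***
IMF 2,*,***,***,***,***,***,***,***,***
IMF 3,***,***,***,***,***,***,***,***,***
IMF 4,***,***,***,***,***,**,***,ns,***
IMF 5,***,**,ns,***,ns,**,***,***,***
IMF 6,***,ns,ns,ns,***,ns,*,**,ns
"""


def reference_conventional_grid() -> pd.DataFrame:
    """The reported channel x statistic significance grid (45 starred cells)."""
    return pd.read_csv(_stdio.StringIO(_REFERENCE_CONVENTIONAL_GRID), index_col=0)


def reference_complexity_ci_grid() -> pd.DataFrame:
    """The reported IMF x channel CI significance grid."""
    return pd.read_csv(_stdio.StringIO(_REFERENCE_COMPLEXITY_CI_GRID), index_col=0)
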