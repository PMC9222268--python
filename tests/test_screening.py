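"""Mixed-model ANOVA screening: oracle equality, calibration, grids."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazecomplexity import MixedAnovaScreener, mixed_anova, screen_features, tier_table
from gazecomplexity.screening import (
    count_significant,
    reference_complexity_ci_grid,
    reference_conventional_grid,
    tier_of,
)
from gazecomplexity.tables import FeatureTable


def brute_force_mixed_f(values, activities, participants):
    """Explicit sums-of-squares oracle for the balanced two-factor design."""
    df = pd.DataFrame({"y": values, "a": activities, "p": participants})
    acts = sorted(df["a"].unique())
    parts = sorted(df["p"].unique())
    a, s = len(acts), len(parts)
    n = len(df) // (a * s)
    grand = df["y"].mean()
    ya = df.groupby("a")["y"].mean()
    yp = df.groupby("p")["y"].mean()
    yc = df.groupby(["a", "p"])["y"].mean()
    ss_act = n * s * sum((ya[x] - grand) ** 2 for x in acts)
    ss_int = n * sum(
        (yc[(x, q)] - ya[x] - yp[q] + grand) ** 2 for x in acts for q in parts
    )
    return (ss_act / (a - 1)) / (ss_int / ((a - 1) * (s - 1)))


def _design(a, s, reps, rng, effect=0.0):
    activities = np.tile(np.repeat(np.arange(a), reps), s)
    participants = np.repeat(np.arange(s), a * reps)
    y = (
        rng.normal(0, 1, s)[participants]
        + effect * activities
        + rng.normal(0, 1, len(activities))
    )
    return y, activities, participants


class TestMixedAnova:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.integers(2, 4),
        s=st.integers(2, 8),
        reps=st.integers(1, 4),
        seed_=st.integers(0, 10_000),
    )
    def test_f_matches_brute_force_oracle(self, a, s, reps, seed_):
        if a * s * reps > 200:
            return
        rng = np.random.default_rng(seed_)
        y, acts, parts = _design(a, s, reps, rng, effect=0.3)
        f_stat, p, dfs = mixed_anova(y, acts, parts)
        expected = brute_force_mixed_f(y, acts, parts)
        assert f_stat == pytest.approx(expected, rel=1e-10)
        assert dfs == (a - 1, (a - 1) * (s - 1))
        assert 0.0 <= p <= 1.0

    def test_constant_feature_not_retained(self):
        rng = np.random.default_rng(0)
        _, acts, parts = _design(3, 4, 2, rng)
        y = np.full(len(acts), 7.0)
        f_stat, p, _ = mixed_anova(y, acts, parts)
        assert f_stat == 0.0 and np.isnan(p)

    def test_missing_cell_error_names_cell(self):
        y = np.arange(8.0)
        acts = np.array(["r", "w"] * 4)
        parts = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        keep = ~((acts == "w") & (parts == 2))
        with pytest.raises(ValueError, match=r"participant 2.*activity 'w'"):
            mixed_anova(y[keep], acts[keep], parts[keep])

    def test_worked_small_design(self):
        """3 activities x 4 participants x 2 replicates against the oracle."""
        rng = np.random.default_rng(99)
        y, acts, parts = _design(3, 4, 2, rng, effect=0.5)
        f_stat, _, _ = mixed_anova(y, acts, parts)
        assert f_stat == pytest.approx(brute_force_mixed_f(y, acts, parts), rel=1e-10)


def _null_table(n_features, s=20, reps=10, seed_=5):
    rng = np.random.default_rng(seed_)
    y, acts, parts = _design(3, s, reps, rng)
    x = rng.normal(0, 1, (len(acts), n_features)) + rng.normal(0, 1, s)[parts][:, None]
    values = pd.DataFrame(x, columns=[f"f{i}" for i in range(n_features)])
    values["participant_id"] = [f"P{p}" for p in parts]
    values["activity_label"] = np.array(["reading", "watching", "typing"])[acts]
    values["window_index"] = np.tile(np.arange(reps), 3 * s)
    return FeatureTable(values=values)


class TestScreenFeatures:
    def test_null_calibration(self):
        """Null features are retained at ~alpha, p-values uniform."""
        from scipy import stats as sstats

        table = _null_table(2000)
        result, filtered = screen_features(table, alpha=0.05)
        rate = result.n_retained / table.n_features
        assert abs(rate - 0.05) <= 0.015
        ks = sstats.kstest(result.stats["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01
        assert filtered.n_features == result.n_retained
        assert filtered.n_rows == table.n_rows

    def test_strong_effect_retained_at_three_stars(self):
        rng = np.random.default_rng(17)
        table = _null_table(10, s=20, reps=20, seed_=17)
        acts = table.values["activity_label"].to_numpy()
        col = table.values.columns.get_loc("f0")
        table.values.iloc[:, col] += np.where(acts == "typing", 3.0, 0.0)
        result, filtered = screen_features(table)
        assert result.stats.loc["f0", "tier"] == "***"
        assert "f0" in filtered.feature_names

    def test_alpha_one_retains_all_complete_features(self):
        table = _null_table(50)
        result, filtered = screen_features(table, alpha=1.0)
        assert result.n_retained == 50

    def test_retention_monotone_in_effect_size(self):
        rates = []
        for effect in (0.0, 0.3, 0.8):
            rng = np.random.default_rng(23)
            y, acts, parts = _design(3, 12, 5, rng)
            x = rng.normal(0, 1, (len(acts), 60)) + effect * acts[:, None]
            scr = MixedAnovaScreener().fit(x, acts, groups=parts)
            rates.append(scr.support_mask_.mean())
        assert rates[0] <= rates[1] <= rates[2]

    def test_high_missingness_excluded_and_reported(self):
        table = _null_table(5)
        table.values.iloc[: int(0.5 * table.n_rows), table.values.columns.get_loc("f1")] = np.nan
        result, filtered = screen_features(table)
        assert "f1" in result.excluded
        assert "f1" not in filtered.feature_names

    def test_cell_mean_aggregation_matches_raw_f(self):
        """Collapsing balanced replicates to cell means leaves F unchanged."""
        table = _null_table(8, s=6, reps=4, seed_=31)
        raw, _ = screen_features(table, aggregate="none")
        agg, _ = screen_features(table, aggregate="cell_mean")
        np.testing.assert_allclose(
            raw.stats["F"].to_numpy(), agg.stats["F"].to_numpy(), rtol=1e-10
        )

    def test_fdr_option_is_more_conservative(self):
        table = _null_table(500)
        raw, _ = screen_features(table, fdr=False)
        corrected, _ = screen_features(table, fdr=True)
        assert corrected.n_retained <= raw.n_retained

    def test_sklearn_selector_interface(self):
        rng = np.random.default_rng(3)
        y, acts, parts = _design(3, 8, 4, rng)
        x = rng.normal(0, 1, (len(acts), 20))
        x[:, 4] += 2.0 * acts
        scr = MixedAnovaScreener().fit(x, acts, groups=parts)
        kept = scr.transform(x)
        assert kept.shape == (x.shape[0], scr.support_mask_.sum())
        assert scr.get_support()[4]


class TestTierTable:
    def test_tier_thresholds(self):
        assert tier_of(0.2) == "ns"
        assert tier_of(0.04) == "*"
        assert tier_of(0.009) == "**"
        assert tier_of(0.0009) == "***"
        assert tier_of(float("nan")) == "ns"

    def test_all_null_grid_is_ns(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i}" for i in range(6)], 6),
                "activity_label": np.tile(np.repeat(["reading", "watching"], 3), 6),
                "window_index": np.tile(np.arange(3), 12),
                "LPD_mean": rng.normal(size=36),
                "LPD_sd": rng.normal(size=36),
            }
        )
        result, _ = screen_features(FeatureTable(values=values), alpha=1e-6)
        grid = tier_table(result, layout="conventional")
        assert (grid == "ns").all().all()
        assert grid.shape == (1, 2)

    def test_conventional_grid_shape(self, study_tables):
        result, _ = screen_features(study_tables["conventional"])
        grid = tier_table(result, layout="conventional")
        assert grid.shape == (8, 7)

    def test_complexity_ci_grid_shape(self, study_tables):
        result, _ = screen_features(study_tables["complexity"])
        grid = tier_table(result, layout="complexity_ci")
        assert grid.shape == (6, 9)

    def test_reference_grids_star_counts(self):
        """The bundled reference grids carry 45 starred cells each."""
        assert count_significant(reference_conventional_grid()) == 45
        assert count_significant(reference_complexity_ci_grid()) == 45
        assert reference_conventional_grid().shape == (8, 7)
        assert reference_complexity_ci_grid().shape == (6, 9)
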