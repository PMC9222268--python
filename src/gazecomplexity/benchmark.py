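"""Activity-detection benchmark: three classifiers x four feature sets.

The protocol mirrors a repeated-holdout study design: for each model
configuration the rows of a feature table are split 80/20 at random
(stratified by activity), the classifier is fitted on the training part and
scored on the held-out part, and the whole procedure is replicated six
times with different split seeds.  Reported per configuration: accuracy per
replication, mean +/- SD accuracy, and the 3 x 3 confusion matrix expressed
as mean (SD) percentages of ALL test samples, so each replication's nine
cells sum to 100 and the accuracy equals the diagonal sum.

Model architectures: SVM with library defaults (RBF kernel) behind a
standardizer fitted on the training part; decision tree with max depth 5
and min samples per leaf 7; random forest with max depth 5 and 1000 trees.

By default rows are split without regard to participant, mirroring the
emulated study; ``group_by_participant=True`` splits whole participants
instead, preventing the optimistic participant leakage the default incurs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import ACTIVITIES
from .tables import FeatureTable

METHODS = ("SVM", "DT", "RF")
FEATURE_SETS = (
    "conventional_all",
    "conventional_screened",
    "complexity_all",
    "complexity_screened",
)


@dataclass(frozen=True)
class BenchmarkSpec:
    """The study grid: methods x feature sets, split and replication policy."""

    methods: tuple[str, ...] = METHODS
    feature_sets: tuple[str, ...] = FEATURE_SETS
    test_fraction: float = 0.2
    n_replications: int = 6
    base_seed: int = 0
    group_by_participant: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature set(s): {sorted(unknown)}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    @property
    def n_configurations(self) -> int:
        return len(self.methods) * len(self.feature_sets)


@dataclass
class ClassifierReport:
    """Results of one model configuration across replications."""

    method: str
    feature_set: str
    n_features: int
    accuracies: np.ndarray  # percent, one per replication
    confusion_mean: pd.DataFrame  # percent of all test samples
    confusion_sd: pd.DataFrame
    seeds: list[int] = field(default_factory=list)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def summary(self) -> str:
        return (
            f"{self.method} / {self.feature_set} ({self.n_features} features): "
            f"{self.accuracy_mean:.2f} +/- {self.accuracy_sd:.2f} %"
        )


def make_classifier(method: str, seed: int, dt_max_depth: int = 5):
    """Instantiate one of the three benchmark models.

    SVM uses the library's default hyperparameters behind a z-score
    standardizer (fitted on the training split only, via the pipeline); the
    tree models use the declared architectures (depth 5, and for the forest
    1000 trees).
    """
    if method == "SVM":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if method == "DT":
        return DecisionTreeClassifier(
            max_depth=dt_max_depth, min_samples_leaf=7, random_state=seed
        )
    if method == "RF":
        return RandomForestClassifier(
            max_depth=5, n_estimators=1000, random_state=seed, n_jobs=1
        )
    raise ValueError(f"unknown method {method!r}")


def split_train_test(
    table: FeatureTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    group_by_participant: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split of the table rows, stratified by activity.

    With ``group_by_participant`` the split is over participants instead of
    rows (no participant contributes to both parts); stratification then
    applies at the participant level implicitly, since every participant
    performs every activity.
    """
    values = table.values
    counts = values["activity_label"].value_counts()
    if (counts < 5).any():
        raise ValueError("need at least 5 rows per activity to split")
    if group_by_participant:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=seed
        )
        train_idx, test_idx = next(
            splitter.split(values, groups=values["participant_id"])
        )
        return values.iloc[train_idx], values.iloc[test_idx]
    train, test = train_test_split(
        values,
        test_size=test_fraction,
        random_state=seed,
        stratify=values["activity_label"],
    )
    return train, test


def train_eval(
    method: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_columns: list[str],
    seed: int = 0,
    dt_max_depth: int = 5,
) -> tuple[float, pd.DataFrame]:
    """Fit one classifier and evaluate on the held-out part.

    Returns (accuracy in percent, 3 x 3 confusion matrix as percent of all
    test samples; rows = true activity, columns = predicted).  Missing
    feature values are median-imputed with medians fitted on the training
    part.  The nine confusion cells sum to 100 and accuracy equals the
    diagonal sum.
    """
    unseen = set(test["activity_label"]) - set(train["activity_label"])
    if unseen:
        raise ValueError(f"activity label(s) absent from training data: {sorted(unseen)}")
    x_train = train[feature_columns].to_numpy(dtype=float)
    x_test = test[feature_columns].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        medians = np.nanmedian(x_train, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    x_train = np.where(np.isfinite(x_train), x_train, medians)
    x_test = np.where(np.isfinite(x_test), x_test, medians)
    labels = [a for a in ACTIVITIES if a in set(train["activity_label"])]
    model = make_classifier(method, seed, dt_max_depth=dt_max_depth)
    model.fit(x_train, train["activity_label"])
    predictions = model.predict(x_test)
    counts = _sk_confusion(test["activity_label"], predictions, labels=labels)
    percent = counts / counts.sum() * 100.0
    confusion = pd.DataFrame(percent, index=labels, columns=labels)
    accuracy = float(np.trace(percent))
    return accuracy, confusion


def run_benchmark(
    spec: BenchmarkSpec,
    tables: dict[str, FeatureTable],
    dt_max_depth: int = 5,
    screen_sources: dict[str, FeatureTable] | None = None,
    screen_alpha: float = 0.05,
) -> list[ClassifierReport]:
    """Run the full benchmark grid.

    ``tables`` maps feature-set names to their tables; the replication r of
    every configuration uses split seed ``base_seed + r`` so the whole grid
    is reproducible from one base seed.

    By default screened tables are taken as given (the screen-then-split
    order of the emulated protocol, optimistic because held-out rows inform
    the screen).  Passing ``screen_sources`` — a map from a screened set's
    name to its unscreened source table — switches those sets to
    leakage-free screening: each replication splits the source table and
    screens on the training rows only.  That requires every
    participant x activity cell to be represented in the training part, so
    it suits window-level tables; task-level tables (one row per cell)
    generally cannot support it.
    """
    missing = set(spec.feature_sets) - set(tables)
    if missing:
        raise ValueError(f"missing feature table(s): {sorted(missing)}")
    screen_sources = screen_sources or {}
    reports: list[ClassifierReport] = []
    for feature_set in spec.feature_sets:
        source = screen_sources.get(feature_set)
        table = source if source is not None else tables[feature_set]
        for method in spec.methods:
            accuracies = []
            confusions = []
            seeds = []
            n_features_used = tables[feature_set].n_features
            for rep in range(spec.n_replications):
                seed = spec.base_seed + rep
                train, test = split_train_test(
                    table,
                    test_fraction=spec.test_fraction,
                    seed=seed,
                    group_by_participant=spec.group_by_participant,
                )
                if source is not None:
                    columns = _screen_on_train(train, table, screen_alpha)
                    n_features_used = len(columns)
                else:
                    columns = table.feature_names
                accuracy, confusion = train_eval(
                    method, train, test, columns, seed=seed, dt_max_depth=dt_max_depth
                )
                accuracies.append(accuracy)
                confusions.append(confusion)
                seeds.append(seed)
            stack = np.stack([c.to_numpy() for c in confusions])
            labels = confusions[0].index
            reports.append(
                ClassifierReport(
                    method=method,
                    feature_set=feature_set,
                    n_features=n_features_used,
                    accuracies=np.array(accuracies),
                    confusion_mean=pd.DataFrame(stack.mean(0), index=labels, columns=labels),
                    confusion_sd=pd.DataFrame(
                        stack.std(0, ddof=1) if len(confusions) > 1 else np.zeros_like(stack[0]),
                        index=labels,
                        columns=labels,
                    ),
                    seeds=seeds,
                )
            )
    return reports


def _screen_on_train(
    train: pd.DataFrame, source: FeatureTable, alpha: float
) -> list[str]:
    """Feature columns retained by screening the training rows only."""
    from .screening import MixedAnovaScreener

    screener = MixedAnovaScreener(alpha=alpha)
    screener.fit(
        train[source.feature_names],
        train["activity_label"],
        groups=train["participant_id"],
    )
    retained = screener.result_.retained_features
    # an empty screen cannot feed a classifier; keep everything instead
    return retained if retained else source.feature_names


def reports_to_frame(reports: list[ClassifierReport]) -> pd.DataFrame:
    """Comparison table: one row per configuration, mean +/- SD accuracy."""
    return pd.DataFrame(
        {
            "method": [r.method for r in reports],
            "feature_set": [r.feature_set for r in reports],
            "n_features": [r.n_features for r in reports],
            "accuracy_mean": [r.accuracy_mean for r in reports],
            "accuracy_sd": [r.accuracy_sd for r in reports],
        }
    )


def save_reports(reports: list[ClassifierReport], path: str | Path) -> Path:
    """Serialize the benchmark to JSON (accuracies, seeds, confusion cells)."""
    payload = [
        {
            "method": r.method,
            "feature_set": r.feature_set,
            "n_features": r.n_features,
            "accuracies_percent": r.accuracies.tolist(),
            "accuracy_mean": r.accuracy_mean,
            "accuracy_sd": r.accuracy_sd,
            "seeds": r.seeds,
            "confusion_mean_percent": r.confusion_mean.to_dict(),
            "confusion_sd_percent": r.confusion_sd.to_dict(),
        }
        for r in reports
    ]
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
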