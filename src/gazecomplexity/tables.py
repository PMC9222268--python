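"""Feature tables with per-column provenance.

A :class:`FeatureTable` is a pandas DataFrame whose rows are analysis units
(keyed by participant, activity and window index) plus a provenance record
for every feature column: which channel it came from and which statistic, or
which IMF and entropy scale, produced it.  Tables serialize as CSV with a
JSON sidecar holding the provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Row-key columns present in every feature table.
KEY_COLUMNS = ("participant_id", "activity_label", "window_index")


@dataclass
class FeatureTable:
    """Analysis units x named features, with column provenance."""

    values: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in KEY_COLUMNS:
            if key not in self.values.columns:
                raise ValueError(f"feature table lacks key column {key!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes}")
        keys = self.values[list(KEY_COLUMNS)]
        if keys.duplicated().any():
            raise ValueError("duplicate (participant, activity, window) row keys")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.values.columns if c not in KEY_COLUMNS]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def feature_matrix(self) -> pd.DataFrame:
        """The numeric feature block, keys dropped."""
        return self.values[self.feature_names]

    def labels(self) -> pd.Series:
        return self.values["activity_label"]

    def participants(self) -> pd.Series:
        return self.values["participant_id"]

    def select(self, columns: list[str]) -> "FeatureTable":
        """A new table restricted to the given feature columns (rows kept)."""
        keep = list(KEY_COLUMNS) + [c for c in self.feature_names if c in set(columns)]
        return FeatureTable(
            values=self.values[keep].copy(),
            provenance={c: self.provenance[c] for c in keep if c in self.provenance},
        )

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing values."""
        return self.feature_matrix().isna().mean()

    def to_csv(self, path: str | Path) -> Path:
        """Write values as CSV and provenance as a ``.provenance.json`` sidecar."""
        path = Path(path)
        self.values.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        values = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(values=values, provenance=provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.values, other.values)
        except AssertionError:
            return False
        return self.provenance == other.provenance


def concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Stack tables with identical columns; provenance merged."""
    if not tables:
        raise ValueError("no tables to concatenate")
    cols = list(tables[0].values.columns)
    for t in tables[1:]:
        if list(t.values.columns) != cols:
            raise ValueError("tables have mismatching columns")
    provenance: dict[str, dict] = {}
    for t in tables:
        provenance.update(t.provenance)
    values = pd.concat([t.values for t in tables], ignore_index=True)
    return FeatureTable(values=values, provenance=provenance)
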