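"""Two-visit feature tables: the central exchange object of the pipeline.

A :class:`FeatureTable` holds one value per (lesion, visit, feature). Lesions
missing either visit cannot participate in a paired repeatability analysis and
are dropped (with a warning) by :meth:`FeatureTable.paired`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: column names of the long (tidy) on-disk representation
LONG_COLUMNS = ("lesion_id", "visit", "feature_name", "value")


@dataclass
class FeatureTable:
    """Lesions x features over repeated visits.

    Parameters
    ----------
    data : pandas.DataFrame
        Wide form: MultiIndex ``(lesion_id, visit)`` rows, one column per
        feature. Values are floats.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.names != [
            "lesion_id",
            "visit",
        ]:
            raise ValueError("FeatureTable rows must be indexed by (lesion_id, visit)")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate (lesion_id, visit) rows: {dupes}")

    # ------------------------------------------------------------------ basic
    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def visits(self) -> list:
        return sorted(self.data.index.get_level_values("visit").unique())

    @property
    def lesion_ids(self) -> list:
        return sorted(self.data.index.get_level_values("lesion_id").unique())

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    # ---------------------------------------------------------------- pairing
    def paired(self) -> "FeatureTable":
        """Return the complete-case table: lesions present at *every* visit.

        Lesions missing a visit (or with any missing feature value) are
        excluded, mirroring a paired test-retest design.
        """
        visits = self.visits
        counts = self.data.groupby(level="lesion_id").size()
        complete = counts[counts == len(visits)].index
        dropped = sorted(set(self.lesion_ids) - set(complete))
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} lesion(s) without all visits: {dropped[:10]}",
                stacklevel=2,
            )
        sub = self.data.loc[self.data.index.get_level_values("lesion_id").isin(complete)]
        bad = sub.columns[sub.isna().any()].tolist()
        if bad:
            warnings.warn(f"dropping feature(s) with missing values: {bad}", stacklevel=2)
            sub = sub.drop(columns=bad)
        return FeatureTable(sub.sort_index(), dict(self.meta))

    def visit_matrix(self, feature: str) -> np.ndarray:
        """n_lesions x n_visits value matrix for one feature (complete cases)."""
        wide = self.data[feature].unstack("visit").dropna()
        return wide.to_numpy(dtype=float)

    def pooled(self, feature: str) -> np.ndarray:
        """All values of a feature pooled over lesions and visits."""
        return self.data[feature].dropna().to_numpy(dtype=float)

    def with_values(self, feature: str, values: np.ndarray) -> "FeatureTable":
        out = self.data.copy()
        out[feature] = np.asarray(values, dtype=float)
        return FeatureTable(out, dict(self.meta))

    # --------------------------------------------------------------------- IO
    def to_long(self) -> pd.DataFrame:
        long = (
            self.data.stack()
            .rename("value")
            .rename_axis(["lesion_id", "visit", "feature_name"])
            .reset_index()
        )
        return long[list(LONG_COLUMNS)]

    @classmethod
    def from_long(cls, long: pd.DataFrame, meta: dict | None = None) -> "FeatureTable":
        missing = set(LONG_COLUMNS) - set(long.columns)
        if missing:
            raise ValueError(f"long-form table missing columns: {sorted(missing)}")
        dup = long.duplicated(subset=["lesion_id", "visit", "feature_name"])
        if dup.any():
            rows = (long.index[dup] + 2).tolist()[:10]  # 1-based + header line
            raise ValueError(f"duplicate (lesion, visit, feature) entries at lines {rows}")
        wide = long.pivot(index=["lesion_id", "visit"], columns="feature_name", values="value")
        wide.columns.name = None
        return cls(wide.sort_index(), meta or {})

    def write_long(self, path: str | Path, sep: str = ",") -> None:
        self.to_long().to_csv(path, sep=sep, index=False)

    def write_wide(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep)

    @classmethod
    def read_long(cls, path: str | Path, sep: str = ",") -> "FeatureTable":
        try:
            long = pd.read_csv(path, sep=sep)
        except pd.errors.ParserError as exc:  # surface the offending line
            raise ValueError(f"malformed feature table {path}: {exc}") from exc
        return cls.from_long(long, {"source": str(path)})

    @classmethod
    def read_wide(cls, path: str | Path, sep: str = ",") -> "FeatureTable":
        wide = pd.read_csv(path, sep=sep, index_col=["lesion_id", "visit"])
        return cls(wide.sort_index(), {"source": str(path)})


def concat_features(tables: Iterable[FeatureTable]) -> FeatureTable:
    """Join tables column-wise on (lesion_id, visit)."""
    frames = [t.data for t in tables]
    return FeatureTable(pd.concat(frames, axis=1))
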