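"""Domain containers: lesion records and the long-format rating table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DuplicateRatingError, FormatError
from .vocab import DIAGNOSES, FEATURES, LOCATIONS, VOCABULARY, normalize_category

RATING_COLUMNS = ("lesion_id", "rater_id", "feature", "category")


@dataclass(frozen=True)
class LesionRecord:
    """One lymph node: axis measurements (mm) and the ground-truth diagnosis.

    Axes are ordered (``short_axis_mm <= long_axis_mm``); violating records
    are rejected here — ordering of human-entered data is repaired (with a
    warning) at read time, not in the container.
    """

    lesion_id: str
    location: str
    long_axis_mm: float
    short_axis_mm: float
    diagnosis: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise FormatError(
                f"lesion {self.lesion_id!r}: location {self.location!r} "
                f"not in {LOCATIONS}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise FormatError(
                f"lesion {self.lesion_id!r}: diagnosis {self.diagnosis!r} "
                f"not in {DIAGNOSES}"
            )
        if not (self.long_axis_mm > 0 and self.short_axis_mm > 0):
            raise FormatError(
                f"lesion {self.lesion_id!r}: axes must be positive"
            )
        if self.short_axis_mm > self.long_axis_mm:
            raise FormatError(
                f"lesion {self.lesion_id!r}: short axis exceeds long axis"
            )


def long_short_ratio(record: LesionRecord) -> float:
    """Short-to-long axis ratio in (0, 1]; 1.0 is a perfectly round node."""
    return record.short_axis_mm / record.long_axis_mm


def lesions_to_frame(records: Iterable[LesionRecord]) -> pd.DataFrame:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "location": r.location,
            "long_axis_mm": r.long_axis_mm,
            "short_axis_mm": r.short_axis_mm,
            "diagnosis": r.diagnosis,
            "subtype": r.subtype,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lesion_id",
            "location",
            "long_axis_mm",
            "short_axis_mm",
            "diagnosis",
            "subtype",
        ],
    )


class RatingTable:
    """Per-rater categorical feature assessments in long format.

    Keys ``(lesion_id, rater_id, feature)`` are unique; categories are
    validated against the feature vocabularies and canonicalized to lower
    case.  A (lesion, feature) cell is *complete* only when every rater in
    the panel rated it; incomplete cells are excluded from kappa and from
    majority consolidation.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in RATING_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"rating table missing required column(s) {missing}")
        df = frame.loc[:, list(RATING_COLUMNS)].copy()
        df["lesion_id"] = df["lesion_id"].astype(str)
        df["rater_id"] = df["rater_id"].astype(str)
        df["category"] = [
            normalize_category(f, c)
            for f, c in zip(df["feature"], df["category"])
        ]
        df["feature"] = df["feature"].str.strip().str.lower()
        dup = df.duplicated(subset=["lesion_id", "rater_id", "feature"])
        if dup.any():
            keys = df.loc[dup, ["lesion_id", "rater_id", "feature"]]
            listed = [tuple(k) for k in keys.itertuples(index=False)]
            raise DuplicateRatingError(
                f"duplicate (lesion, rater, feature) key(s): {listed}"
            )
        self._frame = df.reset_index(drop=True)
        self._rater_ids = tuple(sorted(df["rater_id"].unique()))

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, str, str]]
    ) -> "RatingTable":
        return cls(pd.DataFrame(list(rows), columns=list(RATING_COLUMNS)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def rater_ids(self) -> tuple[str, ...]:
        return self._rater_ids

    @property
    def n_raters(self) -> int:
        return len(self._rater_ids)

    @property
    def lesion_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._frame["lesion_id"].unique()))

    def __len__(self) -> int:
        return len(self._frame)

    def entries(self) -> Mapping[tuple[str, str, str], str]:
        return {
            (r.lesion_id, r.rater_id, r.feature): r.category
            for r in self._frame.itertuples(index=False)
        }

    def _cell_sizes(self, feature: str) -> pd.Series:
        sub = self._frame[self._frame["feature"] == feature]
        return sub.groupby("lesion_id").size()

    def complete_lesions(self, feature: str) -> tuple[str, ...]:
        """Lesions whose (lesion, feature) cell was rated by the full panel."""
        sizes = self._cell_sizes(feature)
        return tuple(sorted(sizes.index[sizes == self.n_raters]))

    def incomplete_cells(self) -> list[tuple[str, str]]:
        out = []
        for feature in FEATURES:
            sizes = self._cell_sizes(feature)
            out.extend(
                (lid, feature)
                for lid in sorted(sizes.index[sizes < self.n_raters])
            )
        return out

    def counts(self, feature: str) -> tuple[tuple[str, ...], np.ndarray]:
        """Complete-case per-lesion category counts for one feature.

        Returns the lesion ids (sorted) and an ``(n_lesions, n_categories)``
        integer matrix whose columns follow the feature's vocabulary order.
        """
        vocab = VOCABULARY[feature]
        lesions = self.complete_lesions(feature)
        sub = self._frame[
            (self._frame["feature"] == feature)
            & self._frame["lesion_id"].isin(lesions)
        ]
        table = (
            sub.groupby(["lesion_id", "category"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=list(lesions), columns=list(vocab), fill_value=0)
        )
        return lesions, table.to_numpy(dtype=np.int64)

    def iter_cells(self) -> Iterator[tuple[str, str, pd.Series]]:
        for (lid, feature), grp in self._frame.groupby(["lesion_id", "feature"]):
            yield lid, feature, grp["category"]
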