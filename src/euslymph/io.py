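"""Readers/writers for the lesion table, rating table and JSON reports.

CSV layouts
-----------
``lesions.csv``: header ``lesion_id,location,long_axis_mm,short_axis_mm,
diagnosis,subtype``.  ``ratings.csv``: long format with header
``lesion_id,rater_id,feature,category``.  Reals are written with ``repr``
so a write/read round trip reproduces them to full precision.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable

from .errors import FormatError
from .model import LesionRecord, RatingTable

logger = logging.getLogger(__name__)

LESION_COLUMNS = (
    "lesion_id",
    "location",
    "long_axis_mm",
    "short_axis_mm",
    "diagnosis",
    "subtype",
)

SCHEMA_VERSION = "1.0"


def read_lesion_table(path: str | Path) -> list[LesionRecord]:
    """Read ``lesions.csv``; axes are ordered (swap + warn) at this boundary."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        for col in LESION_COLUMNS[:-1]:  # subtype optional
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        records: list[LesionRecord] = []
        for row in reader:
            lid = (row["lesion_id"] or "").strip()
            if not lid:
                raise FormatError(f"{path}: row with empty lesion_id")
            try:
                long_mm = float(row["long_axis_mm"])
                short_mm = float(row["short_axis_mm"])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: lesion {lid!r}: non-numeric axis value "
                    f"({row['long_axis_mm']!r}, {row['short_axis_mm']!r})"
                ) from exc
            if short_mm > long_mm:
                logger.warning(
                    "lesion %r: axes out of order (long=%g < short=%g); swapped",
                    lid,
                    long_mm,
                    short_mm,
                )
                long_mm, short_mm = short_mm, long_mm
            subtype = (row.get("subtype") or "").strip() or None
            records.append(
                LesionRecord(
                    lesion_id=lid,
                    location=(row["location"] or "").strip().lower(),
                    long_axis_mm=long_mm,
                    short_axis_mm=short_mm,
                    diagnosis=(row["diagnosis"] or "").strip().lower(),
                    subtype=subtype,
                )
            )
    return records


def write_lesion_table(records: Iterable[LesionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LESION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.lesion_id,
                    r.location,
                    repr(float(r.long_axis_mm)),
                    repr(float(r.short_axis_mm)),
                    r.diagnosis,
                    r.subtype or "",
                ]
            )


def read_rating_table(path: str | Path) -> RatingTable:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        for col in ("lesion_id", "rater_id", "feature", "category"):
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        rows = [
            (row["lesion_id"], row["rater_id"], row["feature"], row["category"])
            for row in reader
        ]
    table = RatingTable.from_rows(rows)
    incomplete = table.incomplete_cells()
    if incomplete:
        logger.warning(
            "%d (lesion, feature) cell(s) lack a full panel and are "
            "excluded from agreement/consensus: %s",
            len(incomplete),
            incomplete[:10],
        )
    return table


def write_rating_table(table: RatingTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lesion_id", "rater_id", "feature", "category"])
        for row in table.frame.itertuples(index=False):
            writer.writerow([row.lesion_id, row.rater_id, row.feature, row.category])


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, fixed separators, trailing newline)."""
    path = Path(path)
    path.write_text(
        json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
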