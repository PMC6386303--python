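"""Cutoff derivation, criteria definitions, lesion scoring and group stats.

The proposed 3-item malignancy score counts: long axis > 20 mm, short axis
> 10 mm, and consensus round-or-oval shape with long-short ratio > 0.5.
The historical 4-item criteria count: long axis > 10 mm, consensus round
shape, consensus clear (sharp) border, consensus dark (hypoechoic)
echogenicity.  Cutoffs are derived by maximizing Youden's J over midpoints
between consecutive observed values and then rounded to a clinical grid
(default 5 mm: 19.7 -> 20, 10.7 -> 10).  All size inequalities are strict
(">") by default, matching the count table that generates the published
percentages; strictness is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import AgreementResult, ConsensusFeatures
from .errors import ConfigError, DegenerateInputError
from .model import LesionRecord, long_short_ratio
from .vocab import FEATURES, MALIGNANT_CATEGORY, VOCABULARY


def _positive_mask(labels, positive) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == positive


# ---------------------------------------------------------------------------
# cutoffs


@dataclass(frozen=True)
class CutoffResult:
    """A Youden-optimal axis cutoff and its clinically rounded version."""

    axis: str
    youden_cutoff_mm: float
    rounded_cutoff_mm: float
    youden_j: float
    sens_at_youden: float
    spec_at_youden: float
    sens_at_rounded: float
    spec_at_rounded: float


def clinical_round(cutoff_mm: float, grid_mm: float = 5.0) -> float:
    """Nearest grid multiple, half rounding up (19.7 -> 20, 12.5 -> 15)."""
    if grid_mm <= 0:
        raise ConfigError("grid_mm must be > 0")
    if cutoff_mm <= 0:
        raise ConfigError("cutoff must be > 0")
    return math.floor(cutoff_mm / grid_mm + 0.5) * grid_mm


def youden_cutoff(
    values: Sequence[float],
    labels: Sequence,
    axis: str = "long",
    grid_mm: float = 5.0,
    positive: str = "malignant",
) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive distinct
    observed values; a lesion is called positive when its value is
    strictly above the threshold.  Ties in J break toward the higher
    cutoff (higher specificity).  Equivalent to exhaustive search.
    """
    v = np.asarray(values, dtype=float)
    y = _positive_mask(labels, positive)
    if y.all() or not y.any():
        raise DegenerateInputError("both diagnosis classes must be present")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise DegenerateInputError(
            "all values identical: no discriminating threshold"
        )
    cands = (distinct[:-1] + distinct[1:]) / 2.0
    pos, neg = v[y], v[~y]
    sens = (pos[:, None] > cands).mean(axis=0)
    spec = (neg[:, None] <= cands).mean(axis=0)
    J = sens + spec - 1.0
    best = int(np.flatnonzero(J >= J.max() - 1e-12).max())
    cutoff = float(cands[best])
    rounded = clinical_round(cutoff, grid_mm)
    return CutoffResult(
        axis=axis,
        youden_cutoff_mm=cutoff,
        rounded_cutoff_mm=rounded,
        youden_j=float(J[best]),
        sens_at_youden=float(sens[best]),
        spec_at_youden=float(spec[best]),
        sens_at_rounded=float((pos > rounded).mean()),
        spec_at_rounded=float((neg <= rounded).mean()),
    )


def select_features(
    agreements: Iterable[AgreementResult], threshold: float = 0.4
) -> list[str]:
    """Features whose kappa is strictly above the agreement threshold."""
    return [a.feature for a in agreements if a.kappa > threshold]


# ---------------------------------------------------------------------------
# criteria definitions


@dataclass(frozen=True)
class AxisItem:
    """Size item: axis measurement above a cutoff."""

    axis: str  # "long" | "short"
    cutoff_mm: float
    strict: bool = True

    @property
    def name(self) -> str:
        op = ">" if self.strict else ">="
        return f"{self.axis}_axis{op}{self.cutoff_mm:g}mm"

    def evaluate(self, row: Mapping) -> bool:
        value = float(row[f"{self.axis}_axis_mm"])
        return value > self.cutoff_mm if self.strict else value >= self.cutoff_mm

    def to_dict(self) -> dict:
        return {
            "type": "axis",
            "axis": self.axis,
            "cutoff_mm": self.cutoff_mm,
            "strict": self.strict,
        }


@dataclass(frozen=True)
class ShapeRatioItem:
    """Shape item: consensus round-or-oval with long-short ratio > 0.5."""

    ratio_threshold: float = 0.5
    strict: bool = True

    @property
    def name(self) -> str:
        op = ">" if self.strict else ">="
        return f"round_or_oval&ratio{op}{self.ratio_threshold:g}"

    def evaluate(self, row: Mapping) -> bool:
        ro = row["shape_round_or_oval"]
        ratio = float(row["ratio"])
        shape_ok = bool(ro) if ro is not None and ro == ro else False
        ratio_ok = (
            ratio > self.ratio_threshold
            if self.strict
            else ratio >= self.ratio_threshold
        )
        return shape_ok and ratio_ok

    def to_dict(self) -> dict:
        return {
            "type": "shape_ratio",
            "ratio_threshold": self.ratio_threshold,
            "strict": self.strict,
        }


@dataclass(frozen=True)
class ConsensusCategoryItem:
    """Consensus feature equals a category (e.g. border == clear)."""

    feature: str
    category: str

    @property
    def name(self) -> str:
        return f"{self.feature}={self.category}"

    def evaluate(self, row: Mapping) -> bool:
        return row.get(self.feature) == self.category

    def to_dict(self) -> dict:
        return {
            "type": "consensus_category",
            "feature": self.feature,
            "category": self.category,
        }


CriterionItem = AxisItem | ShapeRatioItem | ConsensusCategoryItem


@dataclass(frozen=True)
class CriteriaDefinition:
    """A named, ordered set of binary predicates over a lesion + consensus."""

    name: str
    items: tuple[CriterionItem, ...]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def to_dict(self) -> dict:
        return {"name": self.name, "items": [i.to_dict() for i in self.items]}

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaDefinition":
        items = []
        for spec in d["items"]:
            kind = spec["type"]
            if kind == "axis":
                items.append(
                    AxisItem(spec["axis"], spec["cutoff_mm"], spec["strict"])
                )
            elif kind == "shape_ratio":
                items.append(
                    ShapeRatioItem(spec["ratio_threshold"], spec["strict"])
                )
            elif kind == "consensus_category":
                items.append(
                    ConsensusCategoryItem(spec["feature"], spec["category"])
                )
            else:
                raise ConfigError(f"unknown criterion item type {kind!r}")
        return cls(name=d["name"], items=tuple(items))


def new_criteria(
    long_cutoff_mm: float = 20.0,
    short_cutoff_mm: float = 10.0,
    ratio_threshold: float = 0.5,
    strict: bool = True,
    extra_features: Sequence[str] = (),
) -> CriteriaDefinition:
    """The proposed 3-item malignancy criteria (size + shape).

    ``extra_features`` appends consensus-category items for any further
    agreement-selected binary features (empty in the development study,
    where only shape cleared the kappa threshold).
    """
    items: list[CriterionItem] = [
        AxisItem("long", long_cutoff_mm, strict),
        AxisItem("short", short_cutoff_mm, strict),
        ShapeRatioItem(ratio_threshold, strict),
    ]
    for f in extra_features:
        items.append(ConsensusCategoryItem(f, MALIGNANT_CATEGORY[f]))
    return CriteriaDefinition(name="new", items=tuple(items))


def old_criteria(strict: bool = True) -> CriteriaDefinition:
    """The historical 4-item criteria (size, round, sharp border, hypoechoic)."""
    return CriteriaDefinition(
        name="old",
        items=(
            AxisItem("long", 10.0, strict),
            ConsensusCategoryItem("shape", "round"),
            ConsensusCategoryItem("border", "clear"),
            ConsensusCategoryItem("echogenicity", "dark"),
        ),
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class ScoreResult:
    """Per-lesion criteria score: count of satisfied items."""

    lesion_id: str
    criteria_name: str
    score: int
    items: dict[str, bool]


def build_feature_frame(
    lesions: Sequence[LesionRecord], consensus: Sequence[ConsensusFeatures]
) -> pd.DataFrame:
    """Join measurements and consensus features, indexed by lesion_id."""
    cons = {c.lesion_id: c for c in consensus}
    rows = []
    for r in lesions:
        c = cons.get(r.lesion_id)
        row = {
            "lesion_id": r.lesion_id,
            "location": r.location,
            "diagnosis": r.diagnosis,
            "long_axis_mm": r.long_axis_mm,
            "short_axis_mm": r.short_axis_mm,
            "ratio": long_short_ratio(r),
            "shape_round_or_oval": c.shape_round_or_oval if c else None,
        }
        for f in FEATURES:
            row[f] = c.categories.get(f) if c else None
        rows.append(row)
    return pd.DataFrame(rows).set_index("lesion_id", drop=False)


def score_criteria(
    lesion: LesionRecord,
    consensus: ConsensusFeatures,
    definition: CriteriaDefinition,
) -> ScoreResult:
    """Evaluate every item of a criteria definition for one lesion."""
    row = {
        "long_axis_mm": lesion.long_axis_mm,
        "short_axis_mm": lesion.short_axis_mm,
        "ratio": long_short_ratio(lesion),
        "shape_round_or_oval": consensus.shape_round_or_oval,
        **consensus.categories,
    }
    flags = {item.name: bool(item.evaluate(row)) for item in definition.items}
    return ScoreResult(
        lesion_id=lesion.lesion_id,
        criteria_name=definition.name,
        score=sum(flags.values()),
        items=flags,
    )


def score_table(
    frame: pd.DataFrame, definition: CriteriaDefinition
) -> pd.DataFrame:
    """Vectorized scoring of a joined feature frame; adds per-item columns."""
    out = pd.DataFrame(index=frame.index)
    for item in definition.items:
        out[item.name] = [
            bool(item.evaluate(row)) for _, row in frame.iterrows()
        ]
    out["score"] = out.sum(axis=1).astype(int)
    return out


# ---------------------------------------------------------------------------
# group-comparison statistics


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration for small tie-free samples (both n <= 10), otherwise
    the normal approximation with mid-ranks, tie correction and continuity
    correction.  Returns (rank-sum of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    W = float(ranks[: x.size].sum())
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if max(x.size, y.size) <= 10 and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return W, float(res.pvalue)


def assoc_test_2x2(table: Sequence[Sequence[int]]) -> tuple[float, str]:
    """Association test for a 2x2 table: Fisher's exact when any expected
    count is below 5, else Pearson chi-square without continuity correction.

    Returns (two-sided p, test name).  A zero margin is degenerate: p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise DegenerateInputError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(np.int64)
        if (t < 0).any():
            raise DegenerateInputError("counts must be non-negative integers")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return 1.0, "degenerate"
    expected = np.outer(rows, cols) / t.sum()
    if (expected < 5).any():
        return float(stats.fisher_exact(t)[1]), "fisher"
    res = stats.chi2_contingency(t, correction=False)
    return float(res.pvalue), "chi-square"


def group_comparison(frame: pd.DataFrame) -> list[dict]:
    """Published-style class comparison of sizes, indicators and shapes.

    ``frame`` is a joined feature frame (see :func:`build_feature_frame`)
    with a ``diagnosis`` column.  Continuous rows report mean +/- SD per
    class with the rank-sum p; indicator rows report counts per class with
    the chi-square/Fisher p and which test fired.
    """
    mal = frame[frame["diagnosis"] == "malignant"]
    ben = frame[frame["diagnosis"] == "benign"]
    if len(mal) == 0 or len(ben) == 0:
        raise DegenerateInputError("both diagnosis classes must be present")
    rows: list[dict] = []
    for label, col in [
        ("long_axis_mm", "long_axis_mm"),
        ("short_axis_mm", "short_axis_mm"),
        ("long_short_ratio", "ratio"),
    ]:
        _, p = wilcoxon_rank_sum(mal[col], ben[col])
        rows.append(
            {
                "variable": label,
                "kind": "continuous",
                "malignant_mean": float(mal[col].mean()),
                "malignant_sd": float(mal[col].std(ddof=1)),
                "benign_mean": float(ben[col].mean()),
                "benign_sd": float(ben[col].std(ddof=1)),
                "p": p,
                "test": "wilcoxon-rank-sum",
            }
        )

    def indicator_row(label: str, mal_flags, ben_flags) -> dict:
        a, b = int(np.sum(mal_flags)), int(np.sum(ben_flags))
        table = [[a, len(mal) - a], [b, len(ben) - b]]
        p, used = assoc_test_2x2(table)
        return {
            "variable": label,
            "kind": "indicator",
            "malignant_count": a,
            "malignant_pct": 100.0 * a / len(mal),
            "benign_count": b,
            "benign_pct": 100.0 * b / len(ben),
            "p": p,
            "test": used,
        }

    rows.append(
        indicator_row(
            "location_mediastinal",
            mal["location"] == "mediastinal",
            ben["location"] == "mediastinal",
        )
    )
    rows.append(indicator_row("ratio>0.5", mal["ratio"] > 0.5, ben["ratio"] > 0.5))
    for cut, lab in [(10.0, "long_axis>10mm"), (20.0, "long_axis>20mm")]:
        rows.append(
            indicator_row(lab, mal["long_axis_mm"] > cut, ben["long_axis_mm"] > cut)
        )
    rows.append(
        indicator_row(
            "short_axis>10mm", mal["short_axis_mm"] > 10, ben["short_axis_mm"] > 10
        )
    )
    for cat in VOCABULARY["shape"]:
        rows.append(
            indicator_row(f"shape={cat}", mal["shape"] == cat, ben["shape"] == cat)
        )
    ro_mal = mal["shape_round_or_oval"].fillna(False).astype(bool) & (mal["ratio"] > 0.5)
    ro_ben = ben["shape_round_or_oval"].fillna(False).astype(bool) & (ben["ratio"] > 0.5)
    rows.append(indicator_row("round_or_oval&ratio>0.5", ro_mal, ro_ben))
    return rows
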