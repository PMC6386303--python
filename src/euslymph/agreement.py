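"""Multi-rater agreement and majority-vote consensus.

Fleiss' fixed-marginal multi-rater kappa is computed per feature from the
complete-case per-lesion category-count matrix::

    P_i  = (sum_j n_ij^2 - R) / (R (R - 1))      per-lesion agreement
    Pe   = sum_j p_j^2,   p_j pooled marginals    chance agreement
    kappa = (mean_i P_i - Pe) / (1 - Pe)

A single observed category makes ``Pe = 1`` and kappa undefined; this is
an explicit error state (:class:`~euslymph.errors.UndefinedKappaError`),
never silently 0/1/NaN.  Confidence intervals are percentile bootstrap
over lesions (raters kept intact).  Consensus assigns the category with
>= ``min_votes`` of the panel's votes; for criteria use, shape is first
binarized per rater into round-or-oval vs other and then majority-voted,
which is decision-complete for an odd panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateInputError, UndefinedKappaError
from .model import RatingTable
from .vocab import FEATURES, INDETERMINATE, ROUND_OR_OVAL, VOCABULARY

_LANDIS_SCALE = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
)


def landis_koch(kappa: float) -> str:
    """Verbal agreement band for a kappa in [-1, 1].

    Bands: <0 less than chance; (0, .20] slight; (.20, .40] fair;
    (.40, .60] moderate; (.60, .80] substantial; >.80 almost perfect.
    """
    k = float(kappa)
    if not -1.0 - 1e-12 <= k <= 1.0 + 1e-12:
        raise ValueError(f"kappa {k} outside [-1, 1]")
    if k < 0.0:
        return "less than chance"
    for upper, label in _LANDIS_SCALE:
        if k <= upper:
            return label
    return "almost perfect"


def _validated_counts(counts: np.ndarray) -> tuple[np.ndarray, int]:
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise DegenerateInputError("counts must be a 2-D (lesion x category) matrix")
    if counts.shape[0] < 2:
        raise DegenerateInputError("kappa requires at least 2 lesions")
    if (counts < 0).any():
        raise DegenerateInputError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    R = int(row_sums[0])
    if R < 2:
        raise DegenerateInputError("kappa requires at least 2 raters")
    if not (row_sums == R).all():
        raise DegenerateInputError(
            "every lesion must have the same number of ratings (complete case)"
        )
    return counts.astype(np.float64), R


def _per_lesion_agreement(counts: np.ndarray, R: int) -> np.ndarray:
    return ((counts**2).sum(axis=1) - R) / (R * (R - 1))


def fleiss_kappa(counts: np.ndarray) -> float:
    """Fleiss' multi-rater kappa from a per-lesion category-count matrix."""
    counts, R = _validated_counts(counts)
    n = counts.shape[0]
    p = counts.sum(axis=0) / (n * R)
    pe = float((p**2).sum())
    if 1.0 - pe < 1e-12:
        raise UndefinedKappaError(
            "all ratings fall in a single category; chance agreement is 1"
        )
    pbar = float(_per_lesion_agreement(counts, R).mean())
    return (pbar - pe) / (1.0 - pe)


def fleiss_kappa_per_category(counts: np.ndarray) -> dict[int, float]:
    """Category-wise kappas (supplementary output for multi-category features).

    ``kappa_j = 1 - sum_i n_ij (R - n_ij) / (n R (R-1) p_j (1 - p_j))``;
    categories never used (or always used) are omitted.
    """
    counts, R = _validated_counts(counts)
    n = counts.shape[0]
    p = counts.sum(axis=0) / (n * R)
    out: dict[int, float] = {}
    for j, pj in enumerate(p):
        q = pj * (1.0 - pj)
        if q < 1e-12:
            continue
        num = float((counts[:, j] * (R - counts[:, j])).sum())
        out[j] = 1.0 - num / (n * R * (R - 1) * q)
    return out


def kappa_bootstrap_ci(
    counts: np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    max_redraw_rounds: int = 10,
) -> tuple[float, float]:
    """Percentile bootstrap CI for Fleiss kappa, resampling lesions.

    Raters are kept intact within each resampled lesion.  Resamples with
    undefined kappa (all ratings in one category) are redrawn up to
    ``max_redraw_rounds`` passes; any that remain are dropped with a
    warning.  Reproducible from ``seed``.
    """
    if B < 200:
        raise ConfigError("B must be >= 200")
    if not 0.0 < level < 1.0:
        raise ConfigError("level must be in (0, 1)")
    counts, R = _validated_counts(counts)
    n = counts.shape[0]
    if n < 5:
        raise ConfigError("bootstrap CI requires at least 5 complete-case lesions")
    fleiss_kappa(counts)  # observed kappa must itself be defined

    rng = np.random.default_rng(seed)
    P_i = _per_lesion_agreement(counts, R)

    def kappas_for(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pbar = P_i[idx].mean(axis=1)
        marg = counts[idx].sum(axis=1) / (n * R)
        pe = (marg**2).sum(axis=1)
        defined = 1.0 - pe >= 1e-12
        kap = np.full(idx.shape[0], np.nan)
        kap[defined] = (pbar[defined] - pe[defined]) / (1.0 - pe[defined])
        return kap, defined

    idx = rng.integers(0, n, size=(B, n))
    kappas, defined = kappas_for(idx)
    rounds = 0
    while not defined.all() and rounds < max_redraw_rounds:
        bad = np.flatnonzero(~defined)
        k_new, d_new = kappas_for(rng.integers(0, n, size=(bad.size, n)))
        kappas[bad] = k_new
        defined[bad] = d_new
        rounds += 1
    if not defined.all():
        warnings.warn(
            f"{int((~defined).sum())} bootstrap resample(s) had undefined "
            "kappa after redraws and were dropped",
            stacklevel=2,
        )
        kappas = kappas[defined]
    alpha = 1.0 - level
    lo, hi = np.quantile(kappas, [alpha / 2, 1.0 - alpha / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class AgreementResult:
    """Per-feature agreement: kappa, bootstrap CI and Landis-Koch band."""

    feature: str
    kappa: float
    ci_low: float
    ci_high: float
    landis_label: str
    n_lesions_used: int
    per_category: dict[str, float] | None = None


def feature_agreement(
    ratings: RatingTable,
    features: tuple[str, ...] | None = None,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> list[AgreementResult]:
    """Kappa + bootstrap CI + verbal band for each feature.

    Complete-case lesions only.  Per-feature bootstrap seeds are spawned
    deterministically from ``seed``.  Shape additionally reports
    per-category kappas.
    """
    features = tuple(features) if features is not None else FEATURES
    child_seeds = np.random.SeedSequence(seed).generate_state(len(features))
    results = []
    for f, s in zip(features, child_seeds):
        lesions, counts = ratings.counts(f)
        kappa = fleiss_kappa(counts)
        lo, hi = kappa_bootstrap_ci(counts, B=B, level=level, seed=int(s) & 0x7FFFFFFF)
        per_cat = None
        if len(VOCABULARY[f]) > 2:
            vocab = VOCABULARY[f]
            per_cat = {
                vocab[j]: k for j, k in fleiss_kappa_per_category(counts).items()
            }
        results.append(
            AgreementResult(
                feature=f,
                kappa=float(kappa),
                ci_low=lo,
                ci_high=hi,
                landis_label=landis_koch(kappa),
                n_lesions_used=len(lesions),
                per_category=per_cat,
            )
        )
    return results


@dataclass(frozen=True)
class ConsensusFeatures:
    """Per-lesion consensus categories and vote counts.

    ``categories[feature]`` is the category with >= ``min_votes`` votes, or
    ``"indeterminate"`` when none reaches it (possible only for the 4-way
    shape).  ``shape_round_or_oval`` is the binarize-then-vote shape
    decision the criteria consume; ``None`` when the shape cell is
    incomplete.
    """

    lesion_id: str
    categories: dict[str, str] = field(default_factory=dict)
    votes: dict[str, dict[str, int]] = field(default_factory=dict)
    shape_round_or_oval: bool | None = None


def consolidate_majority(
    ratings: RatingTable, min_votes: int = 3
) -> list[ConsensusFeatures]:
    """Majority-vote consensus per (lesion, feature) over complete cells."""
    R = ratings.n_raters
    if min_votes > R:
        raise ConfigError(f"min_votes={min_votes} exceeds panel size {R}")
    categories: dict[str, dict[str, str]] = {}
    votes: dict[str, dict[str, dict[str, int]]] = {}
    shape_ro: dict[str, bool] = {}

    for f in FEATURES:
        vocab = VOCABULARY[f]
        lesions, counts = ratings.counts(f)
        for lid, row in zip(lesions, counts):
            vote_map = {c: int(k) for c, k in zip(vocab, row) if k > 0}
            votes.setdefault(lid, {})[f] = vote_map
            winners = [c for c, k in vote_map.items() if k >= min_votes]
            categories.setdefault(lid, {})[f] = (
                winners[0] if winners else INDETERMINATE
            )
            if f == "shape":
                ro = sum(vote_map.get(c, 0) for c in ROUND_OR_OVAL)
                shape_ro[lid] = ro >= min_votes

    all_lesions = sorted(set(categories) | set(ratings.lesion_ids))
    return [
        ConsensusFeatures(
            lesion_id=lid,
            categories=categories.get(lid, {}),
            votes=votes.get(lid, {}),
            shape_round_or_oval=shape_ro.get(lid),
        )
        for lid in all_lesions
    ]
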