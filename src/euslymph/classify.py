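"""scikit-learn estimator wrapping criteria derivation and scoring.

``fit`` learns the size cutoffs by Youden maximization on the training
lesions (then rounds them to the clinical grid) and gates the shape item
on the agreement screen; ``decision_function`` returns the per-lesion
count of satisfied items and ``predict`` thresholds that count.  A fixed
:class:`~euslymph.criteria.CriteriaDefinition` (e.g. the historical
criteria) can be supplied instead of deriving one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .criteria import (
    CriteriaDefinition,
    new_criteria,
    score_table,
    select_features,
    youden_cutoff,
)


class EusCriteriaClassifier(ClassifierMixin, BaseEstimator):
    """Count-of-items malignancy classifier over lesion + consensus features.

    Parameters
    ----------
    criteria : "derive" or CriteriaDefinition
        ``"derive"`` learns size cutoffs from the training data and builds
        the 3-item criteria; a definition applies fixed criteria.
    min_positive : int
        Minimum number of satisfied items to call a lesion malignant.
    kappa_threshold : float
        Agreement threshold for feature selection when ``agreements`` is
        given (features with kappa strictly above it enter the criteria).
    grid_mm : float
        Clinical rounding grid for derived cutoffs.
    strict : bool
        Use strict ``>`` at size/ratio thresholds.
    agreements : sequence of AgreementResult or None
        Agreement screen for feature selection; ``None`` admits the shape
        item unconditionally (the development study's outcome).

    Attributes
    ----------
    criteria_ : CriteriaDefinition
        The applied criteria after fitting.
    cutoffs_ : dict or None
        Youden cutoff results per axis when criteria were derived.
    classes_ : ndarray
        The two class labels; the malignant-like class is positive.
    """

    def __init__(
        self,
        criteria="derive",
        min_positive: int = 2,
        kappa_threshold: float = 0.4,
        grid_mm: float = 5.0,
        strict: bool = True,
        agreements=None,
    ):
        self.criteria = criteria
        self.min_positive = min_positive
        self.kappa_threshold = kappa_threshold
        self.grid_mm = grid_mm
        self.strict = strict
        self.agreements = agreements

    def _validate_frame(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise ValueError(
                "X must be a feature DataFrame (see build_feature_frame)"
            )
        return X

    def _positive_label(self, classes: np.ndarray):
        if "malignant" in classes:
            return "malignant"
        return classes[-1]  # sorted; 1 for 0/1, True for bool

    def fit(self, X, y):
        X = self._validate_frame(X)
        y = np.asarray(y)
        if y.shape[0] != len(X):
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] != 2:
            raise ValueError("exactly two classes required")
        pos = self._positive_label(self.classes_)
        y_bool = y == pos

        if isinstance(self.criteria, CriteriaDefinition):
            self.criteria_ = self.criteria
            self.cutoffs_ = None
        elif self.criteria == "derive":
            for col in ("long_axis_mm", "short_axis_mm"):
                if col not in X.columns:
                    raise ValueError(f"X lacks required column {col!r}")
            long_res = youden_cutoff(
                X["long_axis_mm"], y_bool, axis="long",
                grid_mm=self.grid_mm, positive=True,
            )
            short_res = youden_cutoff(
                X["short_axis_mm"], y_bool, axis="short",
                grid_mm=self.grid_mm, positive=True,
            )
            if self.agreements is not None:
                selected = select_features(self.agreements, self.kappa_threshold)
            else:
                selected = ["shape"]
            self.criteria_ = new_criteria(
                long_cutoff_mm=long_res.rounded_cutoff_mm,
                short_cutoff_mm=short_res.rounded_cutoff_mm,
                strict=self.strict,
                extra_features=[f for f in selected if f != "shape"],
            )
            if "shape" not in selected:
                self.criteria_ = CriteriaDefinition(
                    name="new", items=self.criteria_.items[:2]
                )
            self.cutoffs_ = {"long": long_res, "short": short_res}
        else:
            raise ValueError(
                "criteria must be 'derive' or a CriteriaDefinition"
            )
        missing = self._missing_columns(X)
        if missing:
            raise ValueError(f"X lacks column(s) required by criteria: {missing}")
        self.positive_label_ = pos
        self.n_features_in_ = X.shape[1]
        return self

    def _missing_columns(self, X: pd.DataFrame) -> list[str]:
        needed: set[str] = set()
        for item in self.criteria_.items:
            d = item.to_dict()
            if d["type"] == "axis":
                needed.add(f"{d['axis']}_axis_mm")
            elif d["type"] == "shape_ratio":
                needed.update(("shape_round_or_oval", "ratio"))
            else:
                needed.add(d["feature"])
        return sorted(needed - set(X.columns))

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "criteria_")
        X = self._validate_frame(X)
        missing = self._missing_columns(X)
        if missing:
            raise ValueError(f"X lacks column(s) required by criteria: {missing}")
        return score_table(X, self.criteria_)["score"].to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        pos = self.positive_label_
        neg = next(c for c in self.classes_ if c != pos)
        return np.where(scores >= self.min_positive, pos, neg)
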