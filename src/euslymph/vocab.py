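"""Category vocabularies for the six EUS lymph-node image features.

Shape is 4-way (round / oval / triangle / polygonal); the remaining five
features are binary.  ``MALIGNANT_CATEGORY`` names, for each binary
feature, the category conventionally read as suggesting malignancy
(sharp/clear border, dark = hypoechoic, absent hilum, ...).
"""

from __future__ import annotations

from .errors import VocabularyError

FEATURES: tuple[str, ...] = (
    "shape",
    "border",
    "margin",
    "echogenicity",
    "homogeneity",
    "hilum",
)

VOCABULARY: dict[str, tuple[str, ...]] = {
    "shape": ("round", "oval", "triangle", "polygonal"),
    "border": ("clear", "fuzzy"),
    "margin": ("regular", "irregular"),
    "echogenicity": ("dark", "intermediate"),
    "homogeneity": ("homogeneous", "heterogeneous"),
    "hilum": ("present", "absent"),
}

#: category read as the malignant-looking one, per binary feature
MALIGNANT_CATEGORY: dict[str, str] = {
    "border": "clear",
    "margin": "irregular",
    "echogenicity": "dark",
    "homogeneity": "heterogeneous",
    "hilum": "absent",
}

ROUND_OR_OVAL: tuple[str, str] = ("round", "oval")

LOCATIONS: tuple[str, str] = ("mediastinal", "abdominal")
DIAGNOSES: tuple[str, str] = ("malignant", "benign")

#: placeholder consensus value when no category reaches the vote threshold
INDETERMINATE = "indeterminate"


def normalize_feature(feature: str) -> str:
    f = str(feature).strip().lower()
    if f not in VOCABULARY:
        raise VocabularyError(
            f"unknown feature {feature!r}; expected one of {FEATURES}"
        )
    return f


def normalize_category(feature: str, category: str) -> str:
    """Canonicalize a category label (case-insensitive in, lower-case out)."""
    f = normalize_feature(feature)
    c = str(category).strip().lower()
    if c not in VOCABULARY[f]:
        raise VocabularyError(
            f"category {category!r} is not valid for feature {f!r}; "
            f"expected one of {VOCABULARY[f]}"
        )
    return c
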