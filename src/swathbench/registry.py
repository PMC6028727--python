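"""Registry of processing methods, keyed by three-letter codes.

The benchmark enumerates chains over three categories:

* 4 transformations + NON  (Box-Cox, cube root, log, power)
* 15 normalizations + NON
* 6 imputations + NON

25 concrete methods in total; with the three "none" options the full
Cartesian product yields 5 x 16 x 7 = 560 analysis chains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "MethodCode",
    "TRANSFORMATIONS",
    "NORMALIZATIONS",
    "IMPUTATIONS",
    "DEFAULT_REGISTRY",
    "get_method",
]

CATEGORIES = ("transformation", "normalization", "imputation")


@dataclass(frozen=True)
class MethodCode:
    """A processing method: category + unique three-letter code."""

    category: str
    code: str
    display_name: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if len(self.code) != 3 or not self.code.isupper():
            raise ValidationError(f"code must be three uppercase letters: {self.code!r}")


def _codes(category: str, entries: list[tuple[str, str]]) -> list[MethodCode]:
    methods = [MethodCode(category, code, name) for code, name in entries]
    codes = [m.code for m in methods]
    if len(set(codes)) != len(codes):
        raise ValidationError(f"duplicate codes in {category}")
    return methods


TRANSFORMATIONS: list[MethodCode] = _codes(
    "transformation",
    [
        ("BOX", "Box-Cox"),
        ("CUB", "Cube Root"),
        ("LOG", "Log"),
        ("POW", "Power"),
        ("NON", "None"),
    ],
)

NORMALIZATIONS: list[MethodCode] = _codes(
    "normalization",
    [
        ("AUT", "Auto Scaling"),
        ("CYC", "Cyclic Loess"),
        ("EIG", "EigenMS"),
        ("LOW", "Locally Weighted Scatterplot Smoothing"),
        ("MAD", "Median Absolute Deviation"),
        ("MEA", "Mean"),
        ("MED", "Median"),
        ("PAR", "Pareto"),
        ("PQN", "Probabilistic Quotient"),
        ("QUA", "Quantile"),
        ("RLR", "Robust Linear Regression"),
        ("TIC", "Total Ion Current"),
        ("TMM", "Trimmed Mean of M Values"),
        ("VSN", "VSN"),
        ("ZSC", "Z-score"),
        ("NON", "None"),
    ],
)

IMPUTATIONS: list[MethodCode] = _codes(
    "imputation",
    [
        ("BAK", "Background"),
        ("BPC", "Bayesian Principal Component"),
        ("CEN", "Censored"),
        ("KNN", "K-nearest Neighbor"),
        ("SVD", "Singular Value Decomposition"),
        ("ZER", "Zero"),
        ("NON", "None"),
    ],
)

#: category -> ordered list of MethodCode (NON included in each)
DEFAULT_REGISTRY: dict[str, list[MethodCode]] = {
    "transformation": TRANSFORMATIONS,
    "normalization": NORMALIZATIONS,
    "imputation": IMPUTATIONS,
}


def get_method(category: str, code: str) -> MethodCode:
    """Look up a method by category and three-letter code."""
    for m in DEFAULT_REGISTRY[category]:
        if m.code == code:
            return m
    raise ValidationError(f"unknown {category} code {code!r}")


def concrete_methods() -> list[MethodCode]:
    """The 25 concrete (non-NON) methods across all categories."""
    return [m for cat in CATEGORIES for m in DEFAULT_REGISTRY[cat] if m.code != "NON"]
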