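"""Agreement statistics for paired ordinal TPS category calls.

Weighted kappa corrects observed agreement for chance using disagreement
weights that grow with the ordinal distance between categories:

    kappa_w = 1 - sum(w_ij * O_ij) / sum(w_ij * E_ij)

with ``O`` the observed joint proportions, ``E`` the outer product of the two
raters' marginals, and ``w_ij = |i - j| / (K - 1)`` (linear, the default) or
``((i - j) / (K - 1))**2`` (quadratic).  Interpretation bands: above 0.8
excellent, above 0.6 good, otherwise below good.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .tps import TPSCategory

DEFAULT_CATEGORIES = (TPSCategory.LT1, TPSCategory.MID, TPSCategory.GE50)


class DegenerateTableError(ValueError):
    """All mass sits in one category for both raters; kappa is undefined."""


@dataclass
class AgreementTable:
    """K x K ordinal contingency table; rows = rater/method A, columns = B."""

    counts: np.ndarray
    categories: Sequence = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} to match the category list")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be nonnegative numbers")
        if self.counts.sum() <= 0:
            raise ValueError("the table must contain at least one pair")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], categories: Sequence = DEFAULT_CATEGORIES
                   ) -> "AgreementTable":
        """Build the table from (call_a, call_b) pairs of category values."""
        index = {c: i for i, c in enumerate(categories)}
        counts = np.zeros((len(categories), len(categories)), dtype=int)
        for a, b in pairs:
            counts[index[a], index[b]] += 1
        return cls(counts, categories)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, col_a: str = "category_a",
                   col_b: str = "category_b",
                   categories: Sequence = DEFAULT_CATEGORIES) -> "AgreementTable":
        return cls.from_pairs(zip(frame[col_a], frame[col_b]), categories)


@dataclass
class KappaResult:
    kappa: float
    weights: str
    band: str
    observed_disagreement: float
    expected_disagreement: float
    percent_concordance: float
    n: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "weights": self.weights,
            "band": self.band,
            "percent_concordance": self.percent_concordance,
            "n": self.n,
        }


def _disagreement_weights(k: int, weights: Literal["linear", "quadratic"]) -> np.ndarray:
    i = np.arange(k)
    d = np.abs(i[:, None] - i[None, :]) / (k - 1)
    if weights == "linear":
        return d
    if weights == "quadratic":
        return d**2
    raise ValueError("weights must be 'linear' or 'quadratic'")


def interpretation_band(kappa: float) -> str:
    if kappa > 0.8:
        return "excellent"
    if kappa > 0.6:
        return "good"
    return "below good"


def weighted_kappa(
    table: AgreementTable, weights: Literal["linear", "quadratic"] = "linear"
) -> KappaResult:
    """Weighted kappa of an agreement table, with its interpretation band."""
    k = len(table.categories)
    if k < 2:
        raise ValueError("weighted kappa needs at least two categories")
    o = table.counts / table.counts.sum()
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    e = np.outer(row, col)
    w = _disagreement_weights(k, weights)
    expected = float((w * e).sum())
    observed = float((w * o).sum())
    if expected == 0.0:
        raise DegenerateTableError(
            "all pairs fall in a single category for both raters; kappa undefined"
        )
    kappa = 1.0 - observed / expected
    return KappaResult(
        kappa=kappa,
        weights=weights,
        band=interpretation_band(kappa),
        observed_disagreement=observed,
        expected_disagreement=expected,
        percent_concordance=percent_concordance(table),
        n=table.n,
    )


def percent_concordance(table: AgreementTable) -> float:
    """Percentage of pairs in the same category: 100 x trace / n."""
    return 100.0 * float(np.trace(table.counts)) / table.counts.sum()
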