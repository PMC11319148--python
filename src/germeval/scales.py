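"""Common ordinal disease scale and resistance summaries.

Pathology scores arrive on heterogeneous scales (1-9 severity, 0-100 percent
severity, or already-categorical reactions).  They are converted to a common
nine-point ordinal reaction scale running from R (resistant, little or no
disease) through MR (moderately resistant) and MS (moderately susceptible) to
VS (very susceptible), with the intermediate hyphenated classes between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ["R", "R-MR", "MR", "MR-MS", "MS", "MS-S", "S", "VS"]
RESISTANT_SET = frozenset({"R", "R-MR", "MR"})

__all__ = [
    "CATEGORIES",
    "RESISTANT_SET",
    "OrdinalScale",
    "ScaleRangeError",
    "to_ordinal",
    "pct_resistant",
]


class ScaleRangeError(ValueError):
    pass


@dataclass(frozen=True)
class OrdinalScale:
    """A named mapping from a raw numeric score range to the common categories.

    Cutpoints are equal-width over ``(lo, hi)`` by default; pass explicit
    ``cutpoints`` (len(CATEGORIES) - 1 increasing interior boundaries) to
    override per pathogen.  Scores at a boundary fall in the lower (more
    resistant) category.
    """

    name: str
    lo: float
    hi: float
    cutpoints: tuple[float, ...] | None = None

    def boundaries(self) -> np.ndarray:
        if self.cutpoints is not None:
            cp = np.asarray(self.cutpoints, dtype=float)
            if len(cp) != len(CATEGORIES) - 1 or np.any(np.diff(cp) <= 0):
                raise ValueError("cutpoints must be 7 strictly increasing values")
            return cp
        return self.lo + (self.hi - self.lo) * np.arange(1, len(CATEGORIES)) / len(CATEGORIES)

    def convert(self, score: float) -> str:
        if not self.lo <= score <= self.hi:
            raise ScaleRangeError(
                f"score {score} outside range [{self.lo}, {self.hi}] of scheme {self.name!r}"
            )
        return CATEGORIES[int(np.searchsorted(self.boundaries(), score, side="left"))]


SCHEMES: dict[str, OrdinalScale] = {
    "1-9": OrdinalScale("1-9", 1.0, 9.0),
    "0-9": OrdinalScale("0-9", 0.0, 9.0),
    "percent": OrdinalScale("percent", 0.0, 100.0),
}


def to_ordinal(score, scheme: str | OrdinalScale = "1-9") -> str:
    """Convert a raw score to the common ordinal category.

    Categorical input (one of the common categories) passes through unchanged
    regardless of scheme; numeric input is mapped by the scheme's cutpoints.
    """
    if isinstance(score, str):
        cat = score.strip().upper()
        if cat not in CATEGORIES:
            raise ScaleRangeError(f"unknown reaction category {score!r}")
        return cat
    if isinstance(scheme, str):
        try:
            scheme = SCHEMES[scheme]
        except KeyError:
            raise ScaleRangeError(f"unknown scoring scheme {scheme!r}") from None
    return scheme.convert(float(score))


def pct_resistant(
    table: pd.DataFrame,
    resistant: frozenset[str] | set[str] = RESISTANT_SET,
) -> pd.Series:
    """Percentage of scored genotypes rated R or MR per disease.

    ``table`` has columns genotype, disease, category; genotypes without a
    score for a disease are excluded from that disease's denominator.
    """
    if table.empty:
        raise ValueError("empty disease table")
    scored = table.dropna(subset=["category"])
    def pct(sub: pd.DataFrame) -> float:
        return 100.0 * sub["category"].isin(resistant).sum() / len(sub)
    return scored.groupby("disease").apply(pct, include_groups=False)
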