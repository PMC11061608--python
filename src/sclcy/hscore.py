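"""Immunohistochemistry H-scores from staining-intensity distributions.

The H-score summarises a marker's staining across a section as
``1*pct_1 + 2*pct_2 + 3*pct_3`` where ``pct_i`` is the percentage of cells at
intensity level i (0-3); the score ranges from 0 (all negative) to 300 (all
strongly positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ValidationError

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class IntensityDistribution:
    """Percentages of cells at staining intensities 0-3; must sum to 100."""

    pct_0: float
    pct_1: float
    pct_2: float
    pct_3: float

    def __post_init__(self) -> None:
        parts = (self.pct_0, self.pct_1, self.pct_2, self.pct_3)
        if any(p < 0 or p > 100 for p in parts):
            raise ValidationError("intensity percentages must lie in [0, 100]")
        if abs(sum(parts) - 100.0) > _SUM_TOL:
            raise ValidationError(f"intensity percentages sum to {sum(parts)!r}, not 100")

    @classmethod
    def from_fractions(cls, f0: float, f1: float, f2: float, f3: float) -> "IntensityDistribution":
        return cls(f0 * 100.0, f1 * 100.0, f2 * 100.0, f3 * 100.0)


def h_score(d: IntensityDistribution) -> float:
    """Weighted-sum H-score in [0, 300]."""
    return 1.0 * d.pct_1 + 2.0 * d.pct_2 + 3.0 * d.pct_3


def h_score_table(table: pd.DataFrame, unit: str = "percent") -> pd.DataFrame:
    """Compute H-scores for a table with columns pct_0..pct_3 (plus any id
    columns, which are carried through). ``unit`` is 'percent' or 'fraction'."""
    if unit not in ("percent", "fraction"):
        raise ValueError("unit must be 'percent' or 'fraction'")
    out = table.copy()
    scores = []
    for _, row in table.iterrows():
        parts = [float(row[f"pct_{i}"]) for i in range(4)]
        if unit == "fraction":
            dist = IntensityDistribution.from_fractions(*parts)
        else:
            dist = IntensityDistribution(*parts)
        scores.append(h_score(dist))
    out["h_score"] = scores
    return out
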