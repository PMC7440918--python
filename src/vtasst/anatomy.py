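"""Anatomical cell-count scaling, co-expression classes and
rostro-caudal density profiles.

Counting experiments sample a fraction of the structure (e.g. nine
40-µm coronal sections covering 40% of the midbrain volume of interest for
immunostaining, or six 12-µm sections covering 9% for in situ
hybridization); whole-structure totals are obtained by dividing the
counted cells by the sampled percentage and multiplying by 100.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountRecord",
    "ScaledCount",
    "scale_section_counts",
    "marker_ratio",
    "classify_coexpression",
    "COEXPRESSION_CATEGORIES",
    "rostrocaudal_profile",
]


@dataclass
class CountRecord:
    """Marker counts for one histological section."""

    section_id: str
    bregma_mm: float
    counts: Mapping[str, float]  # marker -> cells in this section
    thickness_um: float = 40.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative cell counts")


@dataclass
class ScaledCount:
    """Whole-structure estimate with a display rounding."""

    counted: float
    sampled_percent: float
    total: float

    @property
    def total_rounded(self) -> int:
        return int(round(self.total))


def scale_section_counts(counted: float, sampled_percent: float) -> ScaledCount:
    """Scale a sampled count to a whole-structure total.

    ``total = counted / sampled_percent * 100`` — e.g. 320 cells counted in
    sections covering 40% of the structure gives an estimate of 800 cells.
    """
    if not 0 < sampled_percent <= 100:
        raise ValueError("sampled_percent must lie in (0, 100]")
    if counted < 0:
        raise ValueError("counted must be nonnegative")
    return ScaledCount(counted, sampled_percent, counted / sampled_percent * 100.0)


def marker_ratio(count_a: float, count_b: float) -> float:
    """Percentage of marker A cells relative to marker B cells (100·a/b)."""
    if count_b <= 0:
        raise ValueError("denominator count must be positive")
    return 100.0 * count_a / count_b


COEXPRESSION_CATEGORIES = ("GABA", "Glu", "GABA+Glu", "DA", "other", "none")


def _categorize(slc32a1: bool, slc17a6: bool, slc6a3: bool) -> str:
    if slc32a1 and not slc17a6 and not slc6a3:
        return "GABA"
    if slc17a6 and not slc32a1 and not slc6a3:
        return "Glu"
    if slc32a1 and slc17a6 and not slc6a3:
        return "GABA+Glu"
    if slc6a3 and not slc32a1 and not slc17a6:
        return "DA"
    if not (slc32a1 or slc17a6 or slc6a3):
        return "none"
    return "other"  # any combination involving Slc6a3 plus another marker


def classify_coexpression(
    calls: Sequence[tuple[bool, bool, bool]] | pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Classify Sst-positive cells by their transporter co-expression.

    Each call is the boolean triple (Slc32a1, Slc17a6, Slc6a3) — vesicular
    GABA transporter, vesicular glutamate transporter 2, dopamine
    transporter.  Categories: GABA (Slc32a1 only), Glu (Slc17a6 only),
    GABA+Glu, DA (Slc6a3 only), "other" for the remaining marker-positive
    combinations, and "none" for marker-negative cells (warned, as an
    Sst cell with no transporter is likely a staining failure).

    Returns ``(per-cell categories, percentage per category)``; the
    percentages sum to 100 over the cohort.
    """
    if isinstance(calls, pd.DataFrame):
        triples = list(
            calls[["Slc32a1", "Slc17a6", "Slc6a3"]].astype(bool).itertuples(index=False)
        )
        index = calls.index
    else:
        triples = list(calls)
        index = pd.RangeIndex(len(triples))
    cats = [_categorize(*map(bool, t)) for t in triples]
    if "none" in cats:
        warnings.warn(f"{cats.count('none')} cells express no transporter marker")
    per_cell = pd.Series(cats, index=index, name="category")
    n = len(cats)
    counts = Counter(cats)
    proportions = pd.Series(
        {c: 100.0 * counts.get(c, 0) / n for c in COEXPRESSION_CATEGORIES},
        name="percent",
    )
    return per_cell, proportions


def rostrocaudal_profile(
    records: Sequence[CountRecord], marker: str
) -> tuple[pd.Series, int]:
    """Cell-count profile along the rostro-caudal axis for one marker.

    Returns the per-section series indexed by bregma (mm), sorted rostral
    to caudal (descending bregma), together with the sign of the
    least-squares trend of count against caudal distance: +1 when the
    marker density increases caudally, -1 when it decreases, 0 when flat.
    Duplicate bregma levels are averaged with a warning.
    """
    if len(records) < 2:
        raise ValueError("need at least two sections for a profile")
    df = pd.DataFrame(
        {
            "bregma": [r.bregma_mm for r in records],
            "count": [float(r.counts.get(marker, 0.0)) for r in records],
        }
    )
    if df["bregma"].duplicated().any():
        warnings.warn("duplicate bregma levels; averaging")
        df = df.groupby("bregma", as_index=False)["count"].mean()
    df = df.sort_values("bregma", ascending=False)
    series = pd.Series(df["count"].to_numpy(), index=df["bregma"].to_numpy(),
                       name=marker)
    # caudal distance grows as bregma becomes more negative
    slope = np.polyfit(-df["bregma"].to_numpy(), df["count"].to_numpy(), 1)[0]
    trend = 0 if np.isclose(slope, 0.0) else int(np.sign(slope))
    return series, trend
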