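"""Per-cell fraction-in-granule statistics and construct comparisons.

The unit of measurement is one imaged cell: the fraction of its
cytoplasmic smFISH spots that fall inside stress granules. Constructs
are summarized by the median and quartiles of this fraction across
cells, and pairs of constructs are compared with a two-sided rank-sum
test, mirroring the boxplot-and-stars presentation used in tethering
experiments.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    EmptyDatasetError,
    InvalidArgumentError,
    UndefinedFractionError,
)
from .types import CellMeasurement, ConstructDataset, ConstructSummary

logger = logging.getLogger(__name__)

__all__ = [
    "fraction_in_sg",
    "summarize_construct",
    "compare_constructs",
    "star_category",
    "DEFAULT_STAR_THRESHOLDS",
]

#: Figure-legend significance thresholds: p below a cutoff earns the stars.
#: Ordered from most to least stringent.
DEFAULT_STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (1e-7, "***"),
    (1e-4, "**"),
    (1e-3, "*"),
)


def fraction_in_sg(cell: CellMeasurement) -> float:
    """Fraction of a cell's cytoplasmic RNA spots located in granules."""
    if cell.spots_total == 0:
        raise UndefinedFractionError(
            f"cell {cell.cell_id} has no cytoplasmic spots; fraction undefined"
        )
    return cell.spots_in_sg / cell.spots_total


def _valid_fractions(dataset: ConstructDataset) -> np.ndarray:
    fractions = []
    skipped = 0
    for cell in dataset.cells:
        if cell.spots_total == 0:
            skipped += 1
            continue
        fractions.append(cell.spots_in_sg / cell.spots_total)
    if skipped:
        logger.warning(
            "construct %s: excluded %d cell(s) with zero cytoplasmic spots",
            dataset.label,
            skipped,
        )
    return np.asarray(fractions)


def summarize_construct(dataset: ConstructDataset) -> ConstructSummary:
    """Median and quartiles of per-cell in-granule fractions.

    Cells with zero cytoplasmic spots are excluded (logged), not imputed.
    """
    fractions = _valid_fractions(dataset)
    if fractions.size == 0:
        raise EmptyDatasetError(
            f"construct {dataset.label}: no cells with cytoplasmic spots"
        )
    q1, med, q3 = np.percentile(fractions, [25, 50, 75])
    return ConstructSummary(
        label=dataset.label,
        tether_sites=dataset.tether_sites,
        n_cells=int(fractions.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def compare_constructs(
    a: ConstructDataset,
    b: ConstructDataset,
    *,
    thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS,
) -> tuple[float, str]:
    """Two-sided Mann-Whitney rank-sum comparison of per-cell fractions.

    Returns (p-value, star category). The star category is a pure
    threshold function of p using the supplied figure-legend cutoffs;
    an empty string means not significant at any cutoff. The test uses
    the normal approximation with tie correction, appropriate for the
    heavily tied fractions that spot counting produces.
    """
    fa, fb = _valid_fractions(a), _valid_fractions(b)
    if fa.size < 2 or fb.size < 2:
        raise InvalidArgumentError(
            "both constructs need >= 2 cells with cytoplasmic spots"
        )
    _, p = stats.mannwhitneyu(fa, fb, alternative="two-sided", method="asymptotic")
    p = float(min(p, 1.0))
    return p, star_category(p, thresholds)


def star_category(
    p: float,
    thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS,
) -> str:
    """Map a p-value to its figure-legend star string ('' if none apply)."""
    if not (0 < p <= 1):
        raise InvalidArgumentError("p must lie in (0, 1]")
    for cutoff, stars in sorted(thresholds):
        if p < cutoff:
            return stars
    return ""
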