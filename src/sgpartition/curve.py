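"""Enrichment-vs-valency modelling.

The model treats stress-granule recruitment of an mRNP as the summed
effect of its independent contacts with the granule network. An
engineered reporter with k tether sites makes x = k + n total contacts,
where n is the unknown baseline valency of the unmodified reporter. The
percent of the reporter's cytoplasmic molecules inside granules follows
a saturating power law E(x) = c*x**p (capped at 100%), fitted on
log-log axes to per-construct median enrichments, with n selected by
scanning an integer grid and keeping the value that maximizes Pearson's
r of the linearized fit.

Once calibrated the curve is invertible, giving a first-approximation
interaction count for any transcript from its measured granule fraction,
and differentiable in the discrete sense, giving the predicted effect of
adding or removing individual contacts.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InvalidArgumentError, SaturationError
from .types import FitResult, PartitionCurve, ThermoParams

logger = logging.getLogger(__name__)

__all__ = [
    "fit_power_law",
    "select_baseline_n",
    "calibrate_two_point",
    "predict_enrichment",
    "estimate_interactions",
    "delta_enrichment",
    "occupancy_adjust",
    "thermodynamic_fraction",
    "transcriptome_interaction_table",
    "paper_calibrated_curve",
]

#: Printed median enrichments of the tethering dose series used for
#: two-point calibration: 14% at 2 total interactions (0 tether sites,
#: baseline n=2) and 62% at 27 (25 sites + 2).
CALIBRATION_ANCHORS = ((2.0, 14.0), (27.0, 62.0))


def _clean_points(
    medians: Iterable[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Drop non-positive enrichments (log-undefined) with a warning."""
    usable = []
    for k, percent in medians:
        if percent <= 0:
            logger.warning(
                "excluding point (k=%s, %.3g%%): non-positive enrichment "
                "cannot enter a log fit",
                k,
                percent,
            )
            continue
        usable.append((float(k), float(percent)))
    return usable


def fit_power_law(
    medians: Iterable[tuple[float, float]],
    n: int,
    *,
    model: str = "power",
) -> tuple[float, float, float]:
    """Fit E = c*(k+n)**p by least squares on log axes for a fixed n.

    Parameters
    ----------
    medians
        (tether sites k, median enrichment percent) pairs, one per
        construct. Non-positive percents are excluded with a warning.
    n
        Candidate baseline interaction count (>= 1).
    model
        ``"power"`` regresses ln(E) on ln(k+n); ``"semilog"`` regresses
        E on ln(k+n).

    Returns
    -------
    (c, p, r)
        Amplitude/intercept, exponent/slope, and Pearson r of the
        linearized points.
    """
    if n < 1:
        raise InvalidArgumentError("baseline n must be >= 1")
    points = _clean_points(medians)
    if len({k for k, _ in points}) < 3:
        raise FitError(
            f"need >= 3 usable points with distinct tether counts, got {len(points)}"
        )
    x = np.log([k + n for k, _ in points])
    if model == "power":
        y = np.log([e for _, e in points])
    elif model == "semilog":
        y = np.array([e for _, e in points])
    else:
        raise InvalidArgumentError(f"unknown model {model!r}")
    res = stats.linregress(x, y)
    c = math.exp(res.intercept) if model == "power" else res.intercept
    return c, float(res.slope), float(res.rvalue)


def select_baseline_n(
    medians: Iterable[tuple[float, float]],
    n_grid: Sequence[int] = tuple(range(1, 11)),
    *,
    model: str = "power",
    cap: float = 100.0,
) -> FitResult:
    """Scan candidate baseline valencies and keep the best linearized fit.

    Every n in ``n_grid`` is fitted with :func:`fit_power_law`; the n
    attaining the maximal Pearson r is selected, with ties broken toward
    the smallest n. The full (n, r, c, p) table is returned for
    inspection and plotting.
    """
    if len(n_grid) == 0:
        raise InvalidArgumentError("n_grid must be non-empty")
    points = tuple(_clean_points(medians))
    rows = []
    for n in sorted(set(int(n) for n in n_grid)):
        c, p, r = fit_power_law(points, n, model=model)
        rows.append({"n": n, "r": r, "c": c, "p": p})
    table = pd.DataFrame(rows)
    # idxmax on the r column returns the first maximum; rows are sorted by
    # ascending n, so ties already break toward smaller n.
    best = table.loc[table["r"].idxmax()]
    curve = PartitionCurve(
        c=float(best["c"]),
        p=float(best["p"]),
        n=int(best["n"]),
        cap=cap,
        model=model,
    )
    return FitResult(curve=curve, r=float(best["r"]), table=table, points=points)


def calibrate_two_point(
    x1: float,
    e1: float,
    x2: float,
    e2: float,
    *,
    n: int = 2,
    cap: float = 100.0,
) -> PartitionCurve:
    """Closed-form power law through two (total interactions, percent) anchors.

    p = ln(E2/E1) / ln(x2/x1) and c = E1 / x1**p; the returned curve passes
    exactly through both points.
    """
    if not (x2 > x1 >= 1):
        raise InvalidArgumentError("require x2 > x1 >= 1")
    if not (0 < e1 < e2 < cap):
        raise InvalidArgumentError("require 0 < E1 < E2 < cap")
    p = math.log(e2 / e1) / math.log(x2 / x1)
    c = e1 / x1**p
    return PartitionCurve(c=c, p=p, n=n, cap=cap)


def paper_calibrated_curve() -> PartitionCurve:
    """The curve through the printed tethering medians (14% at x=2, 62% at x=27)."""
    (x1, e1), (x2, e2) = CALIBRATION_ANCHORS
    return calibrate_two_point(x1, e1, x2, e2, n=2)


def predict_enrichment(curve: PartitionCurve, x: float) -> float:
    """Predicted percent enrichment at x total interactions.

    Strictly increasing in x until the cap; returns 0 at x = 0.
    """
    if x < 0:
        raise InvalidArgumentError("total interactions x must be non-negative")
    if x == 0:
        return 0.0
    if curve.model == "power":
        e = curve.c * x**curve.p
    else:
        e = curve.c + curve.p * math.log(x)
    return min(max(e, 0.0), curve.cap)


def estimate_interactions(curve: PartitionCurve, e: float) -> float:
    """Invert the curve: the x with E(x) = e.

    Raises :class:`SaturationError` at or above the cap — the saturated
    regime carries no information about the interaction count — and
    :class:`InvalidArgumentError` for non-positive enrichment.
    """
    if e <= 0:
        raise InvalidArgumentError("enrichment must be positive to invert")
    if e >= curve.cap:
        raise SaturationError(
            f"enrichment {e:.3g}% is at or above the cap {curve.cap:.3g}%; "
            "the interaction count is unidentifiable"
        )
    if curve.model == "power":
        return (e / curve.c) ** (1.0 / curve.p)
    return math.exp((e - curve.c) / curve.p)


def delta_enrichment(curve: PartitionCurve, x: float, removed: float) -> float:
    """Drop in predicted enrichment when ``removed`` contacts are lost.

    E(x) - E(x - removed), in percentage points; non-negative, and for a
    single lost contact it shrinks as x grows — high-valency mRNPs are
    buffered against the loss of any one interaction.
    """
    if removed < 0 or removed > x:
        raise InvalidArgumentError("require 0 <= removed <= x")
    return predict_enrichment(curve, x) - predict_enrichment(curve, x - removed)


def occupancy_adjust(k: float, occupancy: float) -> float:
    """Effective interaction count if only a fraction of sites are engaged.

    With occupancy f in (0, 1], k tether sites contribute k*f contacts;
    downstream operations accept the resulting non-integer valency.
    """
    if not (0 < occupancy <= 1):
        raise InvalidArgumentError("occupancy must lie in (0, 1]")
    if k < 0:
        raise InvalidArgumentError("k must be non-negative")
    return k * occupancy


def thermodynamic_fraction(k: float, params: ThermoParams) -> float:
    """Equilibrium granule fraction of an RNP making k contacts.

    Two-state partitioning proportional to e^(-dG/RT) with dG = -k*dg:
    fraction = A*e^(k*dg) / (1 + A*e^(k*dg)). Strictly increasing in k for
    dg > 0 and bounded above by 1.
    """
    if k < 0:
        raise InvalidArgumentError("interaction count k must be non-negative")
    # log-domain logistic to avoid overflow at large k*dg
    logit = math.log(params.prefactor) + k * params.dg
    if logit > 0:
        return 1.0 / (1.0 + math.exp(-logit))
    z = math.exp(logit)
    return z / (1.0 + z)


def transcriptome_interaction_table(
    fractions: pd.Series,
    curve: PartitionCurve,
    *,
    ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Ballpark interaction counts for a table of granule fractions.

    Parameters
    ----------
    fractions
        Per-transcript granule fraction on [0, 1] (a Series indexed by
        transcript id, or any sequence when ``ids`` is given).
    curve
        Calibrated partition curve.

    Returns
    -------
    DataFrame indexed by transcript id with columns ``interactions``
    (float, NaN where not estimable) and ``flag`` (``"ok"``,
    ``"saturated"``, or ``"nonpositive"``). Saturated and non-positive
    rows are flagged rather than silently clamped: the curve carries no
    information there.
    """
    if not isinstance(fractions, pd.Series):
        fractions = pd.Series(
            list(fractions),
            index=list(ids) if ids is not None else None,
            dtype=float,
        )
    est, flags = [], []
    for frac in fractions:
        percent = frac * 100.0
        if percent <= 0:
            est.append(math.nan)
            flags.append("nonpositive")
        elif percent >= curve.cap:
            est.append(math.nan)
            flags.append("saturated")
        else:
            est.append(estimate_interactions(curve, percent))
            flags.append("ok")
    return pd.DataFrame(
        {"interactions": est, "flag": flags}, index=fractions.index
    )
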