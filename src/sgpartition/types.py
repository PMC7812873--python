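"""Shared domain types.

The central object is :class:`PartitionCurve`, the fitted law relating an
mRNP's total number of granule contacts x = k + n (k engineered tether
sites, n baseline contacts of the unmodified reporter) to the percent of
its cytoplasmic molecules found inside stress granules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import InvalidArgumentError

#: Supported functional forms for the enrichment-vs-valency law.
CURVE_MODELS = ("power", "semilog")


@dataclass(frozen=True)
class PartitionCurve:
    """Enrichment-vs-total-interactions law E(x).

    For the default ``power`` model, E(x) = c * x**p capped at ``cap``
    percent. The ``semilog`` alternative, E(x) = c + p*ln(x), linearizes
    only the interaction axis and is kept for model comparison.

    Parameters
    ----------
    c : float
        Amplitude on the percent scale (power model) or intercept in
        percent (semilog model).
    p : float
        Dimensionless exponent (power) or slope per ln-interaction
        (semilog). Must be positive: more contacts, more enrichment.
    n : int
        Baseline number of reporter-granule interactions before any
        engineered tether sites.
    cap : float
        Ceiling on predicted enrichment, in percent (default 100).
    model : str
        ``"power"`` or ``"semilog"``.
    """

    c: float
    p: float
    n: int
    cap: float = 100.0
    model: str = "power"

    def __post_init__(self) -> None:
        if self.model not in CURVE_MODELS:
            raise InvalidArgumentError(f"unknown curve model {self.model!r}")
        if self.model == "power" and self.c <= 0:
            raise InvalidArgumentError("amplitude c must be positive")
        if self.p <= 0:
            raise InvalidArgumentError("exponent/slope p must be positive")
        if self.cap <= 0:
            raise InvalidArgumentError("cap must be positive")
        if self.n < 0:
            raise InvalidArgumentError("baseline n must be non-negative")


@dataclass(frozen=True)
class ThermoParams:
    """Equilibrium-partitioning parameters.

    The granule fraction of an RNP with k contacts is modelled as a
    two-state binding equilibrium, fraction = A*e^(k*dg) / (1 + A*e^(k*dg)),
    i.e. partitioning proportional to e^(-dG/RT) with dG = -k*dg.

    dg : per-interaction favourable free energy, in units of RT.
    prefactor : dimensionless partition prefactor A (> 0).
    """

    dg: float
    prefactor: float = 1.0

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise InvalidArgumentError("prefactor A must be positive")


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell smFISH spot tally: total cytoplasmic spots and the subset
    located inside stress granules."""

    cell_id: str
    spots_total: int
    spots_in_sg: int

    def __post_init__(self) -> None:
        if self.spots_total < 0 or self.spots_in_sg < 0:
            raise InvalidArgumentError("spot counts must be non-negative")
        if self.spots_in_sg > self.spots_total:
            raise InvalidArgumentError(
                f"cell {self.cell_id}: spots_in_sg {self.spots_in_sg} exceeds "
                f"spots_total {self.spots_total}"
            )


@dataclass(frozen=True)
class ConstructDataset:
    """All cells imaged for one reporter construct with k tether sites."""

    label: str
    tether_sites: int
    cells: tuple[CellMeasurement, ...]

    def __post_init__(self) -> None:
        if self.tether_sites < 0:
            raise InvalidArgumentError("tether_sites must be non-negative")
        if len(self.cells) == 0:
            raise InvalidArgumentError(f"construct {self.label}: no cells")


@dataclass(frozen=True)
class TetheringStudy:
    """A dose series of constructs with pairwise-distinct tether counts."""

    constructs: tuple[ConstructDataset, ...]

    def __post_init__(self) -> None:
        ks = [c.tether_sites for c in self.constructs]
        if len(set(ks)) != len(ks):
            raise InvalidArgumentError("tether-site counts must be distinct")

    def construct(self, label: str) -> ConstructDataset:
        for c in self.constructs:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class ConstructSummary:
    """Boxplot-style summary of per-cell in-granule fractions."""

    label: str
    tether_sites: int
    n_cells: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q1 <= self.median <= self.q3 <= 1.0):
            raise InvalidArgumentError(
                f"{self.label}: quartiles must satisfy 0 <= Q1 <= median <= Q3 <= 1"
            )


@dataclass(frozen=True)
class FitResult:
    """Outcome of baseline-n model selection.

    ``table`` holds one row per candidate n with columns n, r, c, p;
    ``curve`` is the selected model (argmax r, ties to smallest n);
    ``points`` are the (k, median percent) pairs that entered the fit.
    """

    curve: PartitionCurve
    r: float
    table: pd.DataFrame
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        best = self.table["r"].max()
        if not math.isclose(self.r, best, rel_tol=0, abs_tol=1e-12):
            raise InvalidArgumentError("selected r must attain the table maximum")


@dataclass(frozen=True)
class SyntheticTranscript:
    """A generated RNA sequence with known planted motif sites."""

    id: str
    sequence: str
    planted_sites: tuple[tuple[str, int], ...] = ()  # (motif name, 1-based start)


@dataclass
class SGSeqTable:
    """Two-compartment sequencing counts: granule-purified vs total RNA.

    ``granule`` and ``total`` are DataFrames indexed by transcript id with
    one integer column per replicate. ``lengths`` maps id -> nt length.
    ``true_interactions`` is the synthetic ground truth when the table was
    generated rather than measured.
    """

    granule: pd.DataFrame
    total: pd.DataFrame
    lengths: pd.Series
    true_interactions: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.granule.index.equals(self.total.index):
            raise InvalidArgumentError("granule/total row sets differ")
        if (self.granule.to_numpy() < 0).any() or (self.total.to_numpy() < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        if (self.lengths.loc[self.granule.index] <= 0).any():
            raise InvalidArgumentError("transcript lengths must be positive")

    @property
    def transcript_ids(self) -> Sequence[str]:
        return list(self.granule.index)


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC nucleotide pattern, e.g. ARE = AUUUA, PRE = UGUANAUA."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise InvalidArgumentError("motif pattern must be non-empty")


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-sequence tally of predicted granule-protein binding sites.

    ``motif_counts`` are scanner-derived (e.g. ARE, PRE); ``external_counts``
    come from supplied tables (e.g. SAM68 CLIP sites) and are never predicted
    from sequence.
    """

    sequence_id: str
    motif_counts: tuple[tuple[str, int], ...] = ()
    external_counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for name, count in (*self.motif_counts, *self.external_counts):
            if count < 0:
                raise InvalidArgumentError(f"{self.sequence_id}/{name}: negative count")

    @property
    def total_sites(self) -> int:
        return sum(c for _, c in self.motif_counts) + sum(
            c for _, c in self.external_counts
        )

    def count(self, category: str) -> int:
        for name, c in (*self.motif_counts, *self.external_counts):
            if name == category:
                return c
        raise KeyError(category)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-transcript granule-vs-total enrichment score.

    ``score`` is log2(granule CPM / total CPM) averaged over replicates;
    ``replicate_scores`` are the per-replicate values; ``mean_abundance``
    is the mean normalized abundance (CPM) across all libraries.
    """

    transcript_id: str
    score: float
    mean_abundance: float
    replicate_scores: tuple[float, ...] = field(default_factory=tuple)
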