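"""IUPAC motif scanning, sequence fragmentation, and site-based prediction.

Counts AU-rich elements (ARE, AUUUA), Pumilio recognition elements
(PRE, UGUANAUA) and arbitrary IUPAC patterns on RNA sequences, splits
sequences into halves/quarters/eighths for deletion-series analyses,
and converts summed site tallies into predicted granule enrichment
through a calibrated partition curve.

Coordinates are 1-based inclusive on the sense (FASTA) strand; T and U
are interchangeable on input and normalized to U internally.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .curve import predict_enrichment
from .errors import (
    InvalidArgumentError,
    SequenceError,
    UndefinedCorrelationError,
)
from .types import MotifSpec, PartitionCurve, SiteAnnotation

__all__ = [
    "ARE",
    "PRE",
    "normalize_rna",
    "count_motif",
    "find_motif",
    "fragment_scheme",
    "antisense",
    "annotate_sequence",
    "correlate_sites_enrichment",
    "predict_from_sites",
    "FRAGMENT_SCHEMES",
]

#: Stock motif definitions. The exact flanking requirements behind any
#: particular published tally are not fixed by these consensi, so both are
#: configuration-level values, not constants of the method.
ARE = MotifSpec("ARE", "AUUUA")
PRE = MotifSpec("PRE", "UGUANAUA")

# IUPAC nucleotide codes in the RNA alphabet.
_IUPAC_RNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

FRAGMENT_SCHEMES = {"halves": 2, "quarters": 4, "eighths": 8}


def normalize_rna(sequence: str, *, what: str = "sequence") -> str:
    """Uppercase, T->U; reject characters outside {A,C,G,U,T,N}."""
    seq = sequence.upper().replace("T", "U")
    for i, ch in enumerate(seq):
        if ch not in "ACGUN":
            raise SequenceError(
                f"{what}: invalid character {ch!r} at position {i + 1}"
            )
    return seq


def _pattern_regex(motif: MotifSpec) -> re.Pattern[str]:
    pat = motif.pattern.upper().replace("T", "U")
    parts = []
    for i, ch in enumerate(pat):
        try:
            bases = _IUPAC_RNA[ch]
        except KeyError:
            raise SequenceError(
                f"motif {motif.name}: invalid IUPAC symbol {ch!r} at position {i + 1}"
            ) from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def find_motif(
    sequence: str, motif: MotifSpec, *, overlapping: bool = True
) -> list[int]:
    """1-based start positions of motif matches on the sense strand.

    Overlapping occurrences are reported by default; with
    ``overlapping=False`` the scan resumes after each match end.
    """
    seq = normalize_rna(sequence)
    regex = _pattern_regex(motif)
    positions: list[int] = []
    start = 0
    while True:
        m = regex.search(seq, start)
        if m is None:
            return positions
        positions.append(m.start() + 1)
        start = m.start() + 1 if overlapping else m.end()


def count_motif(
    sequence: str, motif: MotifSpec, *, overlapping: bool = True
) -> int:
    """Number of motif match positions on the sense strand."""
    return len(find_motif(sequence, motif, overlapping=overlapping))


def fragment_scheme(
    sequence: str, scheme: str
) -> list[tuple[str, str]]:
    """Split a sequence into contiguous halves, quarters, or eighths.

    Fragments are non-overlapping, ordered 5'->3', and reassemble to the
    input; remainder bases go to the final fragment. Fragment ids are
    ``half1``, ``quarter3``, ``eighth8``, etc.
    """
    try:
        n_frag = FRAGMENT_SCHEMES[scheme]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown scheme {scheme!r}; choose from {sorted(FRAGMENT_SCHEMES)}"
        ) from None
    if len(sequence) < n_frag:
        raise InvalidArgumentError(
            f"sequence of length {len(sequence)} cannot be split into {n_frag}"
        )
    size = len(sequence) // n_frag
    stem = scheme.rstrip("s").replace("halve", "half")
    frags = []
    for i in range(n_frag):
        lo = i * size
        hi = (i + 1) * size if i < n_frag - 1 else len(sequence)
        frags.append((f"{stem}{i + 1}", sequence[lo:hi]))
    return frags


def antisense(sequence: str) -> str:
    """Reverse complement in the RNA alphabet (an involution)."""
    seq = normalize_rna(sequence)
    return seq.translate(_COMPLEMENT)[::-1]


def annotate_sequence(
    sequence_id: str,
    sequence: str,
    motifs: Iterable[MotifSpec] = (ARE, PRE),
    *,
    external_counts: Iterable[tuple[str, int]] = (),
    overlapping: bool = True,
) -> SiteAnnotation:
    """Scan a sequence for each motif and bundle counts with external sites."""
    counts = tuple(
        (m.name, count_motif(sequence, m, overlapping=overlapping)) for m in motifs
    )
    return SiteAnnotation(
        sequence_id=sequence_id,
        motif_counts=counts,
        external_counts=tuple(external_counts),
    )


def correlate_sites_enrichment(
    annotations: Sequence[SiteAnnotation],
    enrichments: Sequence[float],
    category: str = "total",
) -> tuple[float, float, float]:
    """Pearson correlation and least-squares line of enrichment on site count.

    ``category`` selects one motif/external tally by name, or ``"total"``
    for the summed site count. Returns (r, slope, intercept).
    """
    if len(annotations) != len(enrichments) or len(annotations) < 3:
        raise InvalidArgumentError("need equal-length inputs with >= 3 entries")
    if category == "total":
        counts = np.array([a.total_sites for a in annotations], dtype=float)
    else:
        counts = np.array([a.count(category) for a in annotations], dtype=float)
    if np.ptp(counts) == 0:
        raise UndefinedCorrelationError(
            f"site counts for {category!r} have zero variance"
        )
    res = stats.linregress(counts, np.asarray(enrichments, dtype=float))
    return float(res.rvalue), float(res.slope), float(res.intercept)


def predict_from_sites(
    annotation: SiteAnnotation, curve: PartitionCurve
) -> float:
    """Predicted percent enrichment from a summed site tally.

    Total predicted sites plus the curve's baseline valency n are fed
    through the partition law; monotone in the site total.
    """
    return predict_enrichment(curve, annotation.total_sites + curve.n)
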