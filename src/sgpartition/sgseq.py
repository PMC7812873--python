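"""Granule-vs-total enrichment scores and cross-condition comparisons.

Works on two-compartment count tables (granule-purified RNA vs total
RNA, replicated). Each library is normalized to counts per million; a
transcript's enrichment score is the log2 granule/total CPM ratio
averaged across replicates. Comparison utilities cover the standard
questions asked of such tables: do two purification strategies or
conditions agree (Pearson r of shared transcripts), is a condition
effect length-dependent (length-binned score differences), and does
enrichment track an external covariate such as CLIP peak counts.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyDatasetError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .types import EnrichmentRecord, SGSeqTable

logger = logging.getLogger(__name__)

__all__ = [
    "enrichment_scores",
    "scores_to_fractions",
    "compare_transcriptomes",
    "length_binned_delta",
    "peak_count_correlation",
]


def enrichment_scores(
    table: SGSeqTable,
    pseudocount: float = 0.5,
    min_count: int = 10,
) -> list[EnrichmentRecord]:
    """Per-transcript log2 granule/total enrichment scores.

    Each library (column) is scaled to counts per million; the replicate-r
    score is log2((granule CPM + pc) / (total CPM + pc)) and the reported
    score is the mean over replicates. Transcripts whose raw count is
    below ``min_count`` in every library are dropped (tallied in a log
    message) — their ratios are dominated by the pseudocount.
    """
    if pseudocount <= 0:
        raise InvalidArgumentError("pseudocount must be positive")
    if table.granule.shape[0] == 0:
        raise EmptyDatasetError("count table has no transcripts")
    if table.granule.shape[1] != table.total.shape[1]:
        raise InvalidArgumentError("granule/total replicate counts differ")

    raw = pd.concat([table.granule, table.total], axis=1)
    keep = (raw >= min_count).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "dropping %d transcript(s) below min_count=%d in all libraries",
            dropped,
            min_count,
        )
    g = table.granule.loc[keep]
    t = table.total.loc[keep]
    g_cpm = g / g.sum(axis=0) * 1e6
    t_cpm = t / t.sum(axis=0) * 1e6

    rep_scores = np.log2(
        (g_cpm.to_numpy() + pseudocount) / (t_cpm.to_numpy() + pseudocount)
    )
    mean_abund = np.concatenate([g_cpm.to_numpy(), t_cpm.to_numpy()], axis=1).mean(
        axis=1
    )
    return [
        EnrichmentRecord(
            transcript_id=tid,
            score=float(rep_scores[i].mean()),
            mean_abundance=float(mean_abund[i]),
            replicate_scores=tuple(float(v) for v in rep_scores[i]),
        )
        for i, tid in enumerate(g.index)
    ]


def scores_to_fractions(records: Sequence[EnrichmentRecord]) -> pd.Series:
    """Convert log2 enrichment scores to granule fractions on [0, 1].

    Inverts the odds coupling used throughout: a score s corresponds to
    partition odds 2**s, hence fraction 2**s / (1 + 2**s). Library-size
    normalization only determines odds up to a global factor, so the
    fractions are comparable across transcripts (ranks are exact) but
    carry an overall scale uncertainty.
    """
    odds = np.array([2.0 ** r.score for r in records])
    frac = odds / (1.0 + odds)
    return pd.Series(frac, index=[r.transcript_id for r in records], name="fraction")


def _score_series(records: Sequence[EnrichmentRecord]) -> pd.Series:
    return pd.Series(
        [r.score for r in records], index=[r.transcript_id for r in records]
    )


def compare_transcriptomes(
    a: Sequence[EnrichmentRecord], b: Sequence[EnrichmentRecord]
) -> tuple[float, int]:
    """Pearson r of enrichment scores over shared transcripts.

    Returns (r, number of shared transcripts); symmetric in its arguments.
    """
    sa, sb = _score_series(a), _score_series(b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise InvalidArgumentError(
            f"need >= 3 shared transcripts, got {len(shared)}"
        )
    r, _ = stats.pearsonr(sa.loc[shared], sb.loc[shared])
    return float(r), int(len(shared))


def length_binned_delta(
    a: Sequence[EnrichmentRecord],
    b: Sequence[EnrichmentRecord],
    lengths: Mapping[str, float],
    bin_edges: Sequence[float],
) -> dict[str, np.ndarray]:
    """Score differences (a - b) for shared transcripts, binned by length.

    Bins are half-open [lo, hi) on transcript length in nucleotides; an
    empty bin maps to an empty array rather than raising.
    """
    if len(bin_edges) < 2:
        raise InvalidArgumentError("need at least two bin edges")
    sa, sb = _score_series(a), _score_series(b)
    shared = sa.index.intersection(sb.index)
    missing = [tid for tid in shared if tid not in lengths]
    if missing:
        raise InvalidArgumentError(
            f"lengths missing for {len(missing)} shared transcript(s), "
            f"e.g. {missing[0]!r}"
        )
    delta = (sa.loc[shared] - sb.loc[shared]).to_numpy()
    ln = np.array([lengths[tid] for tid in shared], dtype=float)
    out: dict[str, np.ndarray] = {}
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (ln >= lo) & (ln < hi)
        out[f"[{lo:g},{hi:g})"] = delta[mask]
    return out


def peak_count_correlation(
    records: Sequence[EnrichmentRecord],
    peak_counts: Mapping[str, int],
) -> tuple[float, float]:
    """(Spearman rho, Pearson r) of enrichment score vs external peak count.

    ``peak_counts`` is a per-transcript tally of binding sites (e.g. CLIP
    peaks); transcripts without a peak count are ignored.
    """
    pairs = [
        (r.score, peak_counts[r.transcript_id])
        for r in records
        if r.transcript_id in peak_counts
    ]
    if len(pairs) < 3:
        raise InvalidArgumentError("need >= 3 transcripts with both values")
    scores = np.array([s for s, _ in pairs])
    peaks = np.array([p for _, p in pairs], dtype=float)
    if np.ptp(peaks) == 0 or np.ptp(scores) == 0:
        raise UndefinedCorrelationError("zero variance in scores or peak counts")
    rho, _ = stats.spearmanr(scores, peaks)
    r, _ = stats.pearsonr(scores, peaks)
    return float(rho), float(r)
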