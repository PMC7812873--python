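"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the three kinds of input the analysis consumes:

* :func:`simulate_tethering_study` — per-cell smFISH spot tables for a
  tethering dose series (constructs with 0/5/7/25 tether sites), with
  cell-to-cell overdispersion around the partition curve;
* :func:`generate_transcript` — random RNA sequences with an exact,
  scanner-verified number of planted motif occurrences;
* :func:`simulate_sgseq` — two-compartment (granule-purified vs total)
  count tables in which each transcript's enrichment is driven by a known
  interaction count through the same partition curve.

All randomness flows from a single integer seed per call; identical
arguments give byte-identical results.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curve import predict_enrichment
from .errors import GenerationError, InvalidArgumentError
from .motifs import count_motif
from .types import (
    CellMeasurement,
    ConstructDataset,
    MotifSpec,
    PartitionCurve,
    SGSeqTable,
    SyntheticTranscript,
    TetheringStudy,
)

__all__ = [
    "simulate_tethering_study",
    "generate_transcript",
    "simulate_sgseq",
]

_BASES = np.array(list("ACGU"))

_IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}


def _draw_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Overdispersed counts: negative binomial with shape ``dispersion``
    (variance = mean + mean^2/dispersion); Poisson in the limit
    dispersion = inf or 0 (0 is read as 'no overdispersion')."""
    if dispersion <= 0 or np.isinf(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_tethering_study(
    curve: PartitionCurve,
    ks: Sequence[int],
    cells_per_construct: int = 30,
    spots_mean: float = 100.0,
    spots_dispersion: float = 10.0,
    cell_noise_concentration: float = 10.0,
    seed: int = 0,
) -> TetheringStudy:
    """Simulate per-cell spot counts for a tethering dose series.

    For a construct with k tether sites the expected in-granule fraction
    is E(k + n)/100 from the partition curve. Each cell draws its own
    fraction from a Beta distribution with that mean and the given
    concentration (alpha + beta), modelling the wide cell-to-cell spread
    seen in single-cell boxplots; its total cytoplasmic spot count is
    negative-binomial; spots in granules are then binomial.

    Parameters
    ----------
    curve
        Ground-truth partition law (its baseline n enters every construct).
    ks
        Tether-site counts, one construct each; must be distinct.
    cells_per_construct
        Cells imaged per construct (>= 1).
    spots_mean, spots_dispersion
        Mean and negative-binomial shape of per-cell total spot counts.
    cell_noise_concentration
        Beta concentration; larger is tighter around the curve mean.
    seed
        Single source of randomness.
    """
    if cells_per_construct < 1:
        raise InvalidArgumentError("cells_per_construct must be >= 1")
    if len(ks) == 0:
        raise InvalidArgumentError("ks must be non-empty")
    if spots_mean <= 0:
        raise InvalidArgumentError("spots_mean must be positive")
    if cell_noise_concentration <= 0:
        raise InvalidArgumentError("cell_noise_concentration must be positive")

    rng = np.random.default_rng(seed)
    constructs = []
    for k in ks:
        mean_frac = predict_enrichment(curve, k + curve.n) / 100.0
        totals = _draw_counts(rng, spots_mean, spots_dispersion, cells_per_construct)
        if mean_frac >= 1.0 - 1e-12:
            probs = np.ones(cells_per_construct)
        elif mean_frac <= 1e-12:
            probs = np.zeros(cells_per_construct)
        else:
            a = mean_frac * cell_noise_concentration
            b = (1.0 - mean_frac) * cell_noise_concentration
            probs = rng.beta(a, b, size=cells_per_construct)
        in_sg = rng.binomial(totals, probs)
        cells = tuple(
            CellMeasurement(
                cell_id=f"k{k}_cell{i + 1}",
                spots_total=int(t),
                spots_in_sg=int(s),
            )
            for i, (t, s) in enumerate(zip(totals, in_sg))
        )
        constructs.append(
            ConstructDataset(label=f"boxb{k}", tether_sites=int(k), cells=cells)
        )
    return TetheringStudy(constructs=tuple(constructs))


def _instantiate(rng: np.random.Generator, pattern: str) -> str:
    """Replace IUPAC ambiguity codes with concrete random bases."""
    return "".join(
        ch if len(_IUPAC_RNA[ch]) == 1 else rng.choice(list(_IUPAC_RNA[ch]))
        for ch in pattern
    )


def generate_transcript(
    length: int,
    plants: Sequence[tuple[Union[str, MotifSpec], int]] = (),
    forbidden: Sequence[Union[str, MotifSpec]] = (),
    seed: int = 0,
    transcript_id: str = "synthetic",
    max_tries: int = 500,
) -> SyntheticTranscript:
    """Random RNA with an exact number of occurrences of each planted motif.

    Background composition is uniform over A/C/G/U. Requested motifs are
    instantiated (ambiguity codes resolved at random) and spliced in at
    random non-overlapping positions; the whole sequence is then verified
    by the scanner, and regenerated if any planted motif matches more or
    fewer times than requested or any forbidden motif appears at all.

    Raises
    ------
    GenerationError
        If no satisfying sequence is found within ``max_tries`` attempts,
        naming the motif whose constraint failed last.
    """
    plant_specs = [
        (m if isinstance(m, MotifSpec) else MotifSpec(str(m), str(m)), int(cnt))
        for m, cnt in plants
    ]
    forb_specs = [
        m if isinstance(m, MotifSpec) else MotifSpec(str(m), str(m))
        for m in forbidden
    ]
    for spec, cnt in plant_specs:
        pat = spec.pattern.upper().replace("T", "U")
        bad = [ch for ch in pat if ch not in _IUPAC_RNA]
        if bad:
            raise InvalidArgumentError(
                f"motif {spec.name}: non-IUPAC symbol {bad[0]!r}"
            )
        if cnt < 0:
            raise InvalidArgumentError(f"motif {spec.name}: negative count")
    footprint = sum(len(s.pattern) * cnt for s, cnt in plant_specs)
    if footprint > length:
        raise InvalidArgumentError(
            f"planted footprint {footprint} exceeds sequence length {length}"
        )

    rng = np.random.default_rng(seed)
    last_failure = "background"
    for _ in range(max_tries):
        seq = rng.choice(_BASES, size=length)
        # greedy non-overlapping placement of all instances
        placements: list[tuple[int, str, str]] = []  # (start0, name, instance)
        occupied = np.zeros(length, dtype=bool)
        ok = True
        for spec, cnt in plant_specs:
            w = len(spec.pattern)
            for _i in range(cnt):
                placed = False
                for start in rng.permutation(length - w + 1):
                    if not occupied[start : start + w].any():
                        inst = _instantiate(rng, spec.pattern.upper().replace("T", "U"))
                        placements.append((int(start), spec.name, inst))
                        occupied[start : start + w] = True
                        placed = True
                        break
                if not placed:
                    ok = False
                    last_failure = spec.name
                    break
            if not ok:
                break
        if not ok:
            continue
        for start, _name, inst in placements:
            seq[start : start + len(inst)] = list(inst)
        sequence = "".join(seq)
        # verify with the scanner: exact planted counts, zero forbidden
        ok = True
        for spec, cnt in plant_specs:
            if count_motif(sequence, spec) != cnt:
                ok, last_failure = False, spec.name
                break
        if ok:
            for spec in forb_specs:
                if count_motif(sequence, spec) != 0:
                    ok, last_failure = False, spec.name
                    break
        if ok:
            sites = tuple(
                sorted((name, start + 1) for start, name, _ in placements)
            )
            return SyntheticTranscript(
                id=transcript_id, sequence=sequence, planted_sites=sites
            )
    raise GenerationError(
        f"could not satisfy motif constraints after {max_tries} attempts "
        f"(last failing motif: {last_failure})"
    )


def simulate_sgseq(
    n_transcripts: int,
    curve: PartitionCurve,
    interaction_counts: Optional[Sequence[int]] = None,
    count_range: tuple[int, int] = (1, 40),
    length_law: tuple[float, float] = (7.5, 0.6),
    depth: int = 1_000_000,
    replicates: int = 3,
    noise_dispersion: float = 0.0,
    seed: int = 0,
    abundance_sd: float = 1.0,
) -> SGSeqTable:
    """Two-compartment count tables driven by known interaction counts.

    Each transcript i has a true interaction count x_i; its expected
    granule:total abundance ratio is the partition odds
    E(x_i) / (100 - E(x_i)) from the curve, so transcripts with more
    granule contacts are more enriched. Baseline abundances are
    log-normal; per-library counts are Poisson at the expected depth
    share (negative binomial when ``noise_dispersion`` > 0, with shape
    1/noise_dispersion).

    Parameters
    ----------
    interaction_counts
        Explicit per-transcript counts; None samples uniform integers
        from the inclusive ``count_range``.
    length_law
        (mean, sd) of log transcript length in nt.
    depth
        Expected total counts per library.
    """
    if depth <= 0:
        raise InvalidArgumentError("depth must be positive")
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    rng = np.random.default_rng(seed)

    if interaction_counts is None:
        lo, hi = count_range
        x = rng.integers(int(lo), int(hi) + 1, size=n_transcripts).astype(float)
    else:
        x = np.asarray(list(interaction_counts), dtype=float)
        if x.size != n_transcripts:
            raise InvalidArgumentError(
                f"got {x.size} interaction counts for {n_transcripts} transcripts"
            )

    ids = [f"tx{i + 1:04d}" for i in range(n_transcripts)]
    lengths = np.maximum(
        50, np.round(rng.lognormal(length_law[0], length_law[1], n_transcripts))
    ).astype(int)
    abundance = rng.lognormal(0.0, abundance_sd, n_transcripts)

    e = np.array([predict_enrichment(curve, xi) for xi in x])
    e = np.minimum(e, 0.999 * curve.cap)  # keep partition odds finite
    odds = e / (100.0 - e)

    total_prop = abundance / abundance.sum()
    granule_w = abundance * odds
    granule_prop = granule_w / granule_w.sum()

    granule_cols, total_cols = {}, {}
    for r in range(1, replicates + 1):
        mu_g = depth * granule_prop
        mu_t = depth * total_prop
        if noise_dispersion <= 0:
            g = rng.poisson(mu_g)
            t = rng.poisson(mu_t)
        else:
            shape = 1.0 / noise_dispersion
            p_g = shape / (shape + mu_g)
            p_t = shape / (shape + mu_t)
            g = rng.negative_binomial(shape, p_g)
            t = rng.negative_binomial(shape, p_t)
        granule_cols[f"granule_rep{r}"] = g
        total_cols[f"total_rep{r}"] = t

    granule = pd.DataFrame(granule_cols, index=ids)
    total = pd.DataFrame(total_cols, index=ids)
    return SGSeqTable(
        granule=granule,
        total=total,
        lengths=pd.Series(lengths, index=ids, name="length"),
        true_interactions=pd.Series(x, index=ids, name="true_interactions"),
    )
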