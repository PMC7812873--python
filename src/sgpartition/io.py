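"""Tab-separated and FASTA I/O for every table the pipeline exchanges.

All tabular formats are plain TSV with a header row; optional comment
lines starting with '#' (used by the pipeline to record the config hash
and seed) are tolerated on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidArgumentError
from .types import (
    CellMeasurement,
    ConstructDataset,
    ConstructSummary,
    EnrichmentRecord,
    FitResult,
    SGSeqTable,
    SyntheticTranscript,
    TetheringStudy,
)

__all__ = [
    "write_tethering_study",
    "read_tethering_study",
    "write_summaries",
    "write_fasta",
    "read_fasta",
    "write_sgseq_table",
    "read_sgseq_table",
    "write_enrichment_records",
    "write_fit_result",
    "read_site_table",
]

PathLike = Union[str, Path]


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _header_lines(header_comments: Sequence[str]) -> str:
    return "".join(f"# {line}\n" for line in header_comments)


def write_tethering_study(
    study: TetheringStudy,
    path: PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    """Columns: construct, tether_sites, cell_id, spots_total, spots_in_sg."""
    rows = [
        {
            "construct": c.label,
            "tether_sites": c.tether_sites,
            "cell_id": cell.cell_id,
            "spots_total": cell.spots_total,
            "spots_in_sg": cell.spots_in_sg,
        }
        for c in study.constructs
        for cell in c.cells
    ]
    with open(path, "w") as fh:
        fh.write(_header_lines(header_comments))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_tethering_study(path: PathLike) -> TetheringStudy:
    df = _read_tsv(path)
    required = {"construct", "tether_sites", "cell_id", "spots_total", "spots_in_sg"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    constructs = []
    for (label, k), grp in df.groupby(["construct", "tether_sites"], sort=False):
        cells = tuple(
            CellMeasurement(
                cell_id=str(row.cell_id),
                spots_total=int(row.spots_total),
                spots_in_sg=int(row.spots_in_sg),
            )
            for row in grp.itertuples()
        )
        constructs.append(
            ConstructDataset(label=str(label), tether_sites=int(k), cells=cells)
        )
    return TetheringStudy(constructs=tuple(constructs))


def write_summaries(
    summaries: Iterable[ConstructSummary],
    path: PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    """Columns: label, k, n_cells, median, q1, q3 (fractions on [0,1])."""
    rows = [
        {
            "label": s.label,
            "k": s.tether_sites,
            "n_cells": s.n_cells,
            "median": s.median,
            "q1": s.q1,
            "q3": s.q3,
        }
        for s in summaries
    ]
    with open(path, "w") as fh:
        fh.write(_header_lines(header_comments))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_fasta(
    transcripts: Iterable[SyntheticTranscript],
    path: PathLike,
    as_dna: bool = False,
) -> None:
    """Write transcripts as FASTA; ``as_dna`` converts U to T."""
    records = []
    for t in transcripts:
        seq = t.sequence.replace("U", "T") if as_dna else t.sequence
        records.append(SeqRecord(Seq(seq), id=t.id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> list[SyntheticTranscript]:
    """Read FASTA records; T/U tolerant (sequences normalized to RNA)."""
    return [
        SyntheticTranscript(
            id=rec.id, sequence=str(rec.seq).upper().replace("T", "U")
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_sgseq_table(
    table: SGSeqTable,
    path: PathLike,
    truth_path: Optional[PathLike] = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Counts as TSV (transcript_id, length, granule_rep*, total_rep*);
    ground-truth interaction counts to an optional sidecar TSV."""
    df = pd.concat([table.lengths.rename("length"), table.granule, table.total], axis=1)
    df.index.name = "transcript_id"
    with open(path, "w") as fh:
        fh.write(_header_lines(header_comments))
        df.to_csv(fh, sep="\t")
    if truth_path is not None and table.true_interactions is not None:
        truth = table.true_interactions.rename("true_interactions").to_frame()
        truth.index.name = "transcript_id"
        truth.to_csv(truth_path, sep="\t")


def read_sgseq_table(
    path: PathLike, truth_path: Optional[PathLike] = None
) -> SGSeqTable:
    df = _read_tsv(path).set_index("transcript_id")
    gcols = [c for c in df.columns if c.startswith("granule_")]
    tcols = [c for c in df.columns if c.startswith("total_")]
    if not gcols or not tcols or "length" not in df.columns:
        raise InvalidArgumentError(
            f"{path}: need length, granule_* and total_* columns"
        )
    truth = None
    if truth_path is not None:
        tdf = _read_tsv(truth_path).set_index("transcript_id")
        truth = tdf["true_interactions"]
    return SGSeqTable(
        granule=df[gcols].astype(int),
        total=df[tcols].astype(int),
        lengths=df["length"],
        true_interactions=truth,
    )


def write_enrichment_records(
    records: Iterable[EnrichmentRecord],
    path: PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    rows = []
    for r in records:
        row = {
            "transcript_id": r.transcript_id,
            "score": r.score,
            "mean_abundance": r.mean_abundance,
        }
        for i, s in enumerate(r.replicate_scores, start=1):
            row[f"score_rep{i}"] = s
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(_header_lines(header_comments))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_fit_result(
    fit: FitResult,
    path: PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    """Per-n goodness-of-fit table with a selected-model header block."""
    curve = fit.curve
    selected = [
        f"selected_model: {curve.model}",
        f"selected_n: {curve.n}",
        f"selected_c: {curve.c:.6g}",
        f"selected_p: {curve.p:.6g}",
        f"selected_r: {fit.r:.6g}",
        f"cap: {curve.cap:.6g}",
    ]
    with open(path, "w") as fh:
        fh.write(_header_lines(tuple(header_comments) + tuple(selected)))
        fit.table.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_site_table(path: PathLike) -> pd.DataFrame:
    """External binding-site intervals: sequence_id, start, end (1-based
    inclusive), optionally a 'site' name column. Returns the parsed frame;
    per-sequence counts come from group sizes."""
    df = _read_tsv(path)
    required = {"sequence_id", "start", "end"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
        raise InvalidArgumentError(f"{path}: invalid 1-based inclusive intervals")
    return df
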