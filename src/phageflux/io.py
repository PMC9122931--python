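"""Readers and writers for the plain-text formats every pipeline stage touches.

All tabular interchange is tab-separated with a header row; lines starting
with ``#`` are comments.  Coordinates in tables are 1-based inclusive (BLAST
convention) and are converted to 0-based half-open here, once, at parse time.
Soft-masked (lowercase) bases are uppercased on input; the pipeline has no
masking semantics.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ContigRecord",
    "FluxRecord",
    "parse_fasta",
    "write_fasta",
    "parse_flux_table",
    "write_flux_table",
    "read_table",
    "write_table",
    "parse_alignment_table",
    "write_alignment_table",
]

_VALID_SEQ = re.compile(r"^[ACGTN]*$")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ContigRecord:
    """A DNA sequence with identity; the unit flowing through curation."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FluxRecord:
    """One sediment-trap collection interval with its particulate carbon flux.

    ``carbon_flux`` is in µmol C m⁻² d⁻¹.  ``is_sep`` (summer export pulse)
    is left ``None`` by the parser and set downstream against an externally
    supplied long-term reference mean.
    """

    sample_id: str
    interval_start: date
    interval_end: date
    carbon_flux: float
    is_sep: bool | None = None


def _open_text(path_or_stream, mode: str = "rt"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    p = Path(path_or_stream)
    if p.suffix == ".gz":
        return gzip.open(p, mode), True
    return open(p, mode), True


def parse_fasta(path_or_stream: Union[PathLike, TextIO]) -> list[ContigRecord]:
    """Parse FASTA text into :class:`ContigRecord` objects, order preserved.

    Wrapped sequence lines are concatenated and uppercased.  A duplicate id
    or a character outside ``{A, C, G, T, N}`` (either case) is a hard error.
    """
    handle, close = _open_text(path_or_stream)
    try:
        records: list[ContigRecord] = []
        seen: set[str] = set()
        for header, seq in SimpleFastaParser(handle):
            cid = header.split()[0] if header.split() else ""
            if not cid:
                raise ValueError("FASTA header with empty id")
            if cid in seen:
                raise ValueError(f"duplicate FASTA id: {cid!r}")
            seen.add(cid)
            seq = seq.upper()
            if not _VALID_SEQ.match(seq):
                pos = next(i for i, c in enumerate(seq) if c not in "ACGTN")
                raise ValueError(
                    f"record {cid!r}: invalid character {seq[pos]!r} at position {pos}"
                )
            records.append(ContigRecord(cid, seq))
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    records: Iterable[ContigRecord],
    path_or_stream: Union[PathLike, TextIO],
    width: int = 70,
) -> None:
    handle, close = _open_text(path_or_stream, "wt")
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def _parse_date(text: str, row: int) -> date:
    text = str(text).strip()
    for fmt in ("%Y-%m-%d", "%Y/%m/%d", "%d-%b-%Y"):
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"row {row}: unparseable date {text!r}")


def parse_flux_table(path: Union[PathLike, TextIO]) -> list[FluxRecord]:
    """Read a flux series TSV (sample_id, interval_start, interval_end,
    carbon_flux), returning records sorted by interval start."""
    df = read_table(path)
    required = {"sample_id", "interval_start", "interval_end", "carbon_flux"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flux table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        flux = float(row.carbon_flux)
        if flux <= 0:
            raise ValueError(f"row {i}: non-positive carbon flux {flux}")
        records.append(
            FluxRecord(
                sample_id=str(row.sample_id),
                interval_start=_parse_date(row.interval_start, i),
                interval_end=_parse_date(row.interval_end, i),
                carbon_flux=flux,
            )
        )
    records.sort(key=lambda r: (r.interval_start, r.sample_id))
    return records


def write_flux_table(records: Sequence[FluxRecord], path: Union[PathLike, TextIO]) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "interval_start": [r.interval_start.isoformat() for r in records],
            "interval_end": [r.interval_end.isoformat() for r in records],
            "carbon_flux": [r.carbon_flux for r in records],
            "is_sep": ["" if r.is_sep is None else int(r.is_sep) for r in records],
        }
    )
    write_table(df, path)


def read_table(path: Union[PathLike, TextIO]) -> pd.DataFrame:
    """Read a TSV with a header row; '#'-prefixed lines are comments."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})


def write_table(df: pd.DataFrame, path: Union[PathLike, TextIO]) -> None:
    df.to_csv(path, sep="\t", index=False)


# Alignment-hit tables use 1-based inclusive coordinates externally (the
# blastn/LAST tabular convention) and 0-based half-open intervals in memory.

_ALN_COLUMNS = [
    "query",
    "subject",
    "percent_identity",
    "aln_length",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
]


def parse_alignment_table(path: Union[PathLike, TextIO]):
    """Read an alignment-hit TSV into :class:`phageflux.seqops.AlignmentHit`
    objects, converting 1-based inclusive to 0-based half-open intervals.

    A ``sstart > send`` pair denotes a minus-strand subject interval.
    """
    from .seqops import AlignmentHit

    df = read_table(path)
    missing = set(_ALN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if sstart <= send else "-"
        if strand == "-":
            sstart, send = send, sstart
        hits.append(
            AlignmentHit(
                query_id=str(row.query),
                subject_id=str(row.subject),
                percent_identity=float(row.percent_identity),
                aln_length=int(row.aln_length),
                query_interval=(int(row.qstart) - 1, int(row.qend)),
                subject_interval=(sstart - 1, send),
                strand=strand,
                score=float(getattr(row, "score", 0.0)),
                query_length=int(row.query_length)
                if hasattr(row, "query_length") and not pd.isna(row.query_length)
                else None,
            )
        )
    return hits


def write_alignment_table(hits, path: Union[PathLike, TextIO]) -> None:
    rows = []
    for h in hits:
        s0, s1 = h.subject_interval
        sstart, send = (s0 + 1, s1) if h.strand == "+" else (s1, s0 + 1)
        rows.append(
            {
                "query": h.query_id,
                "subject": h.subject_id,
                "percent_identity": h.percent_identity,
                "aln_length": h.aln_length,
                "qstart": h.query_interval[0] + 1,
                "qend": h.query_interval[1],
                "sstart": sstart,
                "send": send,
                "evalue": 0.0,
                "score": h.score,
                "query_length": "" if h.query_length is None else h.query_length,
            }
        )
    write_table(pd.DataFrame(rows, columns=_ALN_COLUMNS + ["score", "query_length"]), path)
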