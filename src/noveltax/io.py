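"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython's ``SeqIO``; this module adds
the pipeline's base normalization (uppercase; non-ACGTN characters mapped to
N with a warning), the BLAST 12-column tabular dialect with conversion to
internal 0-based half-open coordinates, and deterministic TSV report
emission.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .records import AlignmentRecord, DatasetTag, SeqRecord

logger = logging.getLogger(__name__)

_ACGTN = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def normalize_bases(seq: str, record_id: str = "?") -> str:
    """Uppercase and map any non-ACGTN character (IUPAC codes etc.) to N."""
    seq = seq.upper()
    if set(seq) <= _ACGTN:
        return seq
    bad = sorted(set(seq) - _ACGTN)
    logger.warning("record %s: mapping non-ACGTN characters %s to N", record_id, bad)
    return "".join(b if b in _ACGTN else "N" for b in seq)


def read_fasta(
    path: Union[str, Path],
    dataset_tag: DatasetTag = DatasetTag.LONG_WGS,
) -> list[SeqRecord]:
    """Read a FASTA file into normalized :class:`SeqRecord` objects.

    Sample/subject tags are parsed from ``sample=... subject=...`` tokens in
    the description line when present.
    """
    path = Path(path)
    text_head = _first_content_line(path)
    if text_head is None:
        raise FormatError(f"{path}: empty file (line 1)")
    if not text_head[1].startswith(">"):
        raise FormatError(
            f"{path}: line {text_head[0]}: expected FASTA header starting "
            f"with '>', got {text_head[1][:30]!r}"
        )
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        sample, subject = _parse_tags(rec.description)
        records.append(
            SeqRecord(
                id=rec.id,
                bases=normalize_bases(str(rec.seq), rec.id),
                sample_id=sample,
                subject_id=subject,
                dataset_tag=dataset_tag,
            )
        )
    return records


def read_fastq(
    path: Union[str, Path],
    dataset_tag: DatasetTag = DatasetTag.SHORT_WGS,
) -> list[SeqRecord]:
    """Read a FASTQ file (qualities are carried but never used downstream)."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        sample, subject = _parse_tags(rec.description)
        records.append(
            SeqRecord(
                id=rec.id,
                bases=normalize_bases(str(rec.seq), rec.id),
                qualities=rec.letter_annotations.get("phred_quality"),
                sample_id=sample,
                subject_id=subject,
                dataset_tag=dataset_tag,
            )
        )
    if not records:
        raise FormatError(f"{path}: empty or malformed FASTQ (line 1)")
    return records


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = ""
            if rec.sample_id:
                desc += f" sample={rec.sample_id}"
            if rec.subject_id:
                desc += f" subject={rec.subject_id}"
            fh.write(f">{rec.id}{desc}\n{rec.bases}\n")


def write_fastq(records: Iterable[SeqRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.qualities or [30] * len(rec.bases)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qline}\n")


def _first_content_line(path: Path):
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip():
                return i, line
    return None


def _parse_tags(description: str) -> tuple[str, str]:
    sample = subject = ""
    for token in description.split():
        if token.startswith("sample="):
            sample = token[len("sample="):]
        elif token.startswith("subject="):
            subject = token[len("subject="):]
    return sample, subject


# -- BLAST 12-column tabular ----------------------------------------------

_BLAST_COLS = 12


def read_blast_tabular(path: Union[str, Path]) -> list[AlignmentRecord]:
    """Read alignments in the 12-column BLAST tabular dialect.

    Input coordinates are 1-based inclusive; minus-strand target hits are
    written with ``tstart > tend`` and are normalized here to a forward
    interval plus a strand flag.  Percent identity is rescaled to [0, 1].
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {_BLAST_COLS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            (q, t, pident, alen, mm, gapo, qs, qe, ts, te, _ev, bits) = fields
            ts_i, te_i = int(ts), int(te)
            strand = "+"
            if ts_i > te_i:
                strand = "-"
                ts_i, te_i = te_i, ts_i
            records.append(
                AlignmentRecord(
                    query_id=q,
                    target_id=t,
                    q_start=int(qs) - 1,
                    q_end=int(qe),
                    t_start=ts_i - 1,
                    t_end=te_i,
                    strand=strand,
                    identity=float(pident) / 100.0,
                    align_len=int(alen),
                    mismatches=int(mm),
                    gaps=int(gapo),
                    score=float(bits),
                )
            )
    return records


def write_blast_tabular(
    alignments: Iterable[AlignmentRecord], path: Union[str, Path]
) -> None:
    """Write alignments back to the 12-column dialect (inverse of reading)."""
    with open(path, "w") as fh:
        for a in alignments:
            ts, te = a.t_start + 1, a.t_end
            if a.strand == "-":
                ts, te = te, ts
            fh.write(
                "\t".join(
                    [
                        a.query_id,
                        a.target_id,
                        f"{a.identity * 100.0:.3f}",
                        str(a.align_len),
                        str(a.mismatches),
                        str(a.gaps),
                        str(a.q_start + 1),
                        str(a.q_end),
                        str(ts),
                        str(te),
                        "0.0",
                        f"{a.score:g}",
                    ]
                )
                + "\n"
            )


# -- TSV reports -----------------------------------------------------------


def write_report(rows: Sequence[dict], path: Union[str, Path], id_column: str) -> None:
    """Write one row per read/OTU, sorted lexicographically by ``id_column``.

    Re-running on the same input yields byte-identical output.
    """
    columns = list(rows[0].keys()) if rows else [id_column]
    df = pd.DataFrame(rows, columns=columns)
    if rows:
        df = df.sort_values(id_column, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
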