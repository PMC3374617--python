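"""Core record types shared across the pipeline.

All coordinates are 0-based half-open.  The only place 1-based inclusive
coordinates appear is at the BLAST-tabular boundary (see :mod:`noveltax.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class DatasetTag(str, Enum):
    """Which platform/protocol a sequence came from.

    Long amplicon reads (V1-3 or V3-5 hypervariable regions), long shotgun
    reads, short paired-end shotgun reads, or a reference-database entry.
    """

    AMPLICON_V13 = "AMPLICON_V13"
    AMPLICON_V35 = "AMPLICON_V35"
    LONG_WGS = "LONG_WGS"
    SHORT_WGS = "SHORT_WGS"
    REFERENCE = "REFERENCE"

    @property
    def is_amplicon(self) -> bool:
        return self in (DatasetTag.AMPLICON_V13, DatasetTag.AMPLICON_V35)


_VALID_BASES = frozenset("ACGTN")


@dataclass
class SeqRecord:
    """A DNA sequence over {A,C,G,T,N} with optional qualities and sample tags.

    Qualities are carried through the pipeline but never consulted by the
    validation logic, which operates on identity alone.
    """

    id: str
    bases: str
    qualities: Optional[Sequence[int]] = None
    sample_id: str = ""
    subject_id: str = ""
    dataset_tag: DatasetTag = DatasetTag.LONG_WGS

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGTN characters {sorted(bad)}; "
                "normalize with noveltax.io.normalize_bases first"
            )
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """One pairwise local alignment between a query and a target sequence.

    ``identity`` is matching columns over total alignment columns; gap
    columns count in the denominator.  ``strand`` is the query strand
    relative to the target; intervals are always given on the forward
    strand of the respective sequence.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # "+" or "-"
    identity: float
    align_len: int
    mismatches: int
    gaps: int
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.q_end < self.q_start or self.t_end < self.t_start:
            raise ValueError("interval end precedes start")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def t_interval(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)


@dataclass
class SupportAlignment:
    """A perfect (100%-identity) placement of a short read on a candidate.

    ``full_read_aligned`` is true when the whole read lies inside the
    candidate; otherwise the unaligned remainder overhangs a candidate end
    (which the validation rules permit as long as the aligned part is long
    enough).  Mate/fragment linkage is carried for the spanning-pair test.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    full_read_aligned: bool
    mate_id: Optional[str] = None
    fragment_id: Optional[str] = None

    identity: float = 1.0

    @property
    def span(self) -> int:
        return self.t_end - self.t_start

    @property
    def t_interval(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)


class PrimerCategory(str, Enum):
    EXACT = "EXACT"
    NEAR = "NEAR"  # 1-2 mismatches
    NO_OVERLAP = "NO_OVERLAP"


@dataclass
class PrimerHit:
    """A seeded, ungapped placement of an amplification primer on a read."""

    read_id: str
    primer_id: str
    mismatches: int
    read_start: int
    read_end: int
    strand: str = "+"

    @property
    def category(self) -> PrimerCategory:
        if self.mismatches == 0:
            return PrimerCategory.EXACT
        if self.mismatches in (1, 2):
            return PrimerCategory.NEAR
        return PrimerCategory.NO_OVERLAP


@dataclass
class NearestNeighborResult:
    """Outcome of the nearest-neighbor novelty screen for one read."""

    read_id: str
    neighbor_id: Optional[str] = None
    identity: Optional[float] = None
    align_len: Optional[int] = None
    passed_length_rules: bool = False
    is_novel_candidate: bool = False
    cultured_neighbor_id: Optional[str] = None
    cultured_identity: Optional[float] = None
    rule_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.identity is not None and self.neighbor_id is None:
            raise ValueError("identity without a neighbor")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]
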