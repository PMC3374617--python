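"""Alignment engines.

Two capabilities back the whole pipeline:

* :func:`align_short_reads` places short paired-end reads on candidate long
  reads by exact matching.  Validation support is defined as 100% identity,
  so exact matching is both sufficient and correct.  The whole read must
  align except for any portion overhanging a candidate end, in which case
  the aligned remainder must still reach the minimum support length.
* :func:`align_pairwise` finds the best-scoring local alignment of a query
  against each target on either strand (match +1, mismatch -1, gap open -2,
  gap extend -1 by default), used for nearest-neighbor novelty screening
  against a reference panel.  It is backed by Biopython's
  ``PairwiseAligner``.

Percent identity is matching columns over total alignment columns, gap
columns included in the denominator.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Optional

from Bio.Align import PairwiseAligner

from .config import ValidationConfig
from .records import (
    AlignmentRecord,
    PrimerHit,
    SeqRecord,
    SupportAlignment,
    revcomp,
)

# -- read pairing ------------------------------------------------------------

_MATE_RE = re.compile(r"^(?P<frag>.+?)(?:/(?P<mate>[12])|[._](?P<mate2>[12]))$")


def infer_pairing(read_id: str) -> tuple[Optional[str], Optional[str]]:
    """Return (fragment_id, mate_id) from "/1,/2"-style read id conventions.

    ``frag7/1`` -> (``frag7``, ``frag7/2``).  Unrecognized ids give
    ``(None, None)``.
    """
    m = _MATE_RE.match(read_id)
    if not m:
        return None, None
    frag = m.group("frag")
    mate = m.group("mate") or m.group("mate2")
    other = "2" if mate == "1" else "1"
    sep = read_id[len(frag)]
    return frag, f"{frag}{sep}{other}"


# -- exact-match short-read placement ---------------------------------------


class _CandidateIndex:
    """Seed index over one candidate: k-mer -> sorted start positions."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append(i)
        self.index = index

    def positions(self, word: str) -> list[int]:
        return self.index.get(word, [])


def _placements_on_candidate(
    idx: _CandidateIndex, read_seq: str, min_len: int
) -> list[tuple[int, int, int, int, bool]]:
    """All exact placements of ``read_seq`` (one strand) on the candidate.

    Returns (t_start, t_end, q_start, q_end, full_read) tuples where the
    q interval is on the oriented read sequence.  Placements are maximal:
    the overlap of read and candidate at the given offset matches exactly
    and is at least ``min_len`` long.
    """
    S, k, n, m = idx.seq, idx.k, len(idx.seq), len(read_seq)
    out: dict[int, tuple[int, int, int, int, bool]] = {}  # keyed by offset

    if m < min_len:
        return []

    if m >= k:
        # interior + right-overhang placements, seeded by the read prefix
        head = read_seq[:k]
        for p in idx.positions(head):
            if p + m <= n:
                if S[p : p + m] == read_seq:
                    out[p] = (p, p + m, 0, m, True)
            else:
                L = n - p
                if L >= min_len and S[p:] == read_seq[:L]:
                    out[p] = (p, n, 0, L, False)
        # left-overhang placements, seeded by the read suffix:
        # a suffix of the read of length L (min_len <= L < m) equals S[:L]
        tail = read_seq[-k:]
        for p in idx.positions(tail):
            L = p + k
            if min_len <= L < m and read_seq[-L:] == S[:L]:
                offset = -(m - L)
                out[offset] = (0, L, m - L, m, False)
    else:
        # read shorter than the seed (only possible with tiny candidates):
        # brute-force all offsets
        for p in range(n - m + 1):
            if S[p : p + m] == read_seq:
                out[p] = (p, p + m, 0, m, True)

    if m > n >= min_len:
        # read longer than the candidate: the candidate itself may sit
        # inside the read (both read ends overhang)
        start = read_seq.find(S)
        while start != -1:
            out[-start] = (0, n, start, start + n, False)
            start = read_seq.find(S, start + 1)

    return list(out.values())


def align_short_reads(
    candidates: list[SeqRecord],
    short_reads: list[SeqRecord],
    cfg: ValidationConfig,
) -> list[SupportAlignment]:
    """Exact-match placement of short reads on candidates, both strands.

    Every reported alignment is an exact substring match of the short read
    (or its reverse complement) within the candidate, or an exact match of
    a read prefix/suffix of length >= ``cfg.support_min_len`` whose
    remainder overhangs a candidate end.  All such placements are reported;
    mate/fragment linkage is inferred from read-id conventions.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    min_len = cfg.support_min_len
    k = min_len
    supports: list[SupportAlignment] = []
    for cand in candidates:
        idx = _CandidateIndex(cand.bases, min(k, len(cand.bases)))
        for read in short_reads:
            if len(read.bases) < min_len:
                continue
            frag, mate = infer_pairing(read.id)
            for strand, oriented in (("+", read.bases), ("-", revcomp(read.bases))):
                for ts, te, qs, qe, full in _placements_on_candidate(
                    idx, oriented, min_len
                ):
                    if strand == "-":
                        qs, qe = len(oriented) - qe, len(oriented) - qs
                    supports.append(
                        SupportAlignment(
                            query_id=read.id,
                            target_id=cand.id,
                            q_start=qs,
                            q_end=qe,
                            t_start=ts,
                            t_end=te,
                            strand=strand,
                            full_read_aligned=full,
                            mate_id=mate,
                            fragment_id=frag,
                        )
                    )
    return supports


# -- general local alignment -------------------------------------------------


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _best_alignment(aligner: PairwiseAligner, target: str, query: str):
    alns = aligner.align(target, query)
    try:
        return alns[0]
    except IndexError:
        return None


def align_pairwise(
    query: SeqRecord,
    targets: list[SeqRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> list[AlignmentRecord]:
    """Best local alignment of the query against each target, either strand.

    For each target, both the query and its reverse complement are aligned
    and the better-scoring placement kept (ties prefer the forward strand).
    Identity is matches / alignment columns (gaps in the denominator).
    Results are ordered by the input target order.
    """
    if len(query.bases) < 30:
        raise ValueError(f"query {query.id!r} shorter than 30 bases")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    rc = revcomp(query.bases)
    out = []
    for target in targets:
        best = None
        for strand, qseq in (("+", query.bases), ("-", rc)):
            aln = _best_alignment(aligner, target.bases, qseq)
            if aln is None:
                continue
            if best is None or aln.score > best[1].score:
                best = (strand, aln)
        if best is None:
            continue
        strand, aln = best
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.internal_gaps
        qs, qe = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
        if strand == "-":
            qs, qe = len(query.bases) - qe, len(query.bases) - qs
        out.append(
            AlignmentRecord(
                query_id=query.id,
                target_id=target.id,
                q_start=qs,
                q_end=qe,
                t_start=int(aln.coordinates[0][0]),
                t_end=int(aln.coordinates[0][-1]),
                strand=strand,
                identity=counts.identities / columns if columns else 0.0,
                align_len=columns,
                mismatches=counts.mismatches,
                gaps=counts.internal_gaps,
                score=float(aln.score),
            )
        )
    return out


# -- primer matching ---------------------------------------------------------


def match_primers(
    read: SeqRecord,
    primers: list[SeqRecord],
    word_size: int = 7,
) -> tuple[list[PrimerHit], int]:
    """Seeded, ungapped primer placement on a read, both strands.

    Every hit is seeded by an exact ``word_size``-mer shared between read
    and primer, then extended ungapped over the portion of the primer that
    overlaps the read; the mismatch count is over that overlap, which must
    be at least ``word_size`` long.  Also returns the longest run of
    consecutive read positions not covered by any hit with <=2 mismatches
    (the read's non-primer content).
    """
    if not primers:
        raise ValueError("no primers supplied")
    seq = read.bases
    read_index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - word_size + 1):
        read_index[seq[i : i + word_size]].append(i)

    hits: dict[tuple[str, str, int], PrimerHit] = {}
    for primer in primers:
        if len(primer.bases) < word_size:
            raise ValueError(f"primer {primer.id!r} shorter than word size")
        for strand, pseq in (("+", primer.bases), ("-", revcomp(primer.bases))):
            for j in range(len(pseq) - word_size + 1):
                word = pseq[j : j + word_size]
                for q in read_index.get(word, []):
                    offset = q - j  # read position of primer base 0
                    rs = max(0, offset)
                    re_ = min(len(seq), offset + len(pseq))
                    if re_ - rs < word_size:
                        continue
                    mm = sum(
                        1
                        for pos in range(rs, re_)
                        if seq[pos] != pseq[pos - offset]
                    )
                    key = (primer.id, strand, offset)
                    if key not in hits or mm < hits[key].mismatches:
                        hits[key] = PrimerHit(
                            read_id=read.id,
                            primer_id=primer.id,
                            mismatches=mm,
                            read_start=rs,
                            read_end=re_,
                            strand=strand,
                        )

    hit_list = sorted(
        hits.values(), key=lambda h: (h.read_start, h.primer_id, h.strand)
    )
    covered = [False] * len(seq)
    for h in hit_list:
        if h.mismatches <= 2:
            for i in range(h.read_start, h.read_end):
                covered[i] = True
    longest = run = 0
    for flag in covered:
        run = 0 if flag else run + 1
        longest = max(longest, run)
    return hit_list, longest
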