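"""Nearest-neighbor novelty screening.

A read is a novelty candidate when its nearest qualifying database neighbor
is below the identity ceiling (default 97%, strict), or when no alignment
qualifies at all.  Qualifying alignments must be at least 100 bp long and,
at each query end independently, leave at most 5 unaligned query bases
unless that end's unaligned remainder overhangs the corresponding target
end.  Among qualifying alignments the highest-scoring one is the nearest
neighbor; ties break deterministically by higher identity, then leftmost
target start, then target id.

Dereplication collapses reads matching an existing representative at 100%
identity over 95% of the shorter read's length; the same greedy
length-sorted engine backs OTU clustering at 97%.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

from .aligners import align_pairwise
from .config import ValidationConfig
from .records import AlignmentRecord, NearestNeighborResult, PrimerHit, SeqRecord


# -- dereplication / greedy identity clustering ------------------------------


def greedy_cluster(
    reads: Sequence[SeqRecord],
    identity: float,
    coverage: float,
    match_fn: Optional[Callable[[SeqRecord, SeqRecord], AlignmentRecord | None]] = None,
) -> list[tuple[SeqRecord, list[str]]]:
    """Greedy length-sorted clustering.

    Reads are visited by decreasing length (ties by id, for determinism);
    each joins the first existing cluster whose representative it matches at
    >= ``identity`` over >= ``coverage`` of the shorter sequence's length,
    else founds a new cluster.  The representative is the longest (first)
    member.  Returns (representative, member ids) per cluster; the union of
    members is the input.
    """
    if match_fn is None:
        match_fn = _best_pairwise
    ordered = sorted(reads, key=lambda r: (-len(r.bases), r.id))
    clusters: list[tuple[SeqRecord, list[str]]] = []
    for read in ordered:
        placed = False
        for rep, members in clusters:
            aln = match_fn(read, rep)
            if aln is None:
                continue
            shorter = min(len(read.bases), len(rep.bases))
            if aln.identity >= identity and aln.align_len >= coverage * shorter:
                members.append(read.id)
                placed = True
                break
        if not placed:
            clusters.append((read, [read.id]))
    return clusters


def _best_pairwise(read: SeqRecord, rep: SeqRecord) -> AlignmentRecord | None:
    alns = align_pairwise(read, [rep])
    return alns[0] if alns else None


def dereplicate(
    reads: Sequence[SeqRecord], cfg: ValidationConfig
) -> list[tuple[SeqRecord, list[str]]]:
    """Collapse near-duplicate reads (100% identity over 95% by default)."""
    return greedy_cluster(reads, cfg.derep_identity, cfg.derep_coverage)


# -- nearest neighbor ---------------------------------------------------------


def _end_rule_ok(
    aln: AlignmentRecord, query_len: int, target_len: int, max_unaligned: int
) -> bool:
    """Per-end unaligned-query rule with the target-overhang exemption.

    An end passes when its unaligned query bases are <= ``max_unaligned``
    or when they extend past the corresponding target end (the database
    entry simply stops there, so the read cannot be penalized).  On the
    minus strand the query's left end corresponds to the target's right
    end and vice versa.
    """
    un_left = aln.q_start
    un_right = query_len - aln.q_end
    room_t_left = aln.t_start
    room_t_right = target_len - aln.t_end
    if aln.strand == "-":
        room_left, room_right = room_t_right, room_t_left
    else:
        room_left, room_right = room_t_left, room_t_right
    left_ok = un_left <= max_unaligned or un_left > room_left
    right_ok = un_right <= max_unaligned or un_right > room_right
    return left_ok and right_ok


def pick_nearest_neighbor(
    read: SeqRecord,
    alignments: Iterable[AlignmentRecord],
    cfg: ValidationConfig,
    target_lengths: Optional[dict[str, int]] = None,
    min_align_len: Optional[int] = None,
    min_coverage: Optional[float] = None,
    restrict_to: Optional[set[str]] = None,
) -> NearestNeighborResult:
    """Filter alignments by the length/end rules and pick the best survivor.

    ``target_lengths`` is needed to evaluate the overhang exemption; when a
    target's length is unknown the exemption is assumed not to apply.
    ``min_coverage`` adds the amplicon-style requirement that the alignment
    cover at least that fraction of the read.  ``restrict_to`` limits the
    search to a target subset (e.g. cultured database entries).
    """
    min_len = cfg.nn_min_align_len if min_align_len is None else min_align_len
    qlen = len(read.bases)
    survivors = []
    for aln in alignments:
        if aln.query_id != read.id:
            raise ValueError(
                f"alignment query {aln.query_id!r} does not match read {read.id!r}"
            )
        if restrict_to is not None and aln.target_id not in restrict_to:
            continue
        if aln.align_len < min_len:
            continue
        if min_coverage is not None and aln.align_len < min_coverage * qlen:
            continue
        tlen = (target_lengths or {}).get(aln.target_id, 10 ** 9)
        if not _end_rule_ok(aln, qlen, tlen, cfg.nn_max_unaligned_end):
            continue
        survivors.append(aln)

    if not survivors:
        return NearestNeighborResult(
            read_id=read.id,
            passed_length_rules=False,
            is_novel_candidate=True,
            rule_flags=["no_qualifying_alignment"],
        )
    best = max(
        survivors,
        key=lambda a: (a.score, a.identity, -a.t_start, _neg_lex(a.target_id)),
    )
    return NearestNeighborResult(
        read_id=read.id,
        neighbor_id=best.target_id,
        identity=best.identity,
        align_len=best.align_len,
        passed_length_rules=True,
        is_novel_candidate=best.identity < cfg.novelty_identity_max,
    )


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def relax_for_primer_context(
    read: SeqRecord,
    primer_hits: Sequence[PrimerHit],
    longest_nonprimer_run: int,
    alignments: Iterable[AlignmentRecord],
    cfg: ValidationConfig,
    target_lengths: Optional[dict[str, int]] = None,
) -> NearestNeighborResult:
    """Re-screen a primer-dominated read with a relaxed length requirement.

    Applies only to reads whose longest stretch of consecutive non-primer
    sequence is shorter than the standard minimum alignment length; the
    minimum is relaxed to that stretch so database entries that merely lack
    the (often-trimmed) primer sequence can still qualify as neighbors.
    """
    if longest_nonprimer_run >= cfg.nn_min_align_len:
        raise ValueError(
            f"read {read.id!r} has {longest_nonprimer_run} bases of "
            "consecutive non-primer sequence; relaxation applies only below "
            f"{cfg.nn_min_align_len}"
        )
    result = pick_nearest_neighbor(
        read,
        alignments,
        cfg,
        target_lengths=target_lengths,
        min_align_len=longest_nonprimer_run,
    )
    result.rule_flags.append(f"relaxed_min_align_len={longest_nonprimer_run}")
    if longest_nonprimer_run == 0:
        result.rule_flags.append("degenerate_all_primer")
    return result


def cultured_nearest_neighbor(
    read: SeqRecord,
    alignments: Iterable[AlignmentRecord],
    cultured_ids: set[str],
    cfg: ValidationConfig,
    target_lengths: Optional[dict[str, int]] = None,
) -> tuple[Optional[str], Optional[float]]:
    """Nearest neighbor restricted to cultured database entries."""
    if not cultured_ids:
        return None, None
    res = pick_nearest_neighbor(
        read, alignments, cfg, target_lengths=target_lengths, restrict_to=cultured_ids
    )
    return res.neighbor_id, res.identity


# -- high-level screen ---------------------------------------------------------


def screen_reads(
    reads: Sequence[SeqRecord],
    references: Sequence[SeqRecord],
    cfg: ValidationConfig,
    cultured_ids: Optional[set[str]] = None,
    min_coverage: Optional[float] = None,
) -> list[NearestNeighborResult]:
    """Align each read to the reference panel and screen it for novelty.

    ``min_coverage`` switches on the amplicon-style pre-filter that only
    lets alignments covering that fraction of the read disqualify it.
    """
    tlens = {r.id: len(r.bases) for r in references}
    results = []
    for read in reads:
        alns = align_pairwise(read, list(references))
        res = pick_nearest_neighbor(
            read, alns, cfg, target_lengths=tlens, min_coverage=min_coverage
        )
        if cultured_ids:
            cid, cident = cultured_nearest_neighbor(
                read, alns, cultured_ids, cfg, target_lengths=tlens
            )
            res.cultured_neighbor_id = cid
            res.cultured_identity = cident
        results.append(res)
    return results
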