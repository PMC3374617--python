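"""Database-independent validation of candidate long reads.

A candidate is validated purely from the geometry of perfect short-read
alignments laid across it, in four ordered checks:

1. **Breadth** — shotgun candidates must be covered over 100% of their
   length; amplicon candidates over strictly more than 95%.
2. **Valley** — the per-start maximum aligned-read length must not dip to
   <= ``valley_floor`` (70) between two shoulders of >= ``valley_shoulder``
   (90).  Such a dip-and-recovery marks a junction or error that no perfect
   read can cross; reads cannot start right before the barrier unless they
   are short enough to end at it, so the profile tapers and then snaps back.
   A terminal window one read-length wide is exempt (reads are naturally
   truncated at the candidate end).
3. **Tiling path** — a chain of alignments each overlapping the previous by
   >= 20 bases and extending coverage by >= 20 bases (the extension waived
   for the final chain step reaching the last covered base) must span the
   candidate to the dataset breadth rule.
4. **Spanning pair** — for long (>200 bp), deeply covered (median depth
   >500) candidates, some sequenced fragment must have both mates aligned
   with an outer span of >= 90% of the candidate.

The first failed check sets the verdict status; all raw evidence is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .config import ValidationConfig
from .records import DatasetTag, SeqRecord, SupportAlignment


@dataclass
class CoverageProfile:
    """Per-position depth and per-start maximum aligned length."""

    candidate_id: str
    length: int
    depth: np.ndarray
    max_len_at_start: np.ndarray
    breadth: float
    median_depth: float

    @classmethod
    def empty(cls, candidate_id: str, length: int) -> "CoverageProfile":
        return cls(
            candidate_id=candidate_id,
            length=length,
            depth=np.zeros(length, dtype=int),
            max_len_at_start=np.zeros(length, dtype=int),
            breadth=0.0,
            median_depth=0.0,
        )


class TilingStatus(str, Enum):
    VALIDATED = "VALIDATED"
    INSUFFICIENT_BREADTH = "INSUFFICIENT_BREADTH"
    VALLEY_IRREGULARITY = "VALLEY_IRREGULARITY"
    NO_TILING_PATH = "NO_TILING_PATH"
    NO_SPANNING_PAIR = "NO_SPANNING_PAIR"
    # Retained for callers who wish to re-label validated candidates whose
    # spanning-pair test was inapplicable; ``classify`` itself reports
    # VALIDATED in that case and records ``pair_test_applied``.
    PAIR_TEST_NOT_APPLICABLE_VALIDATED = "PAIR_TEST_NOT_APPLICABLE_VALIDATED"


@dataclass
class TilingVerdict:
    candidate_id: str
    status: TilingStatus
    breadth: float
    valley: Optional[tuple[int, int]] = None  # (position, min value)
    tiling_path: Optional[list[int]] = None  # indices into the support list
    spanning_pair: Optional[tuple[str, float]] = None  # (fragment, span frac)
    pair_test_applied: bool = False
    median_depth: float = 0.0
    notes: list[str] = field(default_factory=list)

    @property
    def is_validated(self) -> bool:
        return self.status in (
            TilingStatus.VALIDATED,
            TilingStatus.PAIR_TEST_NOT_APPLICABLE_VALIDATED,
        )


# -- profile -------------------------------------------------------------------


def build_profile(
    candidate: SeqRecord, supports: Sequence[SupportAlignment]
) -> CoverageProfile:
    """Depth vector, per-start maximum aligned length, breadth and median."""
    n = len(candidate.bases)
    depth = np.zeros(n + 1, dtype=int)
    max_len = np.zeros(n, dtype=int)
    for s in supports:
        if s.target_id != candidate.id:
            raise ValueError(
                f"support for {s.target_id!r} applied to candidate {candidate.id!r}"
            )
        if not (0 <= s.t_start < s.t_end <= n):
            raise ValueError(
                f"support interval [{s.t_start}, {s.t_end}) outside candidate "
                f"of length {n}"
            )
        depth[s.t_start] += 1
        depth[s.t_end] -= 1
        span = s.t_end - s.t_start
        if span > max_len[s.t_start]:
            max_len[s.t_start] = span
    depth = np.cumsum(depth[:-1])
    covered = int(np.count_nonzero(depth))
    return CoverageProfile(
        candidate_id=candidate.id,
        length=n,
        depth=depth,
        max_len_at_start=max_len,
        breadth=covered / n,
        median_depth=float(np.median(depth)),
    )


def check_breadth(
    profile: CoverageProfile, dataset_tag: DatasetTag, cfg: ValidationConfig
) -> tuple[bool, float]:
    return cfg.breadth_passes(profile.breadth, dataset_tag), profile.breadth


# -- valley --------------------------------------------------------------------


def detect_valley(
    profile: CoverageProfile,
    cfg: ValidationConfig,
    short_read_max_len: int,
) -> Optional[tuple[int, int]]:
    """Shoulder-floor-shoulder dip in the per-start maximum-length profile.

    Scans start positions carrying at least one alignment, excluding the
    terminal window ``[length - short_read_max_len, length)`` where aligned
    lengths are truncated by the candidate end.  Reports the position of
    the deepest qualifying floor (<= ``valley_floor``) that sits strictly
    between two shoulders (>= ``valley_shoulder``), or None.
    """
    ml = profile.max_len_at_start
    cutoff = max(0, profile.length - short_read_max_len)
    positions = [i for i in range(cutoff) if ml[i] > 0]
    if not positions:
        return None
    shoulders = [i for i in positions if ml[i] >= cfg.valley_shoulder]
    if len(shoulders) < 2:
        return None
    best: Optional[tuple[int, int]] = None
    first_sh, last_sh = shoulders[0], shoulders[-1]
    for b in positions:
        if ml[b] > cfg.valley_floor:
            continue
        if not (first_sh < b < last_sh):
            continue
        if best is None or ml[b] < best[1]:
            best = (b, int(ml[b]))
    return best


# -- tiling path ---------------------------------------------------------------


def find_tiling_path(
    candidate: SeqRecord,
    supports: Sequence[SupportAlignment],
    dataset_tag: DatasetTag,
    cfg: ValidationConfig,
) -> Optional[list[int]]:
    """Greedy farthest-reach chaining of support alignments.

    Starts from the leftmost-starting alignment (largest end among those
    sharing that start) and repeatedly takes, among alignments starting at
    <= current_end - ``tiling_min_overlap``, the one reaching farthest.
    Each step must extend coverage by >= ``tiling_min_extend``, except that
    a step reaching the candidate's final covered base is exempt.  Succeeds
    when the chained span satisfies the dataset breadth rule; returns
    indices into ``supports`` in chain order, or None.
    """
    if not supports:
        return None
    # chain geometry depends only on the interval, so deduplicate
    by_interval: dict[tuple[int, int], int] = {}
    for i, s in enumerate(supports):
        by_interval.setdefault((s.t_start, s.t_end), i)
    intervals = sorted(by_interval)
    index_of = by_interval
    leftmost = intervals[0][0]
    final_end = max(e for _, e in intervals)
    n_cand = len(candidate.bases)

    def success(end: int) -> bool:
        return cfg.breadth_passes((end - leftmost) / n_cand, dataset_tag)

    def steps_from(cur_end: int) -> list[tuple[int, int]]:
        out = [
            (s, e)
            for s, e in intervals
            if s <= cur_end - cfg.tiling_min_overlap
            and e > cur_end
            and (e >= cur_end + cfg.tiling_min_extend or e == final_end)
        ]
        # farthest reach first, then leftmost start, for determinism
        out.sort(key=lambda iv: (-iv[1], iv[0]))
        return out

    starts = sorted(
        (iv for iv in intervals if iv[0] == leftmost), key=lambda iv: -iv[1]
    )

    # greedy farthest-reach fast path
    chain = [starts[0]]
    cur_end = starts[0][1]
    while not success(cur_end):
        nxt = steps_from(cur_end)
        if not nxt:
            break
        chain.append(nxt[0])
        cur_end = nxt[0][1]
    if success(cur_end):
        return [index_of[iv] for iv in chain]

    # complete search: continuation depends only on the current chain end,
    # so memoize per interval (ends strictly increase along a chain)
    memo: dict[tuple[int, int], Optional[list[tuple[int, int]]]] = {}

    def solve(iv: tuple[int, int]) -> Optional[list[tuple[int, int]]]:
        if iv in memo:
            return memo[iv]
        if success(iv[1]):
            memo[iv] = [iv]
            return memo[iv]
        memo[iv] = None  # cycle guard (ends strictly increase, so safe)
        for nxt in steps_from(iv[1]):
            tail = solve(nxt)
            if tail is not None:
                memo[iv] = [iv] + tail
                break
        return memo[iv]

    for start in starts:
        path = solve(start)
        if path is not None:
            return [index_of[iv] for iv in path]
    return None


# -- spanning pair -------------------------------------------------------------


def check_spanning_pair(
    candidate: SeqRecord,
    supports: Sequence[SupportAlignment],
    profile: CoverageProfile,
    cfg: ValidationConfig,
) -> tuple[bool, bool, Optional[tuple[str, float]]]:
    """Paired-end spanning test, gated on depth and candidate length.

    Applied only when median depth > ``pair_test_min_depth`` (strict) and
    candidate length > ``pair_test_min_len`` (strict).  Passes when some
    fragment has both mates aligned and the outer span (max end - min
    start across the fragment's alignments) reaches ``pair_span_frac`` of
    the candidate length.  Returns (applied, passed, best (fragment, span)).
    """
    applied = (
        profile.median_depth > cfg.pair_test_min_depth
        and len(candidate.bases) > cfg.pair_test_min_len
    )
    by_fragment: dict[str, dict[str, list[SupportAlignment]]] = {}
    for s in supports:
        if s.fragment_id is None:
            continue
        by_fragment.setdefault(s.fragment_id, {}).setdefault(s.query_id, []).append(s)

    best: Optional[tuple[str, float]] = None
    n = len(candidate.bases)
    for frag, mates in by_fragment.items():
        if len(mates) < 2:
            continue
        starts = [a.t_start for alns in mates.values() for a in alns]
        ends = [a.t_end for alns in mates.values() for a in alns]
        span = (max(ends) - min(starts)) / n
        if best is None or span > best[1]:
            best = (frag, span)
    passed = best is not None and best[1] >= cfg.pair_span_frac
    return applied, passed, best


# -- classification -------------------------------------------------------------


def classify(
    candidate: SeqRecord,
    supports: Sequence[SupportAlignment],
    dataset_tag: DatasetTag,
    cfg: ValidationConfig,
) -> TilingVerdict:
    """Ordered breadth -> valley -> tiling-path -> spanning-pair checks.

    The first failure sets the status; evidence fields are always
    populated.  The result is invariant to the order of ``supports``.
    """
    supports = sorted(
        supports, key=lambda s: (s.t_start, s.t_end, s.query_id, s.strand)
    )
    profile = build_profile(candidate, supports)
    short_read_max = max((s.span for s in supports), default=0)
    valley = detect_valley(profile, cfg, short_read_max)
    path_idx = find_tiling_path(candidate, supports, dataset_tag, cfg)
    path = (
        [supports[i].query_id for i in path_idx] if path_idx is not None else None
    )
    applied, pair_ok, best_pair = check_spanning_pair(
        candidate, supports, profile, cfg
    )

    breadth_ok, breadth = check_breadth(profile, dataset_tag, cfg)
    if not breadth_ok:
        status = TilingStatus.INSUFFICIENT_BREADTH
    elif valley is not None:
        status = TilingStatus.VALLEY_IRREGULARITY
    elif path is None:
        status = TilingStatus.NO_TILING_PATH
    elif applied and not pair_ok:
        status = TilingStatus.NO_SPANNING_PAIR
    else:
        status = TilingStatus.VALIDATED

    return TilingVerdict(
        candidate_id=candidate.id,
        status=status,
        breadth=breadth,
        valley=valley,
        tiling_path=path,
        spanning_pair=best_pair,
        pair_test_applied=applied,
        median_depth=profile.median_depth,
    )


def verdict_rows(verdicts: Sequence[TilingVerdict]) -> list[dict]:
    """Flatten verdicts for TSV reporting."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "candidate_id": v.candidate_id,
                "status": v.status.value,
                "breadth": f"{v.breadth:.6f}",
                "median_depth": v.median_depth,
                "valley_pos": v.valley[0] if v.valley else "",
                "valley_min": v.valley[1] if v.valley else "",
                "tiling_path_len": len(v.tiling_path) if v.tiling_path else 0,
                "pair_test_applied": v.pair_test_applied,
                "best_span_fragment": v.spanning_pair[0] if v.spanning_pair else "",
                "best_span_frac": (
                    f"{v.spanning_pair[1]:.6f}" if v.spanning_pair else ""
                ),
            }
        )
    return rows


def profile_rows(profile: CoverageProfile) -> list[dict]:
    """Per-position dump (position, depth, max aligned length at start)."""
    return [
        {
            "candidate_id": profile.candidate_id,
            "position": i,
            "depth": int(profile.depth[i]),
            "max_len_at_start": int(profile.max_len_at_start[i]),
        }
        for i in range(profile.length)
    ]
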