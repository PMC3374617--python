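"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive offset scans, textbook
dynamic programming, per-position counting and full chain enumeration.
None of it shares code with the package.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_placements(
    candidate: str, read: str, min_len: int
) -> set[tuple[int, int, str, bool]]:
    """Every exact placement of the read on the candidate, both strands.

    Scans all offsets, including those where the read overhangs either
    candidate end; the overlapping portion must match exactly and be at
    least ``min_len`` long.  Returns (t_start, t_end, strand, full_read).
    """
    out = set()
    n, m = len(candidate), len(read)
    for strand in ("+", "-"):
        oriented = read if strand == "+" else rc(read)
        for offset in range(-m + 1, n):
            t_lo = max(0, offset)
            t_hi = min(n, offset + m)
            L = t_hi - t_lo
            if L < min_len:
                continue
            if candidate[t_lo:t_hi] == oriented[t_lo - offset : t_hi - offset]:
                full = offset >= 0 and offset + m <= n
                out.add((t_lo, t_hi, strand, full))
    return out


def gotoh_local_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Textbook affine-gap local alignment score (Gotoh).

    Gap scoring follows the "first gap position costs ``gap_open``, each
    further position ``gap_extend``" convention.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            diag = H[i - 1][j - 1] + (match if ai == b[j - 1] else mismatch)
            h = max(0.0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return best


def brute_force_depth(length: int, intervals: list[tuple[int, int]]) -> list[int]:
    """Per-position coverage by direct counting."""
    depth = [0] * length
    for s, e in intervals:
        for p in range(s, e):
            depth[p] += 1
    return depth


def brute_force_max_len_at_start(
    length: int, intervals: list[tuple[int, int]]
) -> list[int]:
    out = [0] * length
    for s, e in intervals:
        out[s] = max(out[s], e - s)
    return out


def chain_exists(
    intervals: list[tuple[int, int]],
    candidate_len: int,
    min_overlap: int,
    min_extend: int,
    required_span: float,
    strict_span: bool,
) -> bool:
    """Exhaustive enumeration of valid tiling chains.

    A chain starts on any interval beginning at the leftmost covered base
    and repeatedly appends an interval starting at <= current_end -
    ``min_overlap`` that strictly advances the end, extending by at least
    ``min_extend`` unless it reaches the overall final covered base.
    Success when the covered span fraction meets ``required_span``.
    """
    if not intervals:
        return False
    uniq = sorted(set(intervals))
    leftmost = uniq[0][0]
    final_end = max(e for _, e in uniq)

    def ok(end: int) -> bool:
        frac = (end - leftmost) / candidate_len
        return frac > required_span if strict_span else frac >= required_span

    seen: set[int] = set()

    def explore(cur_end: int) -> bool:
        if ok(cur_end):
            return True
        if cur_end in seen:
            return False
        seen.add(cur_end)
        for s, e in uniq:
            if (
                s <= cur_end - min_overlap
                and e > cur_end
                and (e >= cur_end + min_extend or e == final_end)
            ):
                if explore(e):
                    return True
        return False

    return any(explore(e) for s, e in uniq if s == leftmost)
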