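"""Synthetic communities and reads with ground truth.

The generator emulates the statistical regime the pipeline was designed
for: a panel of ~1.5 kb 16S-like reference sequences at controlled pairwise
divergence, "novel" variants at 90-96% identity to their nearest reference,
long reads (amplicon- or shotgun-like) carrying substitutions, indels,
uncalled bases and bimeric chimeric joins, and paired-end short reads drawn
from 100-500 bp fragments.

Everything is driven by a single integer seed; identical specs produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aligners import align_pairwise
from .records import DatasetTag, SeqRecord, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class CommunitySpec:
    """Composition of a synthetic reference panel plus planted novel taxa.

    ``novel_taxa`` lists (parent reference index, target identity) pairs;
    targets must sit below the novelty ceiling (0.90-0.96 is the intended
    band).  ``abundances`` covers references followed by novel taxa and
    defaults to uniform.
    """

    n_taxa: int = 5
    seq_length: int = 1500
    min_pairwise_divergence: float = 0.03
    novel_taxa: list[tuple[int, float]] = field(default_factory=list)
    abundances: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not 0.0 <= self.min_pairwise_divergence < 0.5:
            raise ValueError("min_pairwise_divergence outside [0, 0.5)")
        if self.min_pairwise_divergence * self.seq_length > 0.4 * self.seq_length:
            raise ValueError("divergence unattainable at this length")
        for parent, ident in self.novel_taxa:
            if not 0 <= parent < self.n_taxa:
                raise ValueError(f"novel parent index {parent} out of range")
            if not 0.5 < ident < 0.97:
                raise ValueError(
                    f"novel target identity {ident} must be below the 0.97 "
                    "novelty ceiling"
                )
        n_total = self.n_taxa + len(self.novel_taxa)
        if self.abundances is not None:
            ab = np.asarray(self.abundances, dtype=float)
            if len(ab) != n_total or not np.isclose(ab.sum(), 1.0):
                raise ValueError("abundances must cover all taxa and sum to 1")


@dataclass
class Community:
    """All taxa (references first, then novel variants) plus truth labels."""

    taxa: list[SeqRecord]
    n_references: int
    truth: pd.DataFrame  # taxon_id, parent_id, realized_identity, is_novel
    abundances: np.ndarray

    @property
    def references(self) -> list[SeqRecord]:
        return self.taxa[: self.n_references]

    @property
    def novels(self) -> list[SeqRecord]:
        return self.taxa[self.n_references :]


@dataclass
class LongReadSpec:
    """Long-read simulation: window sampling plus per-base error processes."""

    n_reads: int = 50
    length_range: tuple[int, int] = (100, 600)
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    n_rate: float = 0.0
    chimera_fraction: float = 0.0
    junction_guard_k: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "n_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name}={r} outside [0, 1)")
        if not 0.0 <= self.chimera_fraction <= 1.0:
            raise ValueError("chimera_fraction outside [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 30:
            raise ValueError("invalid length_range")


@dataclass
class ShortReadSpec:
    """Paired-end short-read simulation from uniform-length fragments.

    ``read_length`` may be a single integer (length-trimmed libraries; the
    default 100 matches typical paired-end shotgun data) or a (min, max)
    tuple for heterogeneous read lengths in the 60-100 band.
    """

    read_length: int | tuple[int, int] = 100
    insert_range: tuple[int, int] = (100, 500)
    mean_depth: float = 50.0
    error_free: bool = True
    sub_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self._length_bounds()
        if lo < 20:
            raise ValueError("read_length too small")
        if self.insert_range[0] > self.insert_range[1]:
            raise ValueError("insert_min > insert_max")
        if hi > self.insert_range[0]:
            raise ValueError("read_length exceeds the minimum insert size")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def _length_bounds(self) -> tuple[int, int]:
        if isinstance(self.read_length, tuple):
            return self.read_length
        return self.read_length, self.read_length

    def draw_length(self, rng: np.random.Generator) -> int:
        lo, hi = self._length_bounds()
        if lo == hi:
            return lo
        return int(rng.integers(lo, hi + 1))


# -- community -----------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _substitute(
    seq: str, positions: Sequence[int], rng: np.random.Generator
) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _pairwise_identity(a: SeqRecord, b: SeqRecord) -> float:
    alns = align_pairwise(a, [b])
    return alns[0].identity if alns else 0.0


def generate_community(spec: CommunitySpec) -> Community:
    """Build the reference panel and planted novel variants.

    References are independent mutants of a common root, mutated until all
    pairwise identities drop to <= 1 - ``min_pairwise_divergence``
    (verified by alignment).  Each novel variant accumulates substitutions
    until its aligned identity to its parent falls within +-0.005 of the
    target; substitution-only divergence keeps the novelty signal separate
    from the indel-like platform errors of the long-read simulator.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length
    root = _random_seq(rng, L)
    n_mut = max(1, int(round(spec.min_pairwise_divergence * L)))
    refs: list[SeqRecord] = []
    for i in range(spec.n_taxa):
        positions = rng.choice(L, size=n_mut, replace=False)
        seq = _substitute(root, positions, rng)
        refs.append(
            SeqRecord(
                id=f"ref{i:03d}", bases=seq, dataset_tag=DatasetTag.REFERENCE
            )
        )
    # enforce the pairwise ceiling (usually already satisfied: two taxa at
    # divergence d from the root sit near 2d apart)
    target_ident = 1.0 - spec.min_pairwise_divergence
    for _ in range(50):
        violated = False
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                if _pairwise_identity(refs[i], refs[j]) > target_ident:
                    positions = rng.choice(L, size=max(1, n_mut // 4), replace=False)
                    refs[j] = SeqRecord(
                        id=refs[j].id,
                        bases=_substitute(refs[j].bases, positions, rng),
                        dataset_tag=DatasetTag.REFERENCE,
                    )
                    violated = True
        if not violated:
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("could not reach the requested pairwise divergence")

    rows = [
        {
            "taxon_id": r.id,
            "parent_id": "",
            "realized_identity": np.nan,
            "is_novel": False,
        }
        for r in refs
    ]
    taxa = list(refs)
    tol = 0.005
    for k, (parent_idx, target) in enumerate(spec.novel_taxa):
        parent = refs[parent_idx]
        # bulk substitutions at distinct positions land just above the
        # target; single substitutions (each moving identity by ~1/L, far
        # finer than the +-0.005 band) then walk it into the band
        order = rng.permutation(L)
        n_bulk = max(0, int((1.0 - target) * L) - 8)
        seq = _substitute(parent.bases, order[:n_bulk], rng)
        used = n_bulk
        novel = SeqRecord(
            id=f"novel{k:03d}", bases=seq, dataset_tag=DatasetTag.REFERENCE
        )
        realized = _pairwise_identity(novel, parent)
        while realized > target + tol and used < L:
            novel = SeqRecord(
                id=novel.id,
                bases=_substitute(novel.bases, [order[used]], rng),
                dataset_tag=DatasetTag.REFERENCE,
            )
            used += 1
            realized = _pairwise_identity(novel, parent)
        if not (target - tol <= realized <= target + tol):  # pragma: no cover
            raise RuntimeError(
                f"novel taxon {novel.id}: realized identity {realized:.4f} "
                f"missed target {target}"
            )
        taxa.append(novel)
        rows.append(
            {
                "taxon_id": novel.id,
                "parent_id": parent.id,
                "realized_identity": realized,
                "is_novel": True,
            }
        )

    n_total = len(taxa)
    if spec.abundances is None:
        abundances = np.full(n_total, 1.0 / n_total)
    else:
        abundances = np.asarray(spec.abundances, dtype=float)
    return Community(
        taxa=taxa,
        n_references=spec.n_taxa,
        truth=pd.DataFrame(rows),
        abundances=abundances,
    )


# -- long reads ----------------------------------------------------------------


def _apply_errors(
    seq: str, spec: LongReadSpec, rng: np.random.Generator
) -> tuple[str, dict[str, list[int]]]:
    """Per-base substitution/insertion/deletion/N processes.

    Error positions are recorded in coordinates of the output read.
    """
    out: list[str] = []
    errors: dict[str, list[int]] = {"sub": [], "ins": [], "del": [], "n": []}
    for base in seq:
        r = rng.random()
        if r < spec.del_rate:
            errors["del"].append(len(out))
            continue
        r -= spec.del_rate
        if r < spec.n_rate:
            errors["n"].append(len(out))
            out.append("N")
        elif r - spec.n_rate < spec.sub_rate:
            errors["sub"].append(len(out))
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(base)
        if rng.random() < spec.ins_rate:
            errors["ins"].append(len(out))
            out.append(str(_BASES[rng.integers(0, 4)]))
    return "".join(out), errors


def _junction_is_novel(
    read_seq: str, breakpoint: int, k: int, taxa: Sequence[SeqRecord]
) -> bool:
    """True when no k-window crossing the breakpoint occurs in any taxon."""
    n = len(read_seq)
    # a crossing window contains at least one base from each parent:
    # start in [breakpoint - k + 1, breakpoint - 1]
    lo = max(0, breakpoint - k + 1)
    hi = min(breakpoint - 1, n - k)
    haystacks = [t.bases for t in taxa] + [revcomp(t.bases) for t in taxa]
    for s in range(lo, hi + 1):
        window = read_seq[s : s + k]
        if any(window in h for h in haystacks):
            return False
    return True


def simulate_long_reads(
    community: Community,
    spec: LongReadSpec,
    dataset_tag: DatasetTag = DatasetTag.LONG_WGS,
    abundances: Optional[Sequence[float]] = None,
    id_prefix: str = "long",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw long reads from the community, with errors and chimeras.

    Each read samples a taxon by abundance, a length uniform in the spec's
    range and a window uniform in position.  With probability
    ``chimera_fraction`` the read is instead a bimeric splice of windows
    from two distinct taxa at a uniform breakpoint; with
    ``junction_guard_k`` set, splices are resampled until no guard-length
    window crossing the junction occurs in any taxon on either strand (so
    no perfect short read of that length or more can bridge the join).
    """
    if not community.taxa:
        raise ValueError("empty community")
    rng = np.random.default_rng(spec.seed)
    ab = np.asarray(
        abundances if abundances is not None else community.abundances, dtype=float
    )
    ab = ab / ab.sum()
    reads: list[SeqRecord] = []
    rows = []
    for i in range(spec.n_reads):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        is_chimera = rng.random() < spec.chimera_fraction and len(community.taxa) > 1
        if is_chimera:
            seq, row = _make_chimera(community, length, spec, rng, ab)
        else:
            t_idx = int(rng.choice(len(community.taxa), p=ab))
            taxon = community.taxa[t_idx]
            length = min(length, len(taxon.bases))
            start = int(rng.integers(0, len(taxon.bases) - length + 1))
            seq = taxon.bases[start : start + length]
            row = {
                "source_taxon": taxon.id,
                "source_taxon_2": "",
                "start": start,
                "breakpoint": -1,
                "is_chimera": False,
            }
        seq, errors = _apply_errors(seq, spec, rng)
        read_id = f"{id_prefix}{i:05d}"
        reads.append(
            SeqRecord(id=read_id, bases=seq, dataset_tag=dataset_tag)
        )
        row.update(
            {
                "read_id": read_id,
                "length": len(seq),
                "n_sub": len(errors["sub"]),
                "n_ins": len(errors["ins"]),
                "n_del": len(errors["del"]),
                "n_N": len(errors["n"]),
                "error_positions": ";".join(
                    f"{kind}:{pos}"
                    for kind in ("sub", "ins", "del", "n")
                    for pos in errors[kind]
                ),
            }
        )
        rows.append(row)
    truth = pd.DataFrame(rows)
    return reads, truth


def _make_chimera(
    community: Community,
    length: int,
    spec: LongReadSpec,
    rng: np.random.Generator,
    ab: np.ndarray,
) -> tuple[str, dict]:
    """Bimeric splice of windows from two distinct taxa."""
    for _ in range(1000):
        i, j = rng.choice(len(community.taxa), size=2, replace=False, p=ab)
        a, b = community.taxa[int(i)], community.taxa[int(j)]
        length = min(length, len(a.bases), len(b.bases))
        bp = int(rng.integers(1, length))
        left_start = int(rng.integers(0, len(a.bases) - bp + 1))
        right_len = length - bp
        right_start = int(rng.integers(0, len(b.bases) - right_len + 1))
        seq = (
            a.bases[left_start : left_start + bp]
            + b.bases[right_start : right_start + right_len]
        )
        if spec.junction_guard_k is None or _junction_is_novel(
            seq, bp, spec.junction_guard_k, community.taxa
        ):
            return seq, {
                "source_taxon": a.id,
                "source_taxon_2": b.id,
                "start": left_start,
                "breakpoint": bp,
                "is_chimera": True,
            }
    raise RuntimeError(  # pragma: no cover - defensive
        "could not place a chimera junction absent from all taxa"
    )


# -- short paired-end reads ------------------------------------------------------


def simulate_short_pairs(
    community: Community,
    spec: ShortReadSpec,
    abundances: Optional[Sequence[float]] = None,
    sample_id: str = "",
    subject_id: str = "",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Paired-end reads from uniform-length fragments.

    Fragment counts are set so the abundance-weighted mean per-taxon depth
    equals ``mean_depth``; each fragment lands on a taxon drawn by
    abundance, at a uniform position, with length uniform in the insert
    range.  Mates are the two fragment ends (minus-strand mate
    reverse-complemented) and share a fragment id (``fragXXXXXX/1`` and
    ``/2``).
    """
    if not community.taxa:
        raise ValueError("empty community")
    rng = np.random.default_rng(spec.seed)
    ab = np.asarray(
        abundances if abundances is not None else community.abundances, dtype=float
    )
    ab = ab / ab.sum()
    lo, hi = spec._length_bounds()
    mean_rl = (lo + hi) / 2.0
    mean_len = float(np.mean([len(t.bases) for t in community.taxa]))
    n_frags = int(round(spec.mean_depth * len(community.taxa) * mean_len
                        / (2.0 * mean_rl)))
    reads: list[SeqRecord] = []
    rows = []
    prefix = f"{sample_id}_" if sample_id else ""
    for f in range(n_frags):
        t_idx = int(rng.choice(len(community.taxa), p=ab))
        taxon = community.taxa[t_idx]
        frag_len = int(rng.integers(spec.insert_range[0], spec.insert_range[1] + 1))
        frag_len = min(frag_len, len(taxon.bases))
        start = int(rng.integers(0, len(taxon.bases) - frag_len + 1))
        fragment = taxon.bases[start : start + frag_len]
        frag_id = f"{prefix}frag{f:06d}"
        l1 = min(spec.draw_length(rng), frag_len)
        l2 = min(spec.draw_length(rng), frag_len)
        mate1 = fragment[:l1]
        mate2 = revcomp(fragment[-l2:])
        for mate_no, seq in ((1, mate1), (2, mate2)):
            if not spec.error_free:
                seq = _point_substitutions(seq, spec.sub_rate, rng)
            reads.append(
                SeqRecord(
                    id=f"{frag_id}/{mate_no}",
                    bases=seq,
                    sample_id=sample_id,
                    subject_id=subject_id,
                    dataset_tag=DatasetTag.SHORT_WGS,
                )
            )
        rows.append(
            {
                "fragment_id": frag_id,
                "taxon_id": taxon.id,
                "start": start,
                "fragment_length": frag_len,
                "read1_len": l1,
                "read2_len": l2,
            }
        )
    return reads, pd.DataFrame(rows)


def _point_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    out = list(seq)
    for p in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[p]]
            out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


# -- targeted single-error injection ----------------------------------------------


def inject_single_error(
    read: SeqRecord,
    kind: str,
    community: Community,
    rng: np.random.Generator,
    margin: int = 20,
) -> tuple[SeqRecord, int]:
    """Plant exactly one interior substitution/insertion/deletion/N.

    The error position is resampled until the mutated read is not a
    substring of any community taxon on either strand — a deletion inside a
    homopolymer, for example, can produce a sequence indistinguishable from
    a correct shorter read, which coverage-based validation rightly
    accepts.  Returns the mutated read and the error position.
    """
    if kind not in ("sub", "ins", "del", "n"):
        raise ValueError(f"unknown error kind {kind!r}")
    haystacks = [t.bases for t in community.taxa] + [
        revcomp(t.bases) for t in community.taxa
    ]
    n = len(read.bases)
    if n < 2 * margin + 1:
        raise ValueError("read too short for an interior error")
    for _ in range(200):
        pos = int(rng.integers(margin, n - margin))
        bases = read.bases
        if kind == "sub":
            choices = [b for b in "ACGT" if b != bases[pos]]
            mutated = bases[:pos] + choices[rng.integers(0, 3)] + bases[pos + 1 :]
        elif kind == "n":
            mutated = bases[:pos] + "N" + bases[pos + 1 :]
        elif kind == "ins":
            mutated = bases[:pos] + str(_BASES[rng.integers(0, 4)]) + bases[pos:]
        else:  # del
            mutated = bases[:pos] + bases[pos + 1 :]
        if not any(mutated in h for h in haystacks):
            return (
                SeqRecord(
                    id=f"{read.id}_{kind}",
                    bases=mutated,
                    sample_id=read.sample_id,
                    subject_id=read.subject_id,
                    dataset_tag=read.dataset_tag,
                ),
                pos,
            )
    raise RuntimeError(  # pragma: no cover - defensive
        f"could not plant a distinguishing {kind} error in {read.id}"
    )
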