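"""OTU clustering of validated novel reads and cohort presence estimation.

Validated reads are grouped into operational taxonomic units by greedy
97%-identity clustering (longest read is the representative).  Presence of
each OTU across an extended cohort is then estimated two ways:

* **amplicon route** — extended amplicon reads co-clustering with an OTU
  representative at >= 97% identity count toward that OTU in their sample;
* **shotgun route** — an OTU is present in a sample when that sample's
  short reads alone cover one of the OTU's member long reads over 100% of
  its length at perfect identity (breadth only; the full tiling checks are
  for candidate validation, not presence).

The primer-bias screen checks whether shotgun-only novel reads overlap the
amplification primers, distinguishing exact hits, near hits (1-2
mismatches, which would likely still amplify) and reads with no primer
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .aligners import align_pairwise, align_short_reads, match_primers
from .config import ValidationConfig
from .novelty import greedy_cluster
from .records import PrimerCategory, PrimerHit, SeqRecord
from .tiling import build_profile


@dataclass
class OTU:
    otu_id: str
    representative: SeqRecord
    member_ids: list[str]


@dataclass
class OTUTable:
    """OTUs plus a per-sample presence/abundance count matrix."""

    otus: list[OTU]
    presence: pd.DataFrame  # index: otu_id, columns: sample_id, values: counts
    sample_meta: dict[str, tuple[str, str]] = field(default_factory=dict)

    def otu(self, otu_id: str) -> OTU:
        for o in self.otus:
            if o.otu_id == otu_id:
                return o
        raise KeyError(otu_id)


def cluster_novel_reads(
    reads: Sequence[SeqRecord],
    identity: float = 0.97,
    coverage: float = 0.95,
) -> OTUTable:
    """Greedy identity clustering of validated reads into OTUs.

    Same engine as dereplication, at the OTU identity threshold over the
    shorter sequence's length.  The initial presence matrix counts each
    member read in its sample of origin.
    """
    clusters = greedy_cluster(reads, identity, coverage)
    by_id = {r.id: r for r in reads}
    otus = []
    counts: dict[tuple[str, str], int] = {}
    samples: set[str] = set()
    meta: dict[str, tuple[str, str]] = {}
    for i, (rep, members) in enumerate(clusters, start=1):
        otu_id = f"OTU{i:03d}"
        otus.append(OTU(otu_id=otu_id, representative=rep, member_ids=list(members)))
        for mid in members:
            rec = by_id[mid]
            sample = rec.sample_id or "unknown"
            samples.add(sample)
            meta.setdefault(sample, (rec.subject_id, ""))
            counts[(otu_id, sample)] = counts.get((otu_id, sample), 0) + 1
    presence = pd.DataFrame(
        0,
        index=[o.otu_id for o in otus],
        columns=sorted(samples),
        dtype=int,
    )
    for (otu_id, sample), c in counts.items():
        presence.loc[otu_id, sample] = c
    return OTUTable(otus=otus, presence=presence, sample_meta=meta)


def extend_presence_amplicon(
    table: OTUTable,
    extended_reads: Sequence[SeqRecord],
    cfg: ValidationConfig,
) -> pd.DataFrame:
    """Recruit extended-cohort amplicon reads to OTUs by co-clustering.

    Each extended read matching an OTU representative at
    >= ``extended_cluster_identity`` over ``extended_cluster_coverage`` of
    the shorter sequence joins the best-matching OTU and increments that
    OTU's count in its sample.  Reads matching no representative are
    discarded.  Counts for the extended samples are recomputed from scratch
    on every call (re-application of the same reads is idempotent).
    """
    reps = [o.representative for o in table.otus]
    rep_otu = {o.representative.id: o.otu_id for o in table.otus}
    new_counts: dict[tuple[str, str], int] = {}
    for read in extended_reads:
        alns = align_pairwise(read, reps)
        best = None
        for aln in alns:
            shorter = min(len(read.bases), len(next(
                r.bases for r in reps if r.id == aln.target_id
            )))
            if (
                aln.identity >= cfg.extended_cluster_identity
                and aln.align_len >= cfg.extended_cluster_coverage * shorter
            ):
                if best is None or (aln.identity, aln.score) > (
                    best.identity,
                    best.score,
                ):
                    best = aln
        if best is None:
            continue
        sample = read.sample_id or "unknown"
        key = (rep_otu[best.target_id], sample)
        new_counts[key] = new_counts.get(key, 0) + 1
        table.sample_meta.setdefault(sample, (read.subject_id, ""))

    touched_samples = {s for (_, s) in new_counts} | {
        r.sample_id or "unknown" for r in extended_reads
    }
    for sample in sorted(touched_samples):
        if sample not in table.presence.columns:
            table.presence[sample] = 0
        else:
            table.presence[sample] = 0  # overwrite per-sample, not accumulate
    for (otu_id, sample), c in new_counts.items():
        table.presence.loc[otu_id, sample] = c
    return table.presence


def extend_presence_wgs(
    table: OTUTable,
    member_wgs_reads: Sequence[SeqRecord],
    short_read_samples: dict[str, Sequence[SeqRecord]],
    cfg: ValidationConfig,
) -> pd.DataFrame:
    """Presence of shotgun-member OTUs via full-breadth perfect coverage.

    For each (sample, OTU-member shotgun read): the OTU is present in the
    sample when the sample's short reads alone cover the member read over
    100% of its length at perfect identity.  The count stored is the number
    of member reads so validated in that sample.
    """
    member_ids = {m for o in table.otus for m in o.member_ids}
    members = [r for r in member_wgs_reads if r.id in member_ids]
    otu_of = {m: o.otu_id for o in table.otus for m in o.member_ids}
    for sample, reads in sorted(short_read_samples.items()):
        if sample not in table.presence.columns:
            table.presence[sample] = 0
        else:
            table.presence[sample] = 0
        for member in members:
            supports = align_short_reads([member], list(reads), cfg)
            profile = build_profile(member, supports)
            if profile.breadth >= 1.0:
                table.presence.loc[otu_of[member.id], sample] += 1
    return table.presence


@dataclass
class PrimerScreenSummary:
    exact: int
    near: int
    no_overlap: int


def primer_bias_screen(
    novel_wgs_reads: Sequence[SeqRecord],
    primers: Sequence[SeqRecord],
    cfg: ValidationConfig,
) -> tuple[list[PrimerHit], dict[str, PrimerCategory], PrimerScreenSummary]:
    """Best primer hit per read and an exact/near/no-overlap tally.

    A read's category is the best across primers: EXACT (a 0-mismatch hit),
    NEAR (best hit has 1-2 mismatches) or NO_OVERLAP (no seeded hit at
    all).
    """
    all_hits: list[PrimerHit] = []
    categories: dict[str, PrimerCategory] = {}
    for read in novel_wgs_reads:
        hits, _ = match_primers(read, list(primers), cfg.primer_word_size)
        best_per_primer: dict[str, PrimerHit] = {}
        for h in hits:
            cur = best_per_primer.get(h.primer_id)
            if cur is None or h.mismatches < cur.mismatches:
                best_per_primer[h.primer_id] = h
        all_hits.extend(sorted(best_per_primer.values(), key=lambda h: h.primer_id))
        if not best_per_primer:
            categories[read.id] = PrimerCategory.NO_OVERLAP
        else:
            best_mm = min(h.mismatches for h in best_per_primer.values())
            if best_mm == 0:
                categories[read.id] = PrimerCategory.EXACT
            elif best_mm <= 2:
                categories[read.id] = PrimerCategory.NEAR
            else:
                categories[read.id] = PrimerCategory.NO_OVERLAP
    summary = PrimerScreenSummary(
        exact=sum(1 for c in categories.values() if c is PrimerCategory.EXACT),
        near=sum(1 for c in categories.values() if c is PrimerCategory.NEAR),
        no_overlap=sum(
            1 for c in categories.values() if c is PrimerCategory.NO_OVERLAP
        ),
    )
    return all_hits, categories, summary
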