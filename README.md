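# noveltax

Discovery and cross-platform validation of novel 16S rDNA sequences in
metagenomic data.

## The problem

Deeply sequenced microbial communities (the healthy human gut being the
canonical example) still harbor low-abundance taxa whose 16S rRNA genes are
absent from public databases. Finding them sounds easy — look for reads
with a poor nearest database neighbor — but the naive screen is dominated
by artifacts: PCR chimeras and platform sequencing errors also look
"novel". Database-driven chimera detectors miss chimeras whose components
are themselves poorly represented in the database, which is precisely the
situation when hunting novelty.

`noveltax` implements a database-independent validation strategy for
microbiome researchers: candidate novel long reads (a few hundred bp, from
16S amplicon or shotgun sequencing) are cross-examined against an
independent library of short paired-end shotgun reads, using only the
*geometry of perfect alignments* — no reference is consulted. A real
biological sequence is tiled end-to-end by short reads from the same
community DNA; a chimera or an erroneous base creates a barrier that no
100%-identity read can cross, and the alignment pattern betrays it.

## The method

**Novelty screen.** Long reads are dereplicated (100% identity over 95% of
the shorter read), then aligned to a 16S reference panel. Qualifying
alignments must be ≥100 bp with ≤5 bp unaligned at each read end (unless
that end overhangs the target). The best-scoring survivor is the nearest
neighbor; a read with nearest-neighbor identity < 97% — or no qualifying
neighbor at all — is a novelty candidate. Reads dominated by amplification
primers are re-screened with the length rule relaxed to their longest
non-primer stretch.

**Tiling validation.** Short reads are placed on each candidate by exact
matching (support is defined as 100% identity, ≥60 aligned bp, whole read
aligned except end overhangs). Four ordered checks classify the candidate:

1. *breadth* — shotgun candidates need coverage over 100% of their length,
   amplicon candidates over >95%;
2. *valley* — the maximum aligned read length per start position must not
   dip to ≤70 bp between shoulders of ≥90 bp (the signature of a junction
   approached by ever-shorter reads and never crossed);
3. *tiling path* — a chain of alignments overlapping by ≥20 bp and each
   extending coverage by ≥20 bp must span the candidate;
4. *spanning pair* — deeply covered (median depth >500), long (>200 bp)
   candidates additionally need one sequenced fragment whose mates span
   ≥90% of the candidate.

**OTUs and distribution.** Validated reads are clustered into OTUs at 97%
identity; presence across a larger cohort is estimated by co-clustering
extended amplicon reads with OTU representatives (97%) and, for shotgun
members, by requiring a sample's short reads alone to tile the member read
over 100% of its length.

**Synthetic data.** A fully seeded generator produces reference panels at
controlled pairwise divergence, novel variants at a target identity (e.g.
93%), long reads with substitutions/indels/uncalled bases and bimeric
chimeras, and paired-end short reads from 100–500 bp fragments — so the
whole pipeline is testable against ground truth without any downloads.

## Worked example

Generate a synthetic scene — five 1.5-kb reference taxa, two planted novel
variants at 93% identity, forty long reads of which 20% are chimeric, and
error-free paired short reads at mean depth 50 — then run the pipeline:

```bash
noveltax make-fixture --out-dir scene --n-taxa 5 --n-novel 2 \
    --n-long-reads 40 --chimera-fraction 0.2 --seed 42
noveltax pipeline --reads scene/long_reads.fasta \
    --references scene/references.fasta \
    --shorts scene/shorts_1.fastq --shorts scene/shorts_2.fastq \
    --out-dir out
```

```
screen: 16/40 novelty candidates
validate: 6/16 candidates validated
cluster: 5 OTUs
```

The screen flags 16 reads: the reads drawn from the two planted novel taxa
*and* the chimeras, which also look novel by the database criterion
(`long00000`, a chimera, has a nearest neighbor at only 96.0% identity in
`out/novelty.tsv`). Tiling validation then rejects every chimera — each
shows a coverage gap, a valley, or a broken tiling path at its junction —
leaving 6 validated reads, all from the planted novel taxa.
`out/verdicts.tsv` records the evidence per candidate:

```
candidate_id  status          breadth    median_depth  ...  tiling_path_len
long00000     NO_TILING_PATH  1.000000   33.0               0
long00001     VALIDATED       1.000000   31.0               3
```

`long00000` is instructive: every one of its positions is covered by a
perfect short read, yet no two reads bridge its junction with the required
20-base overlap — reads from the left parent stop at the splice point and
reads from the right parent start there. `long00001` is a genuine
novel-taxon read, tiled end to end by a 3-alignment chain.

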