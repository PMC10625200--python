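"""Exon-skipping statistics from spliced read alignments.

Quantifies the evidence for isoforms lacking a pair of exons -- the
inactive-DNMT3B-like products in which the second and third exons from the
3' end are spliced out. A spliced read is *exclusion* evidence when it
carries the junction joining the two exons flanking the target pair (both
boundaries exact), and *inclusion* evidence when one of its junctions has a
boundary exactly at a boundary of either target exon. The reported ratio is
exclusion / inclusion reads.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

from .io_formats import AlignmentRecord, GeneModel


class SpliceJunction(NamedTuple):
    donor_end: int       # exclusive end of the upstream exonic block (genomic)
    acceptor_start: int  # start of the downstream exonic block (genomic)


@dataclass
class ExonSkipResult:
    exon_pair: tuple[int, int]  # indices from the 3' end
    inclusion_reads: int
    exclusion_reads: int

    @property
    def ratio(self) -> Optional[float]:
        """exclusion/inclusion; undefined (None) when inclusion_reads == 0."""
        if self.inclusion_reads == 0:
            return None
        return self.exclusion_reads / self.inclusion_reads


def extract_junctions(rec: AlignmentRecord) -> list[SpliceJunction]:
    """One junction per CIGAR N operation, from walking M/D/N over the reference."""
    junctions: list[SpliceJunction] = []
    cur = rec.pos
    for n, op in rec.cigar_ops():
        if op in "MD":
            cur += n
        elif op == "N":
            junctions.append(SpliceJunction(donor_end=cur, acceptor_start=cur + n))
            cur += n
    return junctions


def resolve_exon_pair(gene: GeneModel, indices_from_3prime: tuple[int, int]
                      ) -> tuple[list[tuple[int, int]], tuple[int, int], tuple[int, int]]:
    """Map 3'-end exon indices to genomic exons and their flanks.

    Indices count from the 3' end starting at 1, respecting strand (on '-'
    genes the 3'-most exon is the leftmost). The pair must be consecutive.
    Returns (target exons genomically sorted, genomic-left flank exon,
    genomic-right flank exon); both flanks must exist.
    """
    i, j = sorted(indices_from_3prime)
    if j != i + 1:
        raise ValueError(f"exon indices from 3' end must be consecutive, got {indices_from_3prime}")
    n = gene.n_exons
    if i < 2 or j > n - 1:
        raise ValueError(
            f"gene {gene.gene_id!r} with {n} exons cannot resolve 3'-end pair "
            f"{indices_from_3prime} with both flanks"
        )

    def from_3prime(k: int) -> int:  # 1-based 3'-index -> 0-based genomic index
        return n - k if gene.strand == "+" else k - 1

    idx = sorted((from_3prime(i), from_3prime(j)))
    targets = [gene.exons[idx[0]], gene.exons[idx[1]]]
    flank_left = gene.exons[idx[0] - 1]
    flank_right = gene.exons[idx[1] + 1]
    return targets, flank_left, flank_right


def exon_skip_ratio(records: Iterable[AlignmentRecord], gene: GeneModel,
                    indices_from_3prime: tuple[int, int], slop: int = 0,
                    ) -> ExonSkipResult:
    """Classify junction-bearing reads as exclusion or inclusion evidence.

    ``slop`` relaxes boundary matching by +-slop bp for noisy aligners
    (default 0 = exact). A read carrying both kinds of junction counts as
    exclusion (it demonstrates the skipped product); each read is counted in
    at most one category.
    """
    targets, flank_left, flank_right = resolve_exon_pair(gene, indices_from_3prime)
    skip_junction = SpliceJunction(donor_end=flank_left[1], acceptor_start=flank_right[0])
    target_boundaries = {b for exon in targets for b in exon}

    def near(x: int, y: int) -> bool:
        return abs(x - y) <= slop

    inclusion = exclusion = 0
    for rec in records:
        if rec.chrom != gene.chrom:
            continue
        juncs = extract_junctions(rec)
        if not juncs:
            continue
        is_excl = any(
            near(j.donor_end, skip_junction.donor_end)
            and near(j.acceptor_start, skip_junction.acceptor_start)
            for j in juncs
        )
        if is_excl:
            exclusion += 1
            continue
        is_incl = any(
            any(near(j.donor_end, b) or near(j.acceptor_start, b) for b in target_boundaries)
            for j in juncs
        )
        if is_incl:
            inclusion += 1
    return ExonSkipResult(exon_pair=tuple(indices_from_3prime),
                          inclusion_reads=inclusion, exclusion_reads=exclusion)
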