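"""RPKM/FPKM gene quantification, TSS-window RPM and expression ratios.

Counting rules: a read (or fragment, in paired mode) is assigned to a gene
when its reference-consumed intervals (CIGAR M/D blocks, not N gaps) overlap
the gene's exon union by at least ``min_overlap`` bp (default 1). In paired
mode a fragment is counted once per gene, keyed by read_id, if either mate
overlaps. Gene counting is unstranded; TSS-window RPM is always
strand-aware (CAGE semantics: only read 5' ends on the matching strand).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignmentRecord, GeneModel


@dataclass
class ExpressionRecord:
    gene_id: str
    raw_count: int
    rpkm: float

    @property
    def log2_rpkm_plus1(self) -> float:
        return math.log2(self.rpkm + 1.0)


def _overlap_len(blocks: Sequence[tuple[int, int]], exons: Sequence[tuple[int, int]]) -> int:
    total = 0
    for bs, be in blocks:
        for es, ee in exons:
            lo, hi = max(bs, es), min(be, ee)
            if hi > lo:
                total += hi - lo
    return total


def count_gene(records: Iterable[AlignmentRecord], gene: GeneModel,
               paired_mode: bool = False, min_overlap: int = 1) -> int:
    """Reads (or fragments) whose M/D reference blocks overlap the gene's
    exons by >= ``min_overlap`` bp. Records should be primary alignments;
    non-primary records are ignored defensively."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seen_fragments: set[str] = set()
    count = 0
    for rec in records:
        if not rec.is_primary or rec.chrom != gene.chrom:
            continue
        if paired_mode and not rec.is_paired:
            raise ValueError(
                f"paired_mode requested but read {rec.read_id!r} lacks pairing flags"
            )
        if _overlap_len(rec.reference_blocks(), gene.exons) < min_overlap:
            continue
        if paired_mode:
            if rec.read_id in seen_fragments:
                continue
            seen_fragments.add(rec.read_id)
        count += 1
    return count


def rpkm(count: int, gene_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of (exon-union) transcript per million library reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / (gene_length_bp / 1000.0) / (library_size / 1e6)


def quantify_genes(records: Sequence[AlignmentRecord], genes: Iterable[GeneModel],
                   library_size: int | None = None,
                   paired_mode: bool = False) -> list[ExpressionRecord]:
    """RPKM per gene over one library.

    ``library_size`` defaults to the number of primary records (fragments in
    paired mode) in the input -- all primary mapped reads, not only those
    assigned to genes.
    """
    primary = [r for r in records if r.is_primary]
    if library_size is None:
        if paired_mode:
            library_size = len({r.read_id for r in primary})
        else:
            library_size = len(primary)
    out = []
    for gene in genes:
        c = count_gene(primary, gene, paired_mode=paired_mode)
        out.append(ExpressionRecord(gene_id=gene.gene_id,
                                    raw_count=c,
                                    rpkm=rpkm(c, gene.exonic_length, library_size)))
    return out


def window_rpm(records: Iterable[AlignmentRecord], anchor_pos: int, window_bp: int,
               strand: str, library_size: int, chrom: str | None = None) -> float:
    """Reads whose strand-aware 5' end falls within ``window_bp`` of the
    anchor, per million library reads.

    On '+' the window is [anchor, anchor + window); on '-' it extends
    upstream in transcript orientation, i.e. [anchor - window + 1, anchor + 1).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if strand == "+":
        lo, hi = anchor_pos, anchor_pos + window_bp
    elif strand == "-":
        lo, hi = anchor_pos - window_bp + 1, anchor_pos + 1
    else:
        raise ValueError(f"invalid strand {strand!r}")
    n = 0
    for rec in records:
        if not rec.is_primary or rec.strand != strand:
            continue
        if chrom is not None and rec.chrom != chrom:
            continue
        if lo <= rec.five_prime_end() < hi:
            n += 1
    return n / (library_size / 1e6)


def expression_ratio(num: ExpressionRecord | float, den: ExpressionRecord | float) -> float:
    """Ratio of two expression levels (e.g. DNMT3B / DNMT3A RPKM)."""
    num_v = num.rpkm if isinstance(num, ExpressionRecord) else float(num)
    den_v = den.rpkm if isinstance(den, ExpressionRecord) else float(den)
    if den_v == 0:
        raise ZeroDivisionError("undefined expression ratio: denominator RPKM is 0")
    return num_v / den_v


def expression_to_tsv(records: Iterable[ExpressionRecord]) -> str:
    lines = ["gene_id\traw_count\trpkm\tlog2_rpkm_plus1"]
    for r in records:
        lines.append(f"{r.gene_id}\t{r.raw_count}\t{r.rpkm:.6g}\t{r.log2_rpkm_plus1:.6g}")
    return "\n".join(lines) + "\n"
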