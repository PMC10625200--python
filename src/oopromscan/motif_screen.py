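"""Cross-species screening of an oocyte promoter signature through an MSA.

The signature being screened is a TBPL2/TFIIA-type core-promoter element: a
short IUPAC consensus (default ``TTCTTAA``) a fixed distance upstream of the
oocyte TSS, with a pyrimidine-rich (CT) context immediately upstream of the
TSS and a purine-rich (GA) context immediately downstream. The screen is
anchored on a reference species known to carry the signature (mouse in the
motivating study): the reference motif window and TSS are projected through
the alignment into every other species, which is then classified as
``present``, ``partial``, ``region_deleted`` or ``absent``.

Offset convention: the motif-to-TSS distance is measured from the motif
*start* to the TSS, in the ungapped coordinates of each species ("32 bp
upstream of the TSS" means motif start = TSS - 32).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_formats import GAP, GenomicSequence, MultipleAlignment

# IUPAC nucleotide codes -> the set of plain bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifModel:
    """A single IUPAC consensus plus its placement relative to the TSS."""

    consensus: str = "TTCTTAA"
    max_mismatches: int = 1
    expected_offset_upstream_of_tss: int = 32
    offset_tolerance: int = 5

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not self.consensus:
            raise ValueError("empty consensus")
        for i, ch in enumerate(self.consensus):
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} at consensus position {i}")
        if self.max_mismatches < 0 or self.offset_tolerance < 0:
            raise ValueError("max_mismatches and offset_tolerance must be >= 0")


@dataclass
class TssContextModel:
    """CT-rich upstream / GA-rich downstream TSS context thresholds."""

    upstream_window: int = 10
    downstream_window: int = 10
    ct_min_fraction: float = 0.8
    ga_min_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.upstream_window < 1 or self.downstream_window < 1:
            raise ValueError("context windows must be >= 1")
        for f in (self.ct_min_fraction, self.ga_min_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("context fractions must lie in [0,1]")


@dataclass
class MotifHit:
    start: int  # 0-based position in the ungapped sequence scanned
    mismatches: int
    matched_text: str


@dataclass
class PromoterCall:
    species: str
    status: str  # present | partial | region_deleted | absent
    best_hit: Optional[MotifHit] = None
    ct_fraction: float = 0.0
    ga_fraction: float = 0.0
    tss_offset_observed: Optional[int] = None
    gap_fraction: float = 0.0


def reverse_complement(seq: GenomicSequence) -> GenomicSequence:
    """Reverse-complement a sequence; N maps to N, the strand flag is flipped."""
    return GenomicSequence(
        id=seq.id,
        species=seq.species,
        residues=seq.residues.translate(_COMPLEMENT)[::-1],
        strand="-" if seq.strand == "+" else "+",
    )


def _mismatches(window: str, consensus: str) -> int:
    return sum(1 for b, c in zip(window, consensus) if b not in IUPAC[c])


def scan_motif(seq: GenomicSequence | str, model: MotifModel,
               max_mismatches: int | None = None) -> list[MotifHit]:
    """All windows matching the consensus under IUPAC expansion with at most
    ``max_mismatches`` Hamming mismatches, sorted by (mismatches, start)."""
    residues = seq.residues if isinstance(seq, GenomicSequence) else seq.upper()
    mm_cap = model.max_mismatches if max_mismatches is None else max_mismatches
    k = len(model.consensus)
    hits = [
        MotifHit(start=i, mismatches=mm, matched_text=residues[i : i + k])
        for i in range(len(residues) - k + 1)
        if (mm := _mismatches(residues[i : i + k], model.consensus)) <= mm_cap
    ]
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def score_tss_context(seq: GenomicSequence | str, tss_pos: int,
                      model: TssContextModel) -> tuple[float, float, bool]:
    """CT fraction upstream and GA fraction downstream of a TSS position.

    Windows are truncated at sequence edges; fractions are taken over the
    effective (truncated) window. An empty effective window scores 0.
    """
    residues = seq.residues if isinstance(seq, GenomicSequence) else seq.upper()
    if not 0 <= tss_pos <= len(residues):
        raise ValueError(f"tss_pos {tss_pos} out of range for sequence of length {len(residues)}")
    up = residues[max(0, tss_pos - model.upstream_window) : tss_pos]
    down = residues[tss_pos : tss_pos + model.downstream_window]
    ct = sum(1 for b in up if b in "CT") / len(up) if up else 0.0
    ga = sum(1 for b in down if b in "GA") / len(down) if down else 0.0
    return ct, ga, ct >= model.ct_min_fraction and ga >= model.ga_min_fraction


@dataclass
class ProjectedInterval:
    species: str
    columns: tuple[int, int]  # half-open column range in the alignment
    substring: str            # residues of this species in those columns, gaps stripped
    gap_fraction: float       # gap fraction over all spanned columns
    ungapped_start: int       # ungapped position of the first in-range residue
    gap_fraction_ref: float = 0.0  # gap fraction over reference-residue columns only


def _column_map(row: str) -> list[int]:
    """Columns holding a residue (non-gap), indexed by ungapped position."""
    return [i for i, ch in enumerate(row) if ch != GAP]


def project_ref_interval(aln: MultipleAlignment, ref_species: str,
                         ref_start: int, ref_end: int) -> dict[str, ProjectedInterval]:
    """Locate the alignment columns spanned by an ungapped reference interval
    and read out every species' residues in those columns."""
    if ref_species not in aln:
        raise ValueError(f"reference species {ref_species!r} absent from alignment")
    cols = _column_map(aln.rows[ref_species])
    if not 0 <= ref_start <= ref_end <= len(cols):
        raise ValueError(
            f"reference interval [{ref_start},{ref_end}) outside ungapped length {len(cols)}"
        )
    if ref_start == ref_end:
        col_lo = cols[ref_start] if ref_start < len(cols) else aln.length
        col_hi = col_lo
    else:
        col_lo, col_hi = cols[ref_start], cols[ref_end - 1] + 1
    ref_row = aln.rows[ref_species]
    ref_cols = [c for c in range(col_lo, col_hi) if ref_row[c] != GAP]
    out: dict[str, ProjectedInterval] = {}
    for sp, row in aln.rows.items():
        piece = row[col_lo:col_hi]
        sub = piece.replace(GAP, "")
        gaps = piece.count(GAP)
        ref_gaps = sum(1 for c in ref_cols if row[c] == GAP)
        out[sp] = ProjectedInterval(
            species=sp,
            columns=(col_lo, col_hi),
            substring=sub,
            gap_fraction=gaps / len(piece) if piece else 0.0,
            ungapped_start=sum(1 for ch in row[:col_lo] if ch != GAP),
            gap_fraction_ref=ref_gaps / len(ref_cols) if ref_cols else 0.0,
        )
    return out


def call_promoters(
    aln: MultipleAlignment,
    ref_species: str,
    ref_tss_pos: int,
    motif: MotifModel | None = None,
    context: TssContextModel | None = None,
    deletion_gap_threshold: float = 0.5,
    partial_max: int | None = None,
) -> list[PromoterCall]:
    """Classify every species in the alignment against the reference signature.

    The reference species must carry an exact (0-mismatch) consensus hit whose
    start lies ``expected_offset_upstream_of_tss`` bp upstream of
    ``ref_tss_pos`` -- the screen is anchored on it. For each other species
    the reference promoter region (motif start through TSS + downstream
    context) is projected through the alignment; a mostly-gapped projection is
    called ``region_deleted``, otherwise the projected motif neighbourhood
    (+- ``offset_tolerance``) is scanned and the species is called ``present``
    (hit within mismatch budget, CT/GA context passes, offset within
    tolerance), ``partial`` (a hit up to ``partial_max`` mismatches but some
    condition fails) or ``absent``.
    """
    motif = motif or MotifModel()
    context = context or TssContextModel()
    if partial_max is None:
        partial_max = motif.max_mismatches + 2
    if partial_max < motif.max_mismatches:
        raise ValueError("partial_max must be >= max_mismatches")

    ref_seq = aln.ungapped(ref_species)
    k = len(motif.consensus)
    expected = motif.expected_offset_upstream_of_tss
    anchor_start = ref_tss_pos - expected
    anchor_ok = (
        0 <= anchor_start <= len(ref_seq) - k
        and _mismatches(ref_seq.residues[anchor_start : anchor_start + k], motif.consensus) == 0
    )
    if not anchor_ok:
        raise ValueError(
            f"anchor failure: reference {ref_species!r} has no exact consensus match "
            f"{expected} bp upstream of TSS position {ref_tss_pos}"
        )

    tol = motif.offset_tolerance
    ref_len = len(ref_seq)
    # region used for the deletion test: motif through TSS + downstream context
    region_lo = max(0, anchor_start)
    region_hi = min(ref_len, ref_tss_pos + context.downstream_window)
    region = project_ref_interval(aln, ref_species, region_lo, region_hi)
    # neighbourhood actually scanned for the motif
    hood_lo = max(0, anchor_start - tol)
    hood_hi = min(ref_len, anchor_start + k + tol)
    hood = project_ref_interval(aln, ref_species, hood_lo, hood_hi)
    tss_proj = project_ref_interval(aln, ref_species, ref_tss_pos, min(ref_len, ref_tss_pos + 1))

    calls: list[PromoterCall] = []
    for sp in aln.species:
        # deletion test against reference-residue columns, so that insertions
        # private to third species cannot inflate everyone's gap fraction
        gap_frac = region[sp].gap_fraction_ref
        if gap_frac >= deletion_gap_threshold:
            calls.append(PromoterCall(species=sp, status="region_deleted", gap_fraction=gap_frac))
            continue
        sp_seq = aln.ungapped(sp).residues
        sp_tss = tss_proj[sp].ungapped_start
        ct, ga, ctx_pass = score_tss_context(sp_seq, sp_tss, context)
        hits = scan_motif(hood[sp].substring, motif, max_mismatches=partial_max)
        status = "absent"
        best: MotifHit | None = None
        offset_obs: int | None = None
        if hits:
            hood_start = hood[sp].ungapped_start

            def offset_of(h: MotifHit) -> int:
                return sp_tss - (hood_start + h.start)

            best = min(hits, key=lambda h: (h.mismatches, abs(offset_of(h) - expected), h.start))
            offset_obs = offset_of(best)
            best = MotifHit(start=hood_start + best.start, mismatches=best.mismatches,
                            matched_text=best.matched_text)
            if (best.mismatches <= motif.max_mismatches and ctx_pass
                    and abs(offset_obs - expected) <= tol):
                status = "present"
            else:
                status = "partial"
        calls.append(
            PromoterCall(species=sp, status=status, best_hit=best, ct_fraction=ct,
                         ga_fraction=ga, tss_offset_observed=offset_obs,
                         gap_fraction=gap_frac)
        )
    return calls


def calls_to_tsv(calls: list[PromoterCall]) -> str:
    lines = ["species\tstatus\thit_start\tmismatches\tct_fraction\tga_fraction\tobserved_offset"]
    for c in calls:
        hit_start = c.best_hit.start if c.best_hit else ""
        mm = c.best_hit.mismatches if c.best_hit else ""
        off = c.tss_offset_observed if c.tss_offset_observed is not None else ""
        lines.append(
            f"{c.species}\t{c.status}\t{hit_start}\t{mm}\t{c.ct_fraction:.3f}\t{c.ga_fraction:.3f}\t{off}"
        )
    return "\n".join(lines) + "\n"
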