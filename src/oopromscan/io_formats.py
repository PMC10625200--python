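"""Readers and writers for the plain-text genomics formats used by the pipeline.

One internal coordinate convention is used everywhere: 0-based, half-open
intervals. SAM positions (1-based) are shifted at the parsing boundary; BED
input is already 0-based. The alignment gap character is ``'-'``; ``'.'`` is
accepted on input and normalised. Only the CIGAR operations M, I, D, N and S
are supported -- sufficient for spliced RNA-seq alignments -- and anything
else is rejected.
"""
from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

_CIGAR_OP_RE = re.compile(r"(\d+)([A-Z=])")
_CIGAR_VALID_RE = re.compile(r"^(?:\d+[MIDNS])+$")


def _as_text(path_or_text) -> str:
    """Return file contents if the argument names an existing file, else the
    argument itself (so short literal strings can be passed in tests)."""
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    s = str(path_or_text)
    if "\n" not in s and os.path.exists(s):
        return Path(s).read_text()
    return s


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class GenomicSequence:
    """An oriented DNA sequence over {A,C,G,T,N}.

    ``strand`` records the orientation already applied to ``residues`` (the
    residues are stored as-is); flipping it is the job of
    :func:`oopromscan.motif_screen.reverse_complement`.
    """

    id: str
    residues: str
    species: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        for i, ch in enumerate(self.residues):
            if ch not in DNA_ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: non-IUPAC character {ch!r} at offset {i}"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"sequence {self.id!r}: invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path_or_text) -> list[GenomicSequence]:
    """Parse FASTA text (or a file path) into :class:`GenomicSequence` records.

    Residues are uppercased and U is normalised to T; order is preserved.
    """
    text = _as_text(path_or_text)
    records = [
        GenomicSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]
    if not records:
        raise ValueError("no records")
    return records


def write_fasta(records: Iterable[GenomicSequence], path=None, width: int = 60) -> str:
    out = StringIO()
    SeqIO.write(
        (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records),
        out,
        "fasta",
    )
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# multiple alignments
# ---------------------------------------------------------------------------

class MultipleAlignment:
    """Gapped orthologous sequences keyed by species, all rows equal length."""

    def __init__(self, rows: dict[str, str] | Sequence[tuple[str, str]]):
        items = list(rows.items()) if isinstance(rows, dict) else list(rows)
        seen: dict[str, str] = {}
        for name, seq in items:
            if name in seen:
                raise ValueError(f"duplicate species {name!r} in alignment")
            seen[name] = seq.upper().replace(".", GAP)
        if not seen:
            raise ValueError("no records")
        lengths = {name: len(seq) for name, seq in seen.items()}
        if len(set(lengths.values())) > 1:
            longest = max(lengths.values())
            bad = sorted(n for n, l in lengths.items() if l != longest)
            raise ValueError(f"ragged alignment rows for species: {', '.join(bad)}")
        for name, seq in seen.items():
            for i, ch in enumerate(seq):
                if ch != GAP and ch not in DNA_ALPHABET:
                    raise ValueError(
                        f"species {name!r}: invalid character {ch!r} at column {i}"
                    )
        self.rows: dict[str, str] = seen
        self.length: int = len(next(iter(seen.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return self.length

    def __contains__(self, species: str) -> bool:
        return species in self.rows

    def ungapped(self, species: str) -> GenomicSequence:
        if species not in self.rows:
            raise KeyError(f"species {species!r} not in alignment")
        residues = self.rows[species].replace(GAP, "")
        return GenomicSequence(id=species, species=species, residues=residues)

    def to_fasta(self) -> str:
        out = []
        for name, seq in self.rows.items():
            out.append(f">{name}")
            out.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        return "\n".join(out) + "\n"


def _read_aligned_fasta(text: str) -> MultipleAlignment:
    rows: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                rows.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        elif name is not None:
            chunks.append(line)
    if name is not None:
        rows.append((name, "".join(chunks)))
    return MultipleAlignment(rows)


def _read_clustalw(text: str) -> MultipleAlignment:
    """Assemble interleaved ClustalW blocks; conservation lines are ignored."""
    lines = text.splitlines()
    if not lines:
        raise ValueError("no records")
    order: list[str] = []
    chunks: dict[str, list[str]] = {}
    for line in lines[1:]:  # first line is the CLUSTAL/MUSCLE banner
        if not line.strip():
            continue
        if line[0] in " \t":  # conservation annotation row
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        name, seq = parts[0], parts[1]
        if not re.fullmatch(r"[A-Za-z\-\.\*NACGTUacgtun]+", seq):
            continue
        if name not in chunks:
            order.append(name)
            chunks[name] = []
        chunks[name].append(seq)
    if not order:
        raise ValueError("no records")
    return MultipleAlignment([(n, "".join(chunks[n])) for n in order])


def read_alignment(path_or_text, dialect: str = "aligned-fasta") -> MultipleAlignment:
    """Read a multiple alignment in ``aligned-fasta`` or ``clustalw`` dialect."""
    text = _as_text(path_or_text)
    if dialect == "aligned-fasta":
        return _read_aligned_fasta(text)
    if dialect == "clustalw":
        return _read_clustalw(text)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon structure of one gene, exons sorted and disjoint, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id!r}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        """Total exonic bp (exons are disjoint, so a plain sum)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gene_models(path_or_text) -> dict[str, GeneModel]:
    """Read a tab-separated exon table: gene_id, chrom, strand, exon_start, exon_end."""
    text = _as_text(path_or_text)
    acc: dict[str, dict] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene_id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ValueError(f"gene table line {ln}: expected 5 columns, got {len(parts)}")
        gid, chrom, strand, s, e = parts[:5]
        entry = acc.setdefault(gid, {"chrom": chrom, "strand": strand, "exons": []})
        entry["exons"].append((int(s), int(e)))
    if not acc:
        raise ValueError("no records")
    return {
        gid: GeneModel(gene_id=gid, chrom=v["chrom"], strand=v["strand"], exons=v["exons"])
        for gid, v in acc.items()
    }


def write_gene_models(genes: Iterable[GeneModel], path=None) -> str:
    lines = ["gene_id\tchrom\tstrand\texon_start\texon_end"]
    for g in genes:
        for s, e in g.exons:
            lines.append(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{s}\t{e}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# SAM (minimal dialect)
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One aligned read from a minimal SAM body line (0-based ``pos``)."""

    read_id: str
    chrom: str
    pos: int
    cigar: str
    strand: str = "+"
    is_paired: bool = False
    is_first_mate: bool = True
    is_primary: bool = True

    def cigar_ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar, read_id=self.read_id)

    @property
    def reference_span(self) -> int:
        """Reference bases consumed: sum of M, D and N lengths."""
        return sum(n for n, op in self.cigar_ops() if op in "MDN")

    def reference_blocks(self) -> list[tuple[int, int]]:
        """Intervals of reference actually covered (M/D runs), split at N gaps."""
        blocks: list[tuple[int, int]] = []
        cur = self.pos
        start = None
        for n, op in self.cigar_ops():
            if op in "MD":
                if start is None:
                    start = cur
                cur += n
            elif op == "N":
                if start is not None:
                    blocks.append((start, cur))
                    start = None
                cur += n
            # I and S consume no reference
        if start is not None:
            blocks.append((start, cur))
        return blocks

    def five_prime_end(self) -> int:
        """Genomic position of the read's 5' end (strand-aware)."""
        if self.strand == "+":
            return self.pos
        return self.pos + self.reference_span - 1


def parse_cigar(cigar: str, read_id: str = "?") -> list[tuple[int, str]]:
    if not cigar or not _CIGAR_VALID_RE.match(cigar):
        raise ValueError(f"read {read_id!r}: unparsable CIGAR {cigar!r}")
    return [(int(n), op) for n, op in _CIGAR_OP_RE.findall(cigar)]


def parse_sam_min(path_or_text) -> list[AlignmentRecord]:
    """Parse minimal SAM body text: 11 mandatory columns, '@' headers skipped,
    1-based POS converted to 0-based, FLAG decoded for strand/pairing/primary."""
    text = _as_text(path_or_text)
    records: list[AlignmentRecord] = []
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("@"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise ValueError(f"SAM line {ln}: missing columns ({len(fields)} < 11)")
        qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
        flag = int(flag_s)
        records.append(
            AlignmentRecord(
                read_id=qname,
                chrom=rname,
                pos=int(pos_s) - 1,
                cigar=parse_cigar(cigar, read_id=qname) and cigar,
                strand="-" if flag & 0x10 else "+",
                is_paired=bool(flag & 0x1),
                is_first_mate=not (flag & 0x80),
                is_primary=not (flag & 0x100 or flag & 0x800),
            )
        )
    return records


def write_sam_min(records: Iterable[AlignmentRecord], path=None) -> str:
    lines = []
    for r in records:
        flag = 0
        if r.is_paired:
            flag |= 0x1
            if not r.is_first_mate:
                flag |= 0x80
        if r.strand == "-":
            flag |= 0x10
        if not r.is_primary:
            flag |= 0x100
        lines.append(
            "\t".join(
                [r.read_id, str(flag), r.chrom, str(r.pos + 1), "255", r.cigar,
                 "*", "0", "0", "*", "*"]
            )
        )
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "+"


def read_bed6(path_or_text) -> list[BedRecord]:
    text = _as_text(path_or_text)
    out: list[BedRecord] = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"BED line {ln}: expected >= 3 columns")
        rec = BedRecord(
            chrom=f[0], start=int(f[1]), end=int(f[2]),
            name=f[3] if len(f) > 3 else ".",
            score=f[4] if len(f) > 4 else "0",
            strand=f[5] if len(f) > 5 else "+",
        )
        if rec.end <= rec.start:
            raise ValueError(f"BED line {ln}: end <= start")
        out.append(rec)
    return out


def write_bed6(records: Iterable[BedRecord], path=None) -> str:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}"
        for r in records
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted phylogeny node; leaves carry species names, branches lengths."""

    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            for node in child.preorder():
                yield node

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def mrca(self, names: Iterable[str]) -> "TreeNode":
        """Most recent common ancestor of the named leaves."""
        target = set(names)
        all_names = set(self.leaf_names())
        missing = target - all_names
        if missing or not target:
            raise ValueError(f"clade has no MRCA in tree: missing leaves {sorted(missing)}")

        def descend(node: TreeNode) -> TreeNode | None:
            covering = [c for c in node.children if target & set(c.leaf_names())]
            if len(covering) == 1 and set(covering[0].leaf_names()) >= target:
                return descend(covering[0])
            return node

        found = descend(self)
        assert found is not None
        return found


def parse_newick(text: str) -> TreeNode:
    """Parse a single rooted Newick string terminated by ';'."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0
    depth = 0

    def error(msg: str) -> ValueError:
        return ValueError(f"newick parse error at position {pos}: {msg}")

    def parse_subtree() -> TreeNode:
        nonlocal pos, depth
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            depth += 1
            pos += 1
            node.children.append(parse_subtree())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_subtree())
            if pos >= len(s) or s[pos] != ")":
                raise error("unbalanced parentheses (missing ')')")
            depth -= 1
            pos += 1
        # optional label
        m = re.match(r"[^,():;]+", s[pos:])
        if m:
            node.name = m.group(0).strip()
            pos += m.end()
        # optional branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", s[pos:])
            if not m:
                raise error("expected branch length after ':'")
            node.branch_length = float(m.group(0))
            if node.branch_length < 0:
                raise error("negative branch length")
            pos += m.end()
        return node

    root = parse_subtree()
    if pos != len(s) or depth != 0:
        raise ValueError(f"newick parse error at position {pos}: unbalanced parentheses")
    names = root.leaf_names()
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in newick tree")
    return root


def write_newick(node: TreeNode) -> str:
    def fmt(n: TreeNode) -> str:
        label = n.name or ""
        bl = f":{n.branch_length:g}" if n.branch_length else ""
        if n.is_leaf:
            return f"{label}{bl}"
        inner = ",".join(fmt(c) for c in n.children)
        return f"({inner}){label}{bl}"

    return fmt(node) + ";"
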