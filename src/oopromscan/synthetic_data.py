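"""Seeded generators producing inputs with the statistical structure each
pipeline stage assumes, together with truth tables for recovery tests.

Every generator requires an explicit seed and is byte-level reproducible.
The sequence evolver uses Jukes-Cantor substitutions along the tree,
geometric-length indels (p = 0.5, capped at 20 bp), and writes the planted
promoter block into the most recent common ancestor of the gaining clade;
within that clade the planted positions are frozen (no substitutions, no
indels), mimicking a functionally constrained element against a drifting
background. The read simulator draws single-end reads uniformly along a
mixture of a full-length and an exon-skipping isoform; paired-end counting
logic is exercised elsewhere on hand-written records.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conservation_hmm import ColumnSummary, HmmParams
from .codon_evol import STOP_CODONS, _CODON_AA
from .io_formats import (AlignmentRecord, GenomicSequence, GeneModel,
                         MultipleAlignment, TreeNode, parse_newick)
from .isoform_splice import resolve_exon_pair
from .te_quant import CountsTable, TEInsertion, TE_CLASSES

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("seed is mandatory: generators must be reproducible")
    return int(seed)


def random_sequence(length: int, seed: int, gc: float = 0.5) -> GenomicSequence:
    rng = np.random.default_rng(_require_seed(seed))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(list(_BASES), size=length, p=p)
    return GenomicSequence(id=f"random{seed}", residues="".join(bases))


# ---------------------------------------------------------------------------
# alignment evolution with a planted clade motif
# ---------------------------------------------------------------------------

@dataclass
class MotifPlantSpec:
    """Where and in whom the promoter block appears (and disappears)."""

    clade_leaves: frozenset | set
    motif: str
    offset_in_ancestor: int
    deletion_leaf: Optional[str] = None
    deletion_window: Optional[tuple[int, int]] = None  # (start, len) in ancestor coords

    def __post_init__(self) -> None:
        self.clade_leaves = frozenset(self.clade_leaves)
        self.motif = self.motif.upper()
        if not self.clade_leaves:
            raise ValueError("clade_leaves must be non-empty")
        if not self.motif or any(b not in _BASES for b in self.motif):
            raise ValueError("motif must be non-empty plain DNA")
        if self.offset_in_ancestor < 0:
            raise ValueError("offset_in_ancestor must be >= 0")
        if self.deletion_leaf is not None and self.deletion_window is None:
            raise ValueError("deletion_leaf requires deletion_window")


def _ancestors_of(root: TreeNode, target: TreeNode) -> list[TreeNode]:
    """Nodes on the path root -> target, inclusive."""
    path: list[TreeNode] = []

    def walk(node: TreeNode, trail: list[TreeNode]) -> bool:
        trail.append(node)
        if node is target:
            path.extend(trail)
            return True
        for c in node.children:
            if walk(c, trail):
                return True
        trail.pop()
        return False

    walk(root, [])
    return path


def evolve_alignment(
    tree: TreeNode,
    ancestor: GenomicSequence,
    sub_rate: float,
    indel_rate: float,
    plant: Optional[MotifPlantSpec],
    seed: int,
) -> tuple[MultipleAlignment, dict]:
    """Evolve an ancestral sequence down a tree and return the leaf alignment
    plus a truth table of expected per-species promoter calls.

    Substitutions are Jukes-Cantor (per-site change probability
    (3/4)(1 - e^(-4*r*t/3)) on a branch of length t); indel events arrive at
    ``indel_rate`` per site per unit branch, half insertions half deletions,
    geometric(0.5) lengths capped at 20. The planted block is written into
    the MRCA of ``clade_leaves`` (its ancestral sites are shielded from
    deletion on the root-to-MRCA path) and frozen within the clade; the
    ``deletion_leaf`` has the ``deletion_window`` replaced by gaps after
    evolution. Truth labels: present / region_deleted / absent.
    """
    seed = _require_seed(seed)
    if sub_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    if any(b not in _BASES for b in ancestor.residues):
        raise ValueError("ancestor must be plain A/C/G/T")
    rng = np.random.default_rng(seed)
    L = len(ancestor)

    motif_ids: frozenset = frozenset()
    path_nodes: set[int] = set()
    mrca: TreeNode | None = None
    if plant is not None:
        if plant.offset_in_ancestor + len(plant.motif) > L:
            raise ValueError("planted motif exceeds ancestor length")
        mrca = tree.mrca(plant.clade_leaves)
        path_nodes = {id(n) for n in _ancestors_of(tree, mrca)}
        motif_ids = frozenset(range(plant.offset_in_ancestor,
                                    plant.offset_in_ancestor + len(plant.motif)))
        leaves = set(tree.leaf_names())
        if plant.deletion_leaf is not None and plant.deletion_leaf not in leaves:
            raise ValueError(f"deletion_leaf {plant.deletion_leaf!r} not in tree")

    order: list[int] = list(range(L))
    master_pos_cache: dict[int, int] = {}  # rebuilt lazily on insertions
    next_id = L

    def master_index(site_id: int) -> int:
        if len(master_pos_cache) != len(order):
            master_pos_cache.clear()
            master_pos_cache.update({sid: i for i, sid in enumerate(order)})
        return master_pos_cache[site_id]

    def evolve_branch(ids: np.ndarray, bases: np.ndarray, t: float,
                      frozen: frozenset, shield: frozenset
                      ) -> tuple[np.ndarray, np.ndarray]:
        nonlocal next_id
        ids = ids.copy()
        bases = bases.copy()
        n = len(ids)
        if n and sub_rate > 0 and t > 0:
            p_change = 0.75 * (1.0 - math.exp(-4.0 * sub_rate * t / 3.0))
            mask = rng.random(n) < p_change
            if frozen:
                mask &= ~np.isin(ids, np.fromiter(frozen, dtype=np.int64))
            k = int(mask.sum())
            if k:
                bases[mask] = (bases[mask] + rng.integers(1, 4, size=k)) % 4
        if indel_rate > 0 and t > 0:
            protected = frozen | shield
            n_events = rng.poisson(indel_rate * t * max(len(ids), 1))
            for _ in range(n_events):
                is_del = rng.random() < 0.5
                length = int(min(rng.geometric(0.5), 20))
                if is_del:
                    if len(ids) <= length:
                        continue
                    start = int(rng.integers(0, len(ids) - length + 1))
                    seg = ids[start : start + length]
                    if protected and not protected.isdisjoint(seg.tolist()):
                        continue
                    ids = np.delete(ids, slice(start, start + length))
                    bases = np.delete(bases, slice(start, start + length))
                else:
                    pos = int(rng.integers(0, len(ids) + 1))
                    # never insert strictly inside a frozen (or shielded) run
                    if (protected and 0 < pos < len(ids)
                            and int(ids[pos - 1]) in protected and int(ids[pos]) in protected):
                        continue
                    new_ids = np.arange(next_id, next_id + length, dtype=np.int64)
                    next_id += length
                    new_bases = rng.integers(0, 4, size=length)
                    if pos == 0 and len(ids):
                        anchor = master_index(int(ids[0]))
                    elif pos > 0:
                        anchor = master_index(int(ids[pos - 1])) + 1
                    else:
                        anchor = len(order)
                    order[anchor:anchor] = new_ids.tolist()
                    master_pos_cache.clear()
                    ids = np.insert(ids, pos, new_ids)
                    bases = np.insert(bases, pos, new_bases)
        return ids, bases

    leaf_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def recurse(node: TreeNode, ids: np.ndarray, bases: np.ndarray,
                frozen: frozenset) -> None:
        if plant is not None and node is mrca:
            positions = np.flatnonzero(
                np.isin(ids, np.fromiter(motif_ids, dtype=np.int64)))
            assert len(positions) == len(plant.motif), "shielded motif sites lost"
            bases[positions] = [_BASE_INDEX[b] for b in plant.motif]
            frozen = motif_ids
        if node.is_leaf:
            leaf_state[node.name] = (ids, bases)
            return
        for child in node.children:
            shield = motif_ids if (plant is not None and id(child) in path_nodes
                                   and not frozen) else frozenset()
            cids, cbases = evolve_branch(ids, bases, child.branch_length, frozen, shield)
            recurse(child, cids, cbases, frozen)

    root_ids = np.arange(L, dtype=np.int64)
    root_bases = np.array([_BASE_INDEX[b] for b in ancestor.residues], dtype=np.int64)
    recurse(tree, root_ids, root_bases, frozenset())

    # --- assemble the alignment -------------------------------------------
    present: set[int] = set()
    for ids, _ in leaf_state.values():
        present.update(ids.tolist())
    columns = [sid for sid in order if sid in present]
    col_index = {sid: i for i, sid in enumerate(columns)}
    rows: dict[str, list[str]] = {}
    species_order = tree.leaf_names()
    for sp in species_order:
        ids, bases = leaf_state[sp]
        row = ["-"] * len(columns)
        for sid, b in zip(ids.tolist(), bases.tolist()):
            row[col_index[sid]] = _BASES[b]
        rows[sp] = row

    # --- apply the lineage-specific deletion ------------------------------
    if plant is not None and plant.deletion_leaf is not None:
        dstart, dlen = plant.deletion_window
        if not 0 <= dstart < dstart + dlen <= L:
            raise ValueError("deletion_window outside ancestor coordinates")
        p_lo = master_index(dstart)
        p_hi = master_index(dstart + dlen - 1)
        span = {sid for sid in order[p_lo : p_hi + 1]}
        target_row = rows[plant.deletion_leaf]
        for sid in span:
            ci = col_index.get(sid)
            if ci is not None:
                target_row[ci] = "-"

    # drop columns that became (or always were) all-gap
    keep = [i for i in range(len(columns))
            if any(rows[sp][i] != "-" for sp in species_order)]
    aln = MultipleAlignment(
        [(sp, "".join(rows[sp][i] for i in keep)) for sp in species_order])

    # --- truth table -------------------------------------------------------
    truth: dict = {"status": {}, "motif_start": {}}
    clade_members: set[str] = set()
    if plant is not None:
        clade_members = set(mrca.leaf_names())
        motif_first = min(motif_ids)
        kept_index = {old: new for new, old in enumerate(keep)}
        first_col = kept_index.get(col_index.get(motif_first, -1))
        for sp in species_order:
            if sp == plant.deletion_leaf:
                truth["status"][sp] = "region_deleted"
            elif sp in clade_members:
                truth["status"][sp] = "present"
                if first_col is not None:
                    row = aln.rows[sp]
                    truth["motif_start"][sp] = sum(
                        1 for ch in row[:first_col] if ch != "-")
            else:
                truth["status"][sp] = "absent"
    else:
        truth["status"] = {sp: "absent" for sp in species_order}
    return aln, truth


# ---------------------------------------------------------------------------
# ready-made promoter screen scenario (the conditions used for recovery tests)
# ---------------------------------------------------------------------------

# The full planted promoter block: TBPL2/TFIIA-type heptamer, a CT-rich
# spacer leading to the TSS 32 bp downstream of the motif start, the TSS
# adenosine, and a GA-rich downstream run.
PROMOTER_BLOCK = "TTCTTAA" + "CT" * 12 + "C" + "A" + "GAGAGAGAGA"
BLOCK_TSS_OFFSET = 32  # position of the TSS within the block


def _balanced_tree(names: Sequence[str], branch_length: float) -> TreeNode:
    if len(names) == 1:
        return TreeNode(name=names[0], branch_length=branch_length)
    half = len(names) // 2
    node = TreeNode(branch_length=branch_length)
    node.children = [_balanced_tree(names[:half], branch_length),
                     _balanced_tree(names[half:], branch_length)]
    return node


def promoter_screen_scenario(seed: int, n_species: int = 20, clade_size: int = 4,
                             ancestor_len: int = 5000, sub_rate: float = 0.04,
                             indel_rate: float = 0.001,
                             with_deletion_leaf: bool = True) -> dict:
    """Build one clade-restricted promoter-gain scenario.

    A balanced tree of ``n_species`` leaves (unit branch lengths) contains a
    ``clade_size``-leaf clade that gains the full promoter block; one clade
    leaf optionally loses the surrounding region (the prairie-vole pattern).
    The ancestral promoter locus carries a G-run background so that
    non-gaining lineages hold no motif-like sequence, which is the
    biological scenario being emulated. Returns the alignment, the truth
    table and the keyword arguments for
    :func:`oopromscan.motif_screen.call_promoters`.
    """
    seed = _require_seed(seed)
    if clade_size < 2 or n_species < clade_size + 2:
        raise ValueError("need at least 2 clade leaves and 2 outgroup species")
    clade = [f"clade{i}" for i in range(clade_size)]
    outgroup = [f"out{i}" for i in range(n_species - clade_size)]
    root = TreeNode()
    root.children = [_balanced_tree(clade, 1.0), _balanced_tree(outgroup, 1.0)]

    block = PROMOTER_BLOCK
    offset = ancestor_len // 2
    anc = list(random_sequence(ancestor_len, seed=seed).residues)
    margin = 12
    anc[offset - margin : offset + len(block) + margin] = "G" * (len(block) + 2 * margin)
    ancestor = GenomicSequence(id="ancestor", residues="".join(anc))

    deletion_leaf = clade[-1] if with_deletion_leaf else None
    plant = MotifPlantSpec(
        clade_leaves=frozenset(clade),
        motif=block,
        offset_in_ancestor=offset,
        deletion_leaf=deletion_leaf,
        deletion_window=(offset - 10, len(block) + 20) if with_deletion_leaf else None,
    )
    aln, truth = evolve_alignment(root, ancestor, sub_rate, indel_rate, plant,
                                  seed=seed + 1)
    ref = clade[0]
    ref_tss = truth["motif_start"][ref] + BLOCK_TSS_OFFSET
    return {
        "alignment": aln,
        "truth": truth,
        "ref_species": ref,
        "ref_tss_pos": ref_tss,
        "plant": plant,
        "tree": root,
    }


# ---------------------------------------------------------------------------
# spliced-read simulation
# ---------------------------------------------------------------------------

@dataclass
class IsoformMixSpec:
    """A two-isoform mixture: full-length vs exon-skipping transcripts."""

    gene: GeneModel
    skip_exon_indices_from_3prime: tuple[int, int] = (2, 3)
    exclusion_fraction: float = 0.3
    n_reads: int = 10_000
    read_length: int = 50
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.exclusion_fraction <= 1.0:
            raise ValueError("exclusion_fraction must lie in [0,1]")
        if self.n_reads < 0 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be positive")


def default_splice_gene() -> GeneModel:
    """A five-exon '+' gene whose geometry makes the junction-spanning
    probability equal between the two isoforms, so the read-level
    exclusion/inclusion ratio estimates the isoform mixing odds directly
    (with read length 50: skipped mature length 199, full 499)."""
    start = 1000
    lengths = [49, 75, 150, 150, 75]
    gap = 200
    exons = []
    cur = start
    for ln in lengths:
        exons.append((cur, cur + ln))
        cur += ln + gap
    return GeneModel(gene_id="DNMT3B", chrom="chr1", strand="+", exons=exons)


def _isoform_cigar(exons: Sequence[tuple[int, int]], mature_start: int,
                   read_length: int) -> tuple[int, str]:
    """Genomic pos and CIGAR of a read at a mature-coordinate offset."""
    remaining = read_length
    cigar: list[str] = []
    pos = None
    cursor = mature_start
    offset = 0
    prev_end = None
    for s, e in exons:
        ex_len = e - s
        if cursor >= offset + ex_len:
            offset += ex_len
            continue
        within = cursor - offset
        take = min(ex_len - within, remaining)
        g_start = s + within
        if pos is None:
            pos = g_start
        else:
            cigar.append(f"{g_start - prev_end}N")
        cigar.append(f"{take}M")
        prev_end = g_start + take
        remaining -= take
        cursor += take
        offset += ex_len
        if remaining == 0:
            break
    if remaining != 0 or pos is None:
        raise ValueError("read extends past the mature transcript")
    return pos, "".join(cigar)


def simulate_spliced_reads(spec: IsoformMixSpec) -> tuple[list[AlignmentRecord], dict]:
    """Single-end reads from a Bernoulli mixture of the full and the
    exon-skipping isoform, with genomic CIGARs (N at junctions) and a truth
    table of reads spanning the discriminating junctions."""
    seed = _require_seed(spec.seed)
    rng = np.random.default_rng(seed)
    gene = spec.gene
    targets, flank_left, flank_right = resolve_exon_pair(
        gene, spec.skip_exon_indices_from_3prime)
    full_exons = list(gene.exons)
    skip_exons = [e for e in gene.exons if e not in targets]

    def mature_len(exons):
        return sum(e - s for s, e in exons)

    L_full, L_skip = mature_len(full_exons), mature_len(skip_exons)
    if spec.read_length >= L_skip or spec.read_length >= L_full:
        raise ValueError("read_length must be smaller than each isoform's mature length")

    # mature position of the flank_left -> flank_right junction in the skip isoform
    acc = 0
    skip_junction_mature = None
    for s, e in skip_exons:
        acc += e - s
        if (s, e) == tuple(flank_left):
            skip_junction_mature = acc
            break
    assert skip_junction_mature is not None
    target_boundaries = {b for exon in targets for b in exon}
    # full-isoform junctions whose genomic boundaries touch a target exon
    incl_junctions_mature = []
    acc = 0
    for (s, e), nxt in zip(full_exons[:-1], full_exons[1:]):
        acc += e - s
        if e in target_boundaries or nxt[0] in target_boundaries:
            incl_junctions_mature.append(acc)

    records: list[AlignmentRecord] = []
    n_skip = n_excl = n_incl = 0
    for i in range(spec.n_reads):
        is_skip = bool(rng.random() < spec.exclusion_fraction)
        exons = skip_exons if is_skip else full_exons
        L = L_skip if is_skip else L_full
        start = int(rng.integers(0, L - spec.read_length + 1))
        pos, cigar = _isoform_cigar(exons, start, spec.read_length)
        records.append(AlignmentRecord(read_id=f"r{i}", chrom=gene.chrom, pos=pos,
                                       cigar=cigar, strand="+"))
        end = start + spec.read_length
        if is_skip:
            n_skip += 1
            if start < skip_junction_mature < end:
                n_excl += 1
        else:
            if any(start < j < end for j in incl_junctions_mature):
                n_incl += 1
    truth = {
        "n_reads": spec.n_reads,
        "n_skip_isoform_reads": n_skip,
        "n_exclusion_spanning": n_excl,
        "n_inclusion_spanning": n_incl,
        "exclusion_fraction": spec.exclusion_fraction,
    }
    return records, truth


# ---------------------------------------------------------------------------
# TE insertion count simulation
# ---------------------------------------------------------------------------

@dataclass
class TESimSpec:
    n_subfamilies: int = 10
    insertions_per_subfamily: int = 80
    genic_fraction: float = 0.2
    fold_changes: Optional[Sequence[float]] = None  # condition B over A, per subfamily
    mean_count: float = 20.0
    library_sizes: Optional[tuple[int, int]] = None
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_subfamilies < 1 or self.insertions_per_subfamily < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.genic_fraction <= 1.0:
            raise ValueError("genic_fraction must lie in [0,1]")
        if self.fold_changes is None:
            self.fold_changes = [1.0] * self.n_subfamilies
        if len(self.fold_changes) != self.n_subfamilies:
            raise ValueError("fold_changes must have one entry per subfamily")
        if any(f < 0 for f in self.fold_changes):
            raise ValueError("fold changes must be >= 0")


def simulate_te_counts(spec: TESimSpec) -> tuple[list[TEInsertion], CountsTable, pd.DataFrame]:
    """Per-insertion two-condition counts: Poisson around the subfamily mean,
    condition B scaled by the subfamily's true fold change; a fixed fraction
    of insertions per subfamily is genic. Truth records each subfamily's
    fold change and its eligible-insertion count under the default
    (>50 intergenic insertions with >5 reads) filter."""
    seed = _require_seed(spec.seed)
    rng = np.random.default_rng(seed)
    insertions: list[TEInsertion] = []
    rows_a: list[int] = []
    rows_b: list[int] = []
    index: list[str] = []
    n_genic = int(round(spec.genic_fraction * spec.insertions_per_subfamily))
    pos = 10_000
    for s in range(spec.n_subfamilies):
        sf = f"SF{s}"
        te_class = TE_CLASSES[s % 3]  # cycle LINE/SINE/LTR
        fold = spec.fold_changes[s]
        for i in range(spec.insertions_per_subfamily):
            iid = f"{sf}_ins{i}"
            insertions.append(TEInsertion(
                insertion_id=iid, subfamily=sf, te_class=te_class, chrom="chr1",
                start=pos, end=pos + 300, genic=i < n_genic))
            pos += 1000
            rows_a.append(int(rng.poisson(spec.mean_count)))
            rows_b.append(int(rng.poisson(spec.mean_count * fold)))
            index.append(iid)
    counts = pd.DataFrame({"condA": rows_a, "condB": rows_b}, index=index)
    if spec.library_sizes is None:
        lib = {"condA": int(counts["condA"].sum()), "condB": int(counts["condB"].sum())}
    else:
        lib = {"condA": spec.library_sizes[0], "condB": spec.library_sizes[1]}
    table = CountsTable(counts, lib)

    eligible_counts: dict[str, int] = {}
    for ins in insertions:
        if ins.genic:
            continue
        row = counts.loc[ins.insertion_id]
        if row["condA"] > 5 or row["condB"] > 5:
            eligible_counts[ins.subfamily] = eligible_counts.get(ins.subfamily, 0) + 1
    truth = pd.DataFrame({
        "subfamily": [f"SF{s}" for s in range(spec.n_subfamilies)],
        "te_class": [TE_CLASSES[s % 3] for s in range(spec.n_subfamilies)],
        "fold_change": list(spec.fold_changes),
        "eligible_insertions": [eligible_counts.get(f"SF{s}", 0)
                                for s in range(spec.n_subfamilies)],
    }).set_index("subfamily")
    return insertions, table, truth


# ---------------------------------------------------------------------------
# codon mutation
# ---------------------------------------------------------------------------

def _codon_options(codon: str) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """(synonymous, nonsynonymous) single-nucleotide change options that do
    not create a stop codon."""
    syn: list[tuple[int, str]] = []
    nonsyn: list[tuple[int, str]] = []
    aa = _CODON_AA[codon]
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            (syn if _CODON_AA[neighbour] == aa else nonsyn).append((pos, alt))
    return syn, nonsyn


def mutate_codons(seq: str, n_syn: int, n_nonsyn: int, seed: int) -> str:
    """Apply exactly ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous
    single-nucleotide changes at distinct codons, never creating a stop."""
    seed = _require_seed(seed)
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("sequence contains internal stop codons")
    if n_syn < 0 or n_nonsyn < 0:
        raise ValueError("change counts must be >= 0")
    rng = np.random.default_rng(seed)

    options = [(_codon_options(c) if "N" not in c else ([], [])) for c in codons]
    syn_only = [i for i, (s, n) in enumerate(options) if s and not n]
    nonsyn_only = [i for i, (s, n) in enumerate(options) if n and not s]
    both = [i for i, (s, n) in enumerate(options) if s and n]
    for pool in (syn_only, nonsyn_only, both):
        rng.shuffle(pool)

    # nonsynonymous picks prefer codons without synonymous options
    nonsyn_picks = (nonsyn_only + both)[:n_nonsyn]
    remaining_both = [i for i in both if i not in nonsyn_picks]
    syn_picks = (syn_only + remaining_both)[:n_syn]
    if len(nonsyn_picks) < n_nonsyn or len(syn_picks) < n_syn:
        raise ValueError("infeasible request: not enough codons with suitable changes")

    out = list(codons)
    for i in nonsyn_picks:
        pos, alt = options[i][1][int(rng.integers(0, len(options[i][1])))]
        out[i] = out[i][:pos] + alt + out[i][pos + 1 :]
    for i in syn_picks:
        pos, alt = options[i][0][int(rng.integers(0, len(options[i][0])))]
        out[i] = out[i][:pos] + alt + out[i][pos + 1 :]
    return "".join(out)


# ---------------------------------------------------------------------------
# HMM column sampling (for conservation-recovery tests)
# ---------------------------------------------------------------------------

def sample_hmm_columns(n_columns: int, params: HmmParams, n_nongap: int = 8,
                       seed: int = None) -> tuple[list[ColumnSummary], np.ndarray]:
    """Sample column summaries from the conservation HMM itself; returns the
    columns and the true state path (1 = conserved, 0 = background)."""
    seed = _require_seed(seed)
    if n_columns < 1 or n_nongap < 1:
        raise ValueError("n_columns and n_nongap must be >= 1")
    rng = np.random.default_rng(seed)
    A = params.transition_matrix()  # rows: (conserved, background)
    states = np.empty(n_columns, dtype=np.int64)
    conserved = rng.random() < params.target_coverage
    for t in range(n_columns):
        if t > 0:
            stay = A[0, 0] if conserved else A[1, 1]
            if rng.random() >= stay:
                conserved = not conserved
        states[t] = 1 if conserved else 0
    p = np.where(states == 1, params.p_match_conserved, params.p_match_background)
    matches = rng.binomial(n_nongap, p)
    cols = [ColumnSummary(n_nongap, int(k)) for k in matches]
    return cols, states
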