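"""Transposable-element insertion quantification between two conditions.

Implements the TE side of a knock-out vs control comparison: per-class read
fractions, the insertion-eligibility filter (a subfamily is analysed only if
it has more than ``min_insertions`` insertions outside gene annotation with
more than ``min_reads`` reads in either condition -- strict inequalities),
twofold up/down/same classification of individual insertions on
pseudocounted CPM fold changes, and a resampling-based differential
expression probability for designs without biological replicates. The
latter is an explicit approximation in the spirit of NOISeq-sim (simulated
technical replicates define a noise distribution of |log2 fold|, |CPM
difference| pairs); numeric agreement with the published tool is not
claimed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import BedRecord, GeneModel

TE_CLASSES = ("LINE", "SINE", "LTR", "other")


@dataclass
class TEInsertion:
    insertion_id: str
    subfamily: str
    te_class: str
    chrom: str
    start: int
    end: int
    genic: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"insertion {self.insertion_id!r}: end <= start")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"insertion {self.insertion_id!r}: unknown class {self.te_class!r}")


class CountsTable:
    """Non-negative integer counts, rows = features, two condition columns."""

    def __init__(self, counts: pd.DataFrame, library_sizes: dict[str, int] | pd.Series):
        counts = counts.astype(np.int64)
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        lib = pd.Series(library_sizes).astype(np.int64)
        for cond in counts.columns:
            if cond not in lib.index:
                raise ValueError(f"missing library size for condition {cond!r}")
            if lib[cond] < counts[cond].sum():
                raise ValueError(f"library size for {cond!r} smaller than its column sum")
        self.counts = counts
        self.library_sizes = lib[list(counts.columns)]

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


def annotate_genic(insertions: Iterable[TEInsertion], genes: Iterable[GeneModel]
                   ) -> list[TEInsertion]:
    """Flag insertions overlapping any gene body span (exons and introns);
    'outside gene annotation' means zero-bp overlap with any gene body."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append(g.span)
    out = []
    for ins in insertions:
        genic = any(
            ins.start < e and s < ins.end for s, e in spans.get(ins.chrom, [])
        )
        out.append(TEInsertion(ins.insertion_id, ins.subfamily, ins.te_class,
                               ins.chrom, ins.start, ins.end, genic=genic))
    return out


def class_read_fraction(counts: CountsTable,
                        te_class_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Percentage of TE-mapped reads per retrotransposon class, per condition.

    If ``te_class_of`` is given, rows are first aggregated by class;
    otherwise row labels are taken to be classes already.
    """
    df = counts.counts
    if te_class_of is not None:
        df = df.groupby([te_class_of[f] for f in df.index]).sum()
    if df.empty:
        raise ValueError("no TE classes to summarise")
    totals = df.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a condition has zero TE-mapped reads")
    return 100.0 * df / totals


def eligible_subfamilies(insertions: Sequence[TEInsertion], counts: CountsTable,
                         min_insertions: int = 50, min_reads: int = 5) -> set[str]:
    """Subfamilies with more than ``min_insertions`` intergenic insertions
    having more than ``min_reads`` reads in either condition (both strict)."""
    cond_a, cond_b = counts.conditions[:2]
    qualifying: dict[str, int] = {}
    for ins in insertions:
        if ins.genic or ins.insertion_id not in counts.counts.index:
            continue
        row = counts.counts.loc[ins.insertion_id]
        if row[cond_a] > min_reads or row[cond_b] > min_reads:
            qualifying[ins.subfamily] = qualifying.get(ins.subfamily, 0) + 1
    return {sf for sf, n in qualifying.items() if n > min_insertions}


def _cpm(count, library_size, pseudocount: float = 0.5):
    return (np.asarray(count, dtype=float) + pseudocount) / library_size * 1e6


def classify_insertions(counts: CountsTable, fold_threshold: float = 2.0,
                        pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-insertion up/down/same calls on pseudocounted CPM fold change
    (condition B over condition A)."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    cond_a, cond_b = counts.conditions[:2]
    cpm_a = _cpm(counts.counts[cond_a], counts.library_sizes[cond_a], pseudocount)
    cpm_b = _cpm(counts.counts[cond_b], counts.library_sizes[cond_b], pseudocount)
    fold = cpm_b / cpm_a
    cls = np.where(fold > fold_threshold, "up",
                   np.where(fold < 1.0 / fold_threshold, "down", "same"))
    return pd.DataFrame({"fold": fold, "cls": cls}, index=counts.counts.index)


def class_proportions(calls: pd.DataFrame, subfamily_of: dict[str, str]) -> pd.DataFrame:
    """Per-subfamily proportions of up/down/same insertion calls."""
    df = calls.copy()
    df["subfamily"] = [subfamily_of[f] for f in df.index]
    out = (
        df.groupby("subfamily")["cls"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for col in ("up", "down", "same"):
        if col not in out.columns:
            out[col] = 0.0
    return out[["up", "down", "same"]]


def de_probability(counts_a: Sequence[int], counts_b: Sequence[int],
                   library_sizes: tuple[int, int], n_noise_replicates: int = 5,
                   replicate_fraction: float = 0.2, seed: int | None = None,
                   pseudocount: float = 0.5) -> np.ndarray:
    """Per-feature differential-expression probability from simulated
    technical replicates (no biological replicates assumed).

    For each condition, ``n_noise_replicates`` multinomial technical
    replicates of depth ``replicate_fraction * library_size`` are drawn over
    features; all within-condition replicate pairs, pooled over features,
    yield a noise distribution of (|M|, |D|) = (|log2 CPM fold|, |CPM
    difference|) pairs. A feature's probability is the fraction of noise
    pairs strictly dominated (in both coordinates) by its observed
    between-condition (|M|, |D|).
    """
    if not 0.0 < replicate_fraction <= 1.0:
        raise ValueError("replicate_fraction must lie in (0, 1]")
    if n_noise_replicates < 2:
        raise ValueError("need at least 2 noise replicates per condition")
    if seed is None:
        raise ValueError("seed is mandatory for de_probability")
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    lib_a, lib_b = library_sizes
    rng = np.random.default_rng(seed)

    noise_m: list[np.ndarray] = []
    noise_d: list[np.ndarray] = []
    for counts, lib in ((a, lib_a), (b, lib_b)):
        total = counts.sum()
        if total == 0:
            raise ValueError("a condition has zero total counts")
        depth = max(1, int(round(replicate_fraction * lib)))
        reps = rng.multinomial(depth, counts / total, size=n_noise_replicates)
        rep_cpm = _cpm(reps, depth, pseudocount)  # (R, F)
        for i in range(n_noise_replicates):
            for j in range(i + 1, n_noise_replicates):
                noise_m.append(np.abs(np.log2(rep_cpm[i] / rep_cpm[j])))
                noise_d.append(np.abs(rep_cpm[i] - rep_cpm[j]))
    nm = np.concatenate(noise_m)
    nd = np.concatenate(noise_d)

    cpm_a = _cpm(a, lib_a, pseudocount)
    cpm_b = _cpm(b, lib_b, pseudocount)
    obs_m = np.abs(np.log2(cpm_b / cpm_a))
    obs_d = np.abs(cpm_b - cpm_a)

    probs = np.empty(len(a))
    chunk = 256
    for lo in range(0, len(a), chunk):
        hi = min(lo + chunk, len(a))
        dominated = (obs_m[lo:hi, None] > nm[None, :]) & (obs_d[lo:hi, None] > nd[None, :])
        probs[lo:hi] = dominated.mean(axis=1)
    return probs


def insertions_to_bed(insertions: Iterable[TEInsertion]) -> list[BedRecord]:
    return [
        BedRecord(chrom=i.chrom, start=i.start, end=i.end,
                  name=f"{i.subfamily}|{i.te_class}",
                  score="1" if i.genic else "0")
        for i in insertions
    ]


def insertions_from_bed(records: Iterable[BedRecord]) -> list[TEInsertion]:
    out = []
    for n, r in enumerate(records):
        if "|" not in r.name:
            raise ValueError(f"BED name field must be 'subfamily|class', got {r.name!r}")
        subfamily, te_class = r.name.split("|", 1)
        out.append(TEInsertion(insertion_id=f"ins{n}", subfamily=subfamily,
                               te_class=te_class, chrom=r.chrom, start=r.start,
                               end=r.end, genic=r.score == "1"))
    return out
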