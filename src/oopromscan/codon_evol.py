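"""Pairwise dN/dS by the Nei-Gojobori (1986) counting method, plus the
likelihood-ratio test utility used for codon-model comparison.

Synonymous and nonsynonymous *sites* are counted per codon by enumerating
the nine single-nucleotide neighbours under the standard genetic code;
mutations to stop codons are excluded, and each codon position contributes
(synonymous fraction, 1 - synonymous fraction), so S + N = 3 per compared
codon. *Differences* between codons differing at several positions are
averaged over all orderings of minimal mutational paths, with paths passing
through a stop codon excluded. Proportions are Jukes-Cantor corrected,
d = -(3/4) ln(1 - (4/3) p); a proportion >= 3/4 is reported as saturated.
Codons containing N in either sequence are skipped pairwise (the upstream
convention replaces internal stop codons with NNN).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import chi2

_BASES = "ACGT"
_CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


@dataclass
class CodonAlignment:
    """Two gap-free coding sequences of equal length divisible by 3."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper().replace("U", "T")
        self.seq_b = self.seq_b.upper().replace("U", "T")
        for label, s in (("a", self.seq_a), ("b", self.seq_b)):
            if not s:
                raise ValueError(f"sequence {label}: empty")
            if len(s) % 3:
                raise ValueError(f"sequence {label}: length {len(s)} not divisible by 3")
            if any(ch not in "ACGTN" for ch in s):
                raise ValueError(f"sequence {label}: invalid character")
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if "N" not in codon and codon in STOP_CODONS:
                    raise ValueError(f"sequence {label}: internal stop codon {codon} at codon {i // 3}")
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("sequences must have equal length")

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    n_codons_compared: int
    saturated: bool = False


def synonymous_sites(codon: str) -> float:
    """Synonymous site count of one codon: per position, the fraction of the
    (non-stop) single-nucleotide changes that preserve the amino acid."""
    aa = _CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            valid += 1
            if _CODON_AA[neighbour] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _path_differences(ca: str, cb: str) -> Optional[tuple[float, float]]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all stop-free minimal mutational paths; None if every path is
    blocked by a stop codon."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    return (sum(t[0] for t in totals) / len(totals),
            sum(t[1] for t in totals) / len(totals))


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(aln: CodonAlignment) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS estimate."""
    S = N = Sd = Nd = 0.0
    n_compared = 0
    for ca, cb in aln.codon_pairs():
        if "N" in ca or "N" in cb:
            continue
        diffs = _path_differences(ca, cb)
        if diffs is None:
            continue  # all mutational paths blocked by stops; rare, skipped whole
        n_compared += 1
        S += (synonymous_sites(ca) + synonymous_sites(cb)) / 2.0
        N += 3.0 - (synonymous_sites(ca) + synonymous_sites(cb)) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
    if n_compared == 0:
        raise ValueError("no comparable codon pairs")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    saturated = dS is None or dN is None
    omega: Optional[float] = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DnDsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
                      omega=omega, n_codons_compared=n_compared, saturated=saturated)


def likelihood_ratio_test(lnl_null: float, lnl_alt: float, df: int) -> tuple[float, float]:
    """LRT statistic 2(lnL_alt - lnL_null) and its chi-squared upper-tail p."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0:
        warnings.warn("alternative log-likelihood below null; clamping statistic to 0",
                      stacklevel=2)
        stat = 0.0
    return stat, float(chi2.sf(stat, df))
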