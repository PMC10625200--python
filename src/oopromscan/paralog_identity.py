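"""Longest exact identity window between two sequences.

Used to rule out short-read cross-mapping between a gene and its paralogs:
if the longest stretch of continuous sequence identity is far shorter than
the read length, reads cannot multi-map between them. Ambiguity characters
never match: an 'N' in either sequence matches nothing, including another
'N', so undetermined sequence cannot inflate the identity window.

The implementation builds a suffix automaton of the first sequence and
streams the second through it (O(|a| + |b|)); tests check it against a
quadratic dynamic-programming oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GenomicSequence
from .motif_screen import reverse_complement


@dataclass
class IdentityWindow:
    length: int
    pos_a: int
    pos_b: int
    revcomp: bool = False


class _SuffixAutomaton:
    __slots__ = ("next", "link", "length", "last")

    def __init__(self, s: str):
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self.last = 0
        for ch in s:
            self._extend(ch)

    def _extend(self, ch: str) -> None:
        cur = len(self.length)
        self.next.append({})
        self.length.append(self.length[self.last] + 1)
        self.link.append(-1)
        p = self.last
        while p != -1 and ch not in self.next[p]:
            self.next[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.next[p][ch]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.length)
                self.next.append(dict(self.next[q]))
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                while p != -1 and self.next[p].get(ch) == q:
                    self.next[p][ch] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self.last = cur


def _mask_n(s: str, sentinel: str) -> str:
    # each sequence gets its own sentinel so N never matches N across sequences
    return s.replace("N", sentinel)


def _lcs_length(a: str, b: str) -> int:
    """Length of the longest common substring via suffix automaton of ``a``."""
    sam = _SuffixAutomaton(a)
    best = 0
    v, l = 0, 0
    for ch in b:
        while v and ch not in sam.next[v]:
            v = sam.link[v]
            l = sam.length[v]
        if ch in sam.next[v]:
            v = sam.next[v][ch]
            l += 1
        else:
            v, l = 0, 0
        if l > best:
            best = l
    return best


def longest_shared_window(a: GenomicSequence | str, b: GenomicSequence | str,
                          include_revcomp: bool = False) -> IdentityWindow:
    """Longest common exact substring of ``a`` and ``b``.

    Ties are broken by the smallest (pos_a, pos_b). With ``include_revcomp``
    the reverse complement of ``b`` is also searched and the overall maximum
    returned (``revcomp`` flags which orientation won; forward wins ties);
    ``pos_b`` is then a position in the reverse-complemented sequence.
    """
    a_obj = a if isinstance(a, GenomicSequence) else GenomicSequence(id="a", residues=a)
    b_obj = b if isinstance(b, GenomicSequence) else GenomicSequence(id="b", residues=b)
    fwd = _best_window(a_obj.residues, b_obj.residues, revcomp=False)
    if not include_revcomp:
        return fwd
    rc = _best_window(a_obj.residues, reverse_complement(b_obj).residues, revcomp=True)
    return rc if rc.length > fwd.length else fwd


def _best_window(a: str, b: str, revcomp: bool) -> IdentityWindow:
    if not a or not b:
        raise ValueError("empty input sequence")
    am, bm = _mask_n(a, "\x01"), _mask_n(b, "\x02")
    best = _lcs_length(am, bm)
    if best == 0:
        return IdentityWindow(length=0, pos_a=0, pos_b=0, revcomp=revcomp)
    # locate the smallest (pos_a, pos_b) among maximal windows
    candidates = {bm[i : i + best] for i in range(len(bm) - best + 1)}
    pos_a = pos_b = None
    for i in range(len(am) - best + 1):
        sub = am[i : i + best]
        if sub in candidates:
            pos_a = i
            pos_b = bm.find(sub)
            break
    assert pos_a is not None and pos_b is not None and pos_b >= 0
    return IdentityWindow(length=best, pos_a=pos_a, pos_b=pos_b, revcomp=revcomp)
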