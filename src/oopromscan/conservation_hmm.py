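"""A two-state conservation HMM over alignment columns.

This is a deliberately simplified stand-in for phylogenetic conservation
segmentation (phastCons-style): there is no substitution model and no tree.
Each alignment column is summarised by (number of non-gap rows, number of
rows equal to the column majority residue), and a two-state HMM with
binomial emissions -- a conserved state with high per-row match probability
and a background state with a lower one -- is decoded by log-space
forward-backward. The parameterisation keeps the two knobs that matter for
segmentation behaviour: the expected conserved run length L (conserved
self-transition 1 - 1/L) and the stationary conserved coverage gamma
(background-to-conserved rate nu = (gamma/L)/(1 - gamma)).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import binom

from .io_formats import GAP, MultipleAlignment


class ColumnSummary(NamedTuple):
    n_nongap: int
    n_match: int


class UnderflowError(FloatingPointError):
    """Raised when the forward-backward recursion loses all probability mass."""


@dataclass
class HmmParams:
    expected_length: float = 7.0
    target_coverage: float = 0.3
    p_match_conserved: float = 0.9
    p_match_background: float = 0.55

    def __post_init__(self) -> None:
        if self.expected_length <= 1:
            raise ValueError("expected_length must be > 1")
        if not 0.0 < self.target_coverage < 1.0:
            raise ValueError("target_coverage must lie in (0,1)")
        for p in (self.p_match_conserved, self.p_match_background):
            if not 0.0 < p < 1.0:
                raise ValueError("match probabilities must lie in (0,1)")
        if self.p_match_conserved <= self.p_match_background:
            raise ValueError("p_match_conserved must exceed p_match_background")
        if self.nu > 1.0:
            raise ValueError(
                "target_coverage too high for expected_length: derived "
                "background->conserved rate exceeds 1 (need coverage <= L/(1+L))"
            )

    @property
    def self_conserved(self) -> float:
        return 1.0 - 1.0 / self.expected_length

    @property
    def nu(self) -> float:
        """Background -> conserved transition probability."""
        g, L = self.target_coverage, self.expected_length
        return (g / L) / (1.0 - g)

    def transition_matrix(self) -> np.ndarray:
        """Rows/cols ordered (conserved, background); stationary = (gamma, 1-gamma)."""
        return np.array(
            [[self.self_conserved, 1.0 - self.self_conserved],
             [self.nu, 1.0 - self.nu]]
        )

    def stationary(self) -> np.ndarray:
        return np.array([self.target_coverage, 1.0 - self.target_coverage])


@dataclass
class ConservationTrack:
    posterior_conserved: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)
    columns: list[ColumnSummary] = field(default_factory=list)
    log_likelihood: float = 0.0


def summarize_columns(aln: MultipleAlignment,
                      species_subset: Iterable[str] | None = None) -> list[ColumnSummary]:
    """Per-column (non-gap count, matches to the majority residue) over a
    species subset. Majority ties go to the lexicographically smallest
    residue; an all-gap column summarises to (0, 0)."""
    subset = list(species_subset) if species_subset is not None else aln.species
    missing = [s for s in subset if s not in aln]
    if missing:
        raise ValueError(f"species not in alignment: {missing}")
    if len(subset) < 2:
        raise ValueError("need at least 2 species to summarise conservation")
    rows = [aln.rows[s] for s in subset]
    out: list[ColumnSummary] = []
    for j in range(aln.length):
        residues = [r[j] for r in rows if r[j] != GAP]
        if not residues:
            out.append(ColumnSummary(0, 0))
            continue
        counts: dict[str, int] = {}
        for b in residues:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        majority = min(b for b, c in counts.items() if c == best)
        out.append(ColumnSummary(len(residues), counts[majority]))
    return out


def _log_emissions(cols: Sequence[ColumnSummary], params: HmmParams) -> np.ndarray:
    """(T, 2) log emission likelihoods; all-gap columns emit likelihood 1."""
    n = np.array([c.n_nongap for c in cols])
    k = np.array([c.n_match for c in cols])
    logB = np.zeros((len(cols), 2))
    informative = n > 0
    for s, p in enumerate((params.p_match_conserved, params.p_match_background)):
        logB[informative, s] = binom.logpmf(k[informative], n[informative], p)
    if not np.all(np.isfinite(logB)):
        raise UnderflowError("non-finite emission log-likelihood")
    return logB


def posterior_conserved(cols: Sequence[ColumnSummary], params: HmmParams,
                        segment_threshold: float = 0.5,
                        segment_min_len: int = 1) -> ConservationTrack:
    """Forward-backward posterior probability of the conserved state per column."""
    if len(cols) == 0:
        raise ValueError("need at least one column")
    logB = _log_emissions(cols, params)
    logA = np.log(params.transition_matrix())
    logpi = np.log(params.stationary())
    T = len(cols)

    fwd = np.empty((T, 2))
    fwd[0] = logpi + logB[0]
    for t in range(1, T):
        # fwd[t, j] = logsum_i fwd[t-1, i] + logA[i, j] + logB[t, j]
        fwd[t] = logB[t] + np.logaddexp(fwd[t - 1, 0] + logA[0], fwd[t - 1, 1] + logA[1])
    loglik = float(np.logaddexp(fwd[-1, 0], fwd[-1, 1]))
    if not np.isfinite(loglik):
        raise UnderflowError("forward recursion underflowed")

    bwd = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        term = bwd[t + 1] + logB[t + 1]
        bwd[t] = np.logaddexp(logA[:, 0] + term[0], logA[:, 1] + term[1])

    log_post = fwd + bwd - loglik
    post = np.exp(log_post)
    norm = post.sum(axis=1)
    if not np.all(np.isfinite(norm)) or np.any(norm <= 0):
        raise UnderflowError("posterior normalisation underflowed")
    post /= norm[:, None]

    track = ConservationTrack(
        posterior_conserved=post[:, 0],
        columns=list(cols),
        log_likelihood=loglik,
    )
    track.segments = conserved_segments(track, segment_threshold, segment_min_len)
    return track


def conserved_segments(track: ConservationTrack | np.ndarray, threshold: float,
                       min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of posterior >= threshold, at least ``min_len`` long,
    as half-open column ranges."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0,1)")
    post = track.posterior_conserved if isinstance(track, ConservationTrack) else np.asarray(track)
    segments: list[tuple[int, int]] = []
    start = None
    for i, p in enumerate(post):
        if p >= threshold:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                segments.append((start, i))
            start = None
    if start is not None and len(post) - start >= min_len:
        segments.append((start, len(post)))
    return segments


def track_to_tsv(track: ConservationTrack) -> str:
    lines = ["column\tn_nongap\tn_match\tposterior_conserved"]
    for i, p in enumerate(track.posterior_conserved):
        c = track.columns[i] if track.columns else ColumnSummary(0, 0)
        lines.append(f"{i}\t{c.n_nongap}\t{c.n_match}\t{p:.6f}")
    return "\n".join(lines) + "\n"
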