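"""End-to-end screen orchestration: configuration, logging, report bundle.

``run_screen`` ties the per-stage operations together: it reads an
alignment, produces per-species promoter calls, a conservation track with
segments, and (when read alignments and gene models are supplied) an
expression table. Outputs are deterministic given the inputs and seed, and
re-running into the same directory overwrites them identically.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .conservation_hmm import (HmmParams, posterior_conserved, summarize_columns,
                               track_to_tsv)
from .expression_quant import expression_to_tsv, quantify_genes
from .io_formats import parse_sam_min, read_alignment, read_gene_models
from .motif_screen import MotifModel, TssContextModel, call_promoters, calls_to_tsv


@dataclass
class ScreenConfig:
    alignment: str
    ref_species: str
    ref_tss_pos: int
    alignment_dialect: str = "aligned-fasta"
    sam: Optional[str] = None
    genes: Optional[str] = None
    paired: bool = False
    consensus: str = "TTCTTAA"
    max_mismatches: int = 1
    expected_offset: int = 32
    offset_tolerance: int = 5
    partial_max: Optional[int] = None
    deletion_gap_threshold: float = 0.5
    upstream_window: int = 10
    downstream_window: int = 10
    ct_min_fraction: float = 0.8
    ga_min_fraction: float = 0.8
    expected_length: float = 7.0
    target_coverage: float = 0.3
    p_match_conserved: float = 0.9
    p_match_background: float = 0.55
    segment_threshold: float = 0.5
    segment_min_len: int = 1
    hmm_species: Optional[list[str]] = None
    seed: int = 0
    out_dir: str = "screen_out"

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for label, p in (("alignment", self.alignment), ("sam", self.sam),
                         ("genes", self.genes)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config error: {label} path {p!r} does not exist")


def run_screen(config: ScreenConfig) -> dict[str, Path]:
    """Run the full screen and write calls.tsv, track.tsv, segments.bed,
    expr.tsv (if reads given) and run.log into the output directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"oopromscan {__version__}", "config:"]
    log_lines += [f"  {k}: {v}" for k, v in vars(config).items()]
    outputs: dict[str, Path] = {}
    timings: list[tuple[str, float]] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    log_lines.append(f"stage {name}: FAILED ({exc})")
                    (out / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                timings.append((name, time.perf_counter() - self_inner.t0))

        return _Timer()

    with stage("screen"):
        aln = read_alignment(config.alignment, dialect=config.alignment_dialect)
        motif = MotifModel(consensus=config.consensus,
                           max_mismatches=config.max_mismatches,
                           expected_offset_upstream_of_tss=config.expected_offset,
                           offset_tolerance=config.offset_tolerance)
        context = TssContextModel(upstream_window=config.upstream_window,
                                  downstream_window=config.downstream_window,
                                  ct_min_fraction=config.ct_min_fraction,
                                  ga_min_fraction=config.ga_min_fraction)
        calls = call_promoters(aln, config.ref_species, config.ref_tss_pos,
                               motif=motif, context=context,
                               deletion_gap_threshold=config.deletion_gap_threshold,
                               partial_max=config.partial_max)
        outputs["calls"] = out / "calls.tsv"
        outputs["calls"].write_text(calls_to_tsv(calls))

    with stage("conservation"):
        params = HmmParams(expected_length=config.expected_length,
                           target_coverage=config.target_coverage,
                           p_match_conserved=config.p_match_conserved,
                           p_match_background=config.p_match_background)
        cols = summarize_columns(aln, config.hmm_species)
        track = posterior_conserved(cols, params,
                                    segment_threshold=config.segment_threshold,
                                    segment_min_len=config.segment_min_len)
        outputs["track"] = out / "track.tsv"
        outputs["track"].write_text(track_to_tsv(track))
        outputs["segments"] = out / "segments.bed"
        bed = "".join(f"alignment\t{s}\t{e}\tconserved\t0\t+\n" for s, e in track.segments)
        outputs["segments"].write_text(bed)

    if config.sam is not None and config.genes is not None:
        with stage("expression"):
            records = parse_sam_min(config.sam)
            genes = read_gene_models(config.genes)
            expr = quantify_genes(records, genes.values(), paired_mode=config.paired)
            outputs["expr"] = out / "expr.tsv"
            outputs["expr"].write_text(expression_to_tsv(expr))

    for name, dt in timings:
        log_lines.append(f"stage {name}: {dt:.3f}s")
    outputs["log"] = out / "run.log"
    outputs["log"].write_text("\n".join(log_lines) + "\n")
    return outputs
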