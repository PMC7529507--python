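"""End-to-end driver: simulate -> correct -> segment -> infer, config-driven.

The run configuration is a flat ``key: value`` text file (one pair per
line, ``#`` comments allowed); unknown keys are rejected so typos fail
loudly.  All outputs are plain TSV without timestamps, so an identical
configuration and seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons
from . import infer, io, preprocess, simulate

log = logging.getLogger("puriploid")

__all__ = ["RunConfig", "read_config", "run_pipeline", "call_sample"]


@dataclass
class RunConfig:
    """Validated flat configuration for `puriploid run`."""

    seed: int = 0
    out_dir: str = "puriploid_out"
    sample: str = "sample"
    # simulation
    purity: float = 0.6
    n_chroms: int = 8
    chrom_length: int = simulate.DEFAULT_CHROM_LENGTH
    event_rate: float = 3.0
    wgd: bool = False
    subclone_fraction: float | None = None
    coverage: float = 0.5
    bin_size: int = 100_000
    snps_per_mb: float = 150.0
    # preprocessing
    penalty: float | None = None
    min_snps: int = preprocess.DEFAULT_MIN_SNPS
    min_total_depth: int = preprocess.DEFAULT_MIN_TOTAL_DEPTH
    # inference
    max_copies: int = infer.DEFAULT_MAX_COPIES
    wgd_margin: float = infer.DEFAULT_WGD_MARGIN
    abstain_aberrant_frac: float = 0.01
    # optional downstream inputs
    purity_matrix: str | None = None
    pathology: str | None = None
    analyte_map: str | None = None


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_config(path) -> RunConfig:
    """Parse a flat key:value config file into a RunConfig."""
    known = {f.name: f for f in fields(RunConfig)}
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise io.ValidationError(f"{path}: line {lineno}: expected 'key: value'")
            key, val = (s.strip() for s in line.split(":", 1))
            if key not in known:
                raise io.ValidationError(f"{path}: line {lineno}: unknown key {key!r}")
            values[key] = val
    cfg = RunConfig()
    for key, val in values.items():
        f = known[key]
        ann = f.type
        if val.lower() in ("none", "na", ""):
            setattr(cfg, key, None)
        elif ann in ("int",):
            setattr(cfg, key, int(val))
        elif ann in ("float", "float | None"):
            setattr(cfg, key, float(val))
        elif ann == "bool":
            if val.lower() not in _BOOL:
                raise io.ValidationError(f"{path}: {key}: expected a boolean, got {val!r}")
            setattr(cfg, key, _BOOL[val.lower()])
        else:
            setattr(cfg, key, val)
    return cfg


def call_sample(
    bins: pd.DataFrame,
    snps: pd.DataFrame,
    penalty: float | None = None,
    min_snps: int = preprocess.DEFAULT_MIN_SNPS,
    min_total_depth: int = preprocess.DEFAULT_MIN_TOTAL_DEPTH,
    max_copies: int = infer.DEFAULT_MAX_COPIES,
    wgd_margin: float = infer.DEFAULT_WGD_MARGIN,
    thresholds: infer.Thresholds | None = None,
) -> infer.PurityCall:
    """Run GC correction, segmentation, BAF pooling and joint inference."""
    curve = preprocess.fit_gc_correction(bins)
    corrected = preprocess.apply_gc_correction(bins, curve)
    segments = preprocess.segment_logr(corrected, penalty=penalty)
    segments = preprocess.refine_segments_baf(segments, corrected, snps)
    segments = preprocess.aggregate_segment_baf(
        segments, snps, min_snps=min_snps, min_total_depth=min_total_depth
    )
    return infer.call_segments(
        segments,
        max_copies=max_copies,
        wgd_score_margin=wgd_margin,
        thresholds=thresholds,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured chain and write artifacts under ``out_dir``.

    Returns a summary dict with the paths written and the purity call.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run: seed=%d out_dir=%s", cfg.seed, cfg.out_dir)

    truth = simulate.simulate_truth_profile(
        n_chroms=cfg.n_chroms,
        purity=cfg.purity,
        event_rate=cfg.event_rate,
        wgd=cfg.wgd,
        subclone_fraction=cfg.subclone_fraction,
        seed=cfg.seed,
        chrom_length=cfg.chrom_length,
    )
    sim_cfg = simulate.SimConfig(
        mean_coverage=cfg.coverage,
        bin_size=cfg.bin_size,
        n_het_snps_per_mb=cfg.snps_per_mb,
        seed=cfg.seed,
    )
    bins = simulate.simulate_bin_counts(truth, sim_cfg)
    snps = simulate.simulate_allele_counts(truth, sim_cfg)
    io.write_truth(truth, out / "truth.tsv")
    io.write_bins(bins, out / "bins.tsv")
    io.write_snps(snps, out / "snps.tsv")

    thresholds = infer.Thresholds(quiet_aberrant_fraction=cfg.abstain_aberrant_frac)
    call = call_sample(
        bins,
        snps,
        penalty=cfg.penalty,
        min_snps=cfg.min_snps,
        min_total_depth=cfg.min_total_depth,
        max_copies=cfg.max_copies,
        wgd_margin=cfg.wgd_margin,
        thresholds=thresholds,
    )
    io.write_seg(call.segments, out / "segments.tsv", sample=cfg.sample)
    io.write_purity_call(call, out / "purity_call.tsv", sample=cfg.sample)
    log.info(
        "call: purity=%s ploidy=%s abstained=%s reason=%s",
        call.purity, call.ploidy, call.abstained, call.abstain_reason,
    )

    summary = {
        "truth_purity": truth.purity,
        "truth_ploidy": truth.tumor_ploidy,
        "call": call,
        "artifacts": [str(out / n) for n in ("truth.tsv", "bins.tsv", "snps.tsv", "segments.tsv", "purity_call.tsv")],
    }

    if cfg.purity_matrix:
        matrix = io.read_purity_matrix(cfg.purity_matrix)
        amap = io.read_analyte_map(cfg.analyte_map) if cfg.analyte_map else None
        table = cons.consensus_table(matrix, amap)
        table.to_csv(out / "consensus.tsv", sep="\t", na_rep=io.NA, float_format="%.6g")
        summary["artifacts"].append(str(out / "consensus.tsv"))
    return summary
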