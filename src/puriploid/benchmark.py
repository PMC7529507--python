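"""Canonical simulation conditions for benchmarking the purity caller.

The recovery benchmark spans a purity x ploidy grid.  Ploidy is steered by
the event catalogue: deletion-heavy genomes settle near 1.8, drift-balanced
catalogues near 2.0, and genome-doubled catalogues near 3.6-4.3.  Draws are
conditioned on carrying at least ``min_aberrant`` aberrant segments (a
quiet genome is unidentifiable by construction), and genome-doubled draws
additionally on at least one odd-total segment and one nB=0 segment --
without an allele-floor state a doubled profile is analytically equivalent
to a lower-ploidy one and no estimator could recover it.

All functions are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from . import pipeline, simulate
from .simulate import DEFAULT_EVENT_WEIGHTS, WGD_EVENT_WEIGHTS, SimConfig

__all__ = ["PLOIDY_CELLS", "PURITY_LEVELS", "draw_tumor", "call_simulated_tumor", "recovery_cell"]

#: event catalogue, WGD flag and event rate per target-ploidy label
PLOIDY_CELLS = {
    "1.8": ({(1, 0): 0.6, (2, 0): 0.4}, False, 1.5),
    "2.0": ({(1, 0): 0.35, (2, 0): 0.3, (2, 1): 0.35}, False, 3.0),
    "3.6": (WGD_EVENT_WEIGHTS, True, 2.2),
}
PURITY_LEVELS = (0.2, 0.4, 0.6, 0.8)
N_CHROMS = 8


def draw_tumor(
    purity: float,
    cell: str = "2.0",
    seed: int = 0,
    min_aberrant: int = 5,
    event_rate: float | None = None,
):
    """Draw a truth profile satisfying the cell's identifiability conditions."""
    weights, wgd, rate = PLOIDY_CELLS[cell]
    if event_rate is not None:
        rate = event_rate
    for attempt in range(8):
        truth = simulate.simulate_truth_profile(
            N_CHROMS, purity, rate, wgd=wgd,
            seed=(seed + 1009 * attempt) & 0x7FFFFFFF,
            event_weights=weights,
        )
        n_aberrant = sum(1 for s in truth.segments if (s.nA, s.nB) != truth.base_state)
        anchored = (not wgd) or (
            any((s.nA + s.nB) % 2 == 1 for s in truth.segments)
            and any(s.nB == 0 for s in truth.segments)
        )
        if n_aberrant >= min_aberrant and anchored:
            return truth
    return truth


def call_simulated_tumor(truth, seed: int, coverage: float = 0.5, bin_size: int = 100_000):
    """Simulate reads for a truth profile and run the full caller."""
    cfg = SimConfig(mean_coverage=coverage, bin_size=bin_size, seed=seed & 0x7FFFFFFF)
    bins = simulate.simulate_bin_counts(truth, cfg)
    snps = simulate.simulate_allele_counts(truth, cfg)
    return pipeline.call_sample(bins, snps)


def recovery_cell(
    purity: float,
    cell: str,
    n_replicates: int = 20,
    seed: int = 0,
    coverage: float = 0.5,
) -> dict:
    """Median absolute purity/ploidy error over replicates of one cell."""
    errs_rho, errs_psi, n_abstained = [], [], 0
    for r in range(n_replicates):
        rep_seed = (seed + 7919 * r) & 0x7FFFFFFF
        truth = draw_tumor(purity, cell, seed=rep_seed)
        call = call_simulated_tumor(truth, seed=rep_seed, coverage=coverage)
        if call.abstained:
            n_abstained += 1
            errs_rho.append(np.nan)
            errs_psi.append(np.nan)
            continue
        errs_rho.append(abs(call.purity - truth.purity))
        errs_psi.append(abs(call.ploidy - truth.tumor_ploidy))
    return {
        "purity": purity,
        "cell": cell,
        "median_abs_purity_error": float(np.nanmedian(errs_rho)),
        "median_abs_ploidy_error": float(np.nanmedian(errs_psi)),
        "n_abstained": n_abstained,
        "n_replicates": n_replicates,
    }
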