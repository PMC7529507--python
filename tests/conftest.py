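import numpy as np
import pandas as pd
import pytest

from puriploid import preprocess, simulate


@pytest.fixture(scope="session")
def small_tumor():
    """A modest aberrant tumor at purity 0.6, 0.5x coverage, with truth."""
    truth = simulate.simulate_truth_profile(
        4, 0.6, 3.0, seed=11,
        event_weights={(1, 0): 0.35, (2, 0): 0.3, (2, 1): 0.35},
    )
    cfg = simulate.SimConfig(seed=11)
    bins = simulate.simulate_bin_counts(truth, cfg)
    snps = simulate.simulate_allele_counts(truth, cfg)
    return truth, cfg, bins, snps


@pytest.fixture(scope="session")
def small_segments(small_tumor):
    truth, cfg, bins, snps = small_tumor
    curve = preprocess.fit_gc_correction(bins)
    corrected = preprocess.apply_gc_correction(bins, curve)
    seg = preprocess.segment_logr(corrected)
    seg = preprocess.refine_segments_baf(seg, corrected, snps)
    return preprocess.aggregate_segment_baf(seg, snps)


def noiseless_profile(truth, purity, scale_ploidy, n_bins_per_seg=200):
    """Exact expected (logR, BAF) segment profile for a truth genome."""
    from puriploid import infer

    rows = []
    for s in truth.segments:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_bins": max(1, s.length // 300_000),
                "mean_logr": infer.expected_logr(s.nA + s.nB, purity, scale_ploidy),
                "logr_se": 0.005,
                "mirrored_baf": infer.expected_baf(s.nA, s.nB, purity),
                "baf_se": 0.01,
                "baf_se_lo": 0.01,
                "baf_se_hi": 0.01,
                "n_snps": 1000,
            }
        )
    return pd.DataFrame(rows)
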