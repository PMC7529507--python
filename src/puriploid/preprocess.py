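"""Depth normalization and segmentation for low-pass tumor--normal profiles.

The pipeline is: fit a GC-bias curve from binned counts, correct counts and
form a median-centered log2 tumor/normal ratio (logR), cut each chromosome
into piecewise-constant segments, then pool heterozygous-SNP allele counts
per segment into a mirrored B-allele fraction (BAF).

GC bias is assumed shared between the paired tumor and normal libraries
(same protocol), so one multiplicative curve, fitted on the combined
counts, corrects both.  At 0.5x coverage per-SNP allele fractions are far
too sparse to segment on, so changepoints come from logR only and the
allelic signal is used downstream at fit time.

The mirrored-BAF estimator is a maximum-likelihood fit of a two-sided
binomial mixture: each SNP's alt count is Binomial(depth, b) or
Binomial(depth, 1-b) with equal weight, reflecting the random phase of the
alt allele.  Depth-1 SNPs carry no information about b (the mixture
likelihood is constant), so only SNPs with depth >= 2 contribute; naive
folding of per-SNP fractions would instead be biased upward near 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "GCCurve",
    "fit_gc_correction",
    "apply_gc_correction",
    "segment_logr",
    "refine_segments_baf",
    "aggregate_segment_baf",
    "mirrored_baf_mle",
    "DEFAULT_MIN_SNPS",
    "DEFAULT_MIN_TOTAL_DEPTH",
]

DEFAULT_MIN_SNPS = 10
DEFAULT_MIN_TOTAL_DEPTH = 50
MIN_GC_BINS = 100


@dataclass
class GCCurve:
    """Multiplicative GC-bias correction curve, evaluated by interpolation."""

    gc: np.ndarray
    factor: np.ndarray
    flat: bool = False

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        if self.flat:
            return np.ones_like(np.asarray(gc, dtype=float))
        return np.interp(np.asarray(gc, dtype=float), self.gc, self.factor)


def fit_gc_correction(bins: pd.DataFrame, frac: float = 0.3) -> GCCurve:
    """Fit a LOESS curve of read count against GC fraction.

    The curve is fitted on combined tumor+normal counts (bias shared by the
    pair) and median-normalized so that the returned multiplicative factor
    is ~1 for a typical bin.  Requires at least 100 usable bins; identical
    GC across all bins degrades to a flat curve with a warning.
    """
    usable = bins[(bins["tumor_count"] + bins["normal_count"]) >= 0].copy()
    if len(usable) < MIN_GC_BINS:
        raise ValueError(f"need >= {MIN_GC_BINS} bins to fit a GC curve, got {len(usable)}")
    gc = usable["gc"].to_numpy(dtype=float)
    total = (usable["tumor_count"] + usable["normal_count"]).to_numpy(dtype=float)
    if np.ptp(gc) < 1e-6:
        warnings.warn("GC fraction is constant across bins; returning a flat correction curve")
        return GCCurve(gc=np.array([0.0, 1.0]), factor=np.ones(2), flat=True)
    fitted = lowess(total, gc, frac=frac, it=2, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, order = np.unique(xs, return_index=True)
    ys = ys[order]
    med = np.median(ys)
    if med <= 0:
        raise ValueError("GC curve fit degenerate: non-positive median fitted count")
    factor = np.clip(ys / med, 0.05, None)
    return GCCurve(gc=xs, factor=factor)


def apply_gc_correction(bins: pd.DataFrame, curve: GCCurve) -> pd.DataFrame:
    """Divide counts by the GC factor and compute median-centered logR.

    ``corrected_logr = log2((tumor/factor) / (normal/factor) / median ratio)``,
    defined only for bins with positive counts in both samples; the genome
    median of the corrected logR is zero by construction.
    """
    out = bins.copy()
    factor = curve(out["gc"].to_numpy())
    if np.any(factor <= 0):
        raise ValueError("GC correction factor must be positive")
    out["corrected_tumor"] = out["tumor_count"] / factor
    out["corrected_normal"] = out["normal_count"] / factor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["corrected_tumor"].to_numpy() / out["corrected_normal"].to_numpy()
    ratio[~np.isfinite(ratio) | (ratio <= 0)] = np.nan
    logr = np.log2(ratio)
    logr -= np.nanmedian(logr)
    out["corrected_logr"] = logr
    return out


def _best_split(csum: np.ndarray, csum2: np.ndarray, i: int, j: int, min_size: int):
    """Best single changepoint of x[i:j] by least-squares cost reduction."""
    n = j - i
    if n < 2 * min_size:
        return None, 0.0
    ks = np.arange(i + min_size, j - min_size + 1)
    s_all = csum[j] - csum[i]
    s2_all = csum2[j] - csum2[i]
    cost_all = s2_all - s_all**2 / n
    s_left = csum[ks] - csum[i]
    s2_left = csum2[ks] - csum2[i]
    nl = ks - i
    cost_left = s2_left - s_left**2 / nl
    s_right = s_all - s_left
    s2_right = s2_all - s2_left
    nr = j - ks
    cost_right = s2_right - s_right**2 / nr
    gains = cost_all - cost_left - cost_right
    b = int(np.argmax(gains))
    return int(ks[b]), float(gains[b])


def _binseg(x: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Recursive binary segmentation; returns sorted interior changepoints."""
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x**2)])
    bps: list[int] = []
    stack = [(0, len(x))]
    while stack:
        i, j = stack.pop()
        k, gain = _best_split(csum, csum2, i, j, min_size)
        if k is not None and gain > penalty:
            bps.append(k)
            stack.append((i, k))
            stack.append((k, j))
    return sorted(bps)


def _auto_penalty(x: np.ndarray) -> float:
    # noise variance from median absolute successive difference (robust to
    # level shifts), BIC-style multiplier
    if len(x) < 3:
        return 1.0
    sigma = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2.0)
    sigma = max(sigma, 1e-6)
    return 3.0 * sigma**2 * np.log(len(x))


def segment_logr(
    bins: pd.DataFrame, penalty: float | None = None, min_size: int = 5
) -> pd.DataFrame:
    """Cut corrected logR into piecewise-constant segments per chromosome.

    ``penalty`` is the minimum least-squares cost reduction required to
    accept a changepoint; ``None`` selects a BIC-style value from the
    chromosome's own noise level.  Segments never span chromosomes.  Bins
    with undefined logR are carried by their neighboring segment so the
    output tiles the binned genome.
    """
    if penalty is not None and penalty <= 0:
        raise ValueError("penalty must be positive")
    if "corrected_logr" not in bins.columns:
        raise ValueError("bins must be GC-corrected first (missing corrected_logr)")
    rows = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        finite = grp["corrected_logr"].notna().to_numpy()
        if not finite.any():
            continue
        kept = grp[finite].reset_index(drop=True)
        x = kept["corrected_logr"].to_numpy(dtype=float)
        pen = _auto_penalty(x) if penalty is None else penalty
        bps = _binseg(x, pen, min_size)
        bounds = [0] + bps + [len(x)]
        chrom_end = int(grp["end"].iloc[-1])
        for a, b in zip(bounds, bounds[1:]):
            start = int(kept["start"].iloc[a])
            end = int(kept["start"].iloc[b]) if b < len(x) else chrom_end
            if a == 0:
                start = int(grp["start"].iloc[0])
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_bins": b - a,
                    "mean_logr": float(np.mean(x[a:b])),
                    "logr_se": float(np.std(x[a:b], ddof=1) / np.sqrt(b - a)) if b - a > 1 else np.nan,
                }
            )
    if not rows:
        raise ValueError("no usable bins on any chromosome")
    seg = pd.DataFrame(rows)
    # fill per-segment SE where undefined with the genome-wide bin SD
    genome_sd = float(
        np.nanmedian(seg["logr_se"] * np.sqrt(seg["n_bins"].clip(lower=1)))
    )
    if not np.isfinite(genome_sd):
        genome_sd = 0.1
    fallback = genome_sd / np.sqrt(seg["n_bins"].clip(lower=1))
    seg["logr_se"] = seg["logr_se"].fillna(fallback).clip(lower=1e-4)
    return seg


#: systematic BAF dispersion floor: absorbs unmodelled within-segment
#: heterogeneity (e.g. copy-neutral LOH boundaries invisible to logR-only
#: segmentation contaminating a segment with balanced SNPs)
BAF_SE_FLOOR = 0.015
#: allelic split-gain thresholds in units of var(z) * log(n): the null
#: maximum gain sits near 2.1 (99th percentile, simulated at low depth)
SPLIT_GAIN_MULT = 2.5
HET_GUARD_MULT = 1.6


def refine_segments_baf(
    segments: pd.DataFrame,
    bins: pd.DataFrame,
    snps: pd.DataFrame,
    min_size_snps: int = 40,
    min_size_bins: int = 3,
) -> pd.DataFrame:
    """Split logR segments at allelic (BAF) changepoints.

    Copy states with equal total copy number but different allelic balance
    (e.g. diploid (1,1) vs copy-neutral LOH (2,0)) are invisible in logR,
    so a logR-only segmentation merges them and the pooled segment BAF fits
    neither state.  This pass runs binary segmentation on the per-SNP
    folded deviation ``|alt/depth - 1/2|`` of informative (depth >= 2) SNPs
    within each segment and re-tiles, recomputing logR statistics per piece
    from the corrected bins.  ``min_size_snps`` controls the smallest
    allelic segment; boundaries with fewer than ``min_size_bins`` bins on a
    side are dropped.
    """
    depth = snps["ref_count"] + snps["alt_count"]
    informative = snps[depth >= 2].copy()
    informative["z"] = (
        informative["alt_count"] / (informative["ref_count"] + informative["alt_count"]) - 0.5
    ).abs()
    rows = []
    for _, seg in segments.iterrows():
        chrom, start, end = seg["chrom"], int(seg["start"]), int(seg["end"])
        chrom_bins = bins[(bins["chrom"] == chrom)]
        seg_bins = chrom_bins[
            (chrom_bins["start"] >= start) & (chrom_bins["start"] < end)
        ]
        kept = seg_bins[seg_bins["corrected_logr"].notna()]
        sub = informative[
            (informative["chrom"] == chrom)
            & (informative["pos"] - 1 >= start)
            & (informative["pos"] - 1 < end)
        ].sort_values("pos")
        cuts: list[int] = []
        if len(sub) >= 2 * min_size_snps:
            z = sub["z"].to_numpy(dtype=float)
            # split only at decisive allelic boundaries: the null max gain
            # of binary segmentation on folded deviations is ~2.1 var log n
            # (99th pct, simulated); 2.5 keeps false splits rare
            pen = SPLIT_GAIN_MULT * np.var(z) * np.log(len(z))
            bps = _binseg(z, pen, min_size_snps)
            cuts = [int(sub["pos"].iloc[b] - 1) for b in bps]
        bounds = [start] + cuts + [end]
        # drop cuts leaving fewer than min_size_bins bins on a side
        cleaned = [start]
        for b in bounds[1:-1]:
            n_left = int(((kept["start"] >= cleaned[-1]) & (kept["start"] < b)).sum())
            if n_left >= min_size_bins:
                cleaned.append(b)
        cleaned.append(end)
        for a, b in zip(cleaned, cleaned[1:]):
            piece = kept[(kept["start"] >= a) & (kept["start"] < b)]
            x = piece["corrected_logr"].to_numpy(dtype=float)
            if len(x) == 0:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": a,
                    "end": b,
                    "n_bins": len(x),
                    "mean_logr": float(np.mean(x)),
                    "logr_se": float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    genome_sd = float(np.nanmedian(out["logr_se"] * np.sqrt(out["n_bins"].clip(lower=1))))
    if not np.isfinite(genome_sd):
        genome_sd = 0.1
    fallback = genome_sd / np.sqrt(out["n_bins"].clip(lower=1))
    out["logr_se"] = out["logr_se"].fillna(fallback).clip(lower=1e-4)
    return out


#: shared evaluation grid for the folded-BAF profile likelihood
BAF_GRID = np.linspace(0.5, 0.999, 250)


def baf_profile_loglik(
    ref: np.ndarray, alt: np.ndarray, grid: np.ndarray | None = None
) -> np.ndarray | None:
    """Profile log-likelihood of the mirrored allele fraction on ``grid``.

    Two-sided binomial mixture with equal weights (random phase of the alt
    allele); only SNPs with depth >= 2 contribute (depth-1 SNPs have a
    constant mixture likelihood).  Returns None when no SNP is informative.
    """
    ref = np.asarray(ref, dtype=int)
    alt = np.asarray(alt, dtype=int)
    depth = ref + alt
    keep = depth >= 2
    if not keep.any():
        return None
    d, k = depth[keep], alt[keep]
    pairs, counts = np.unique(np.stack([d, k], axis=1), axis=0, return_counts=True)
    dd, kk = pairs[:, 0], pairs[:, 1]
    if grid is None:
        grid = BAF_GRID
    logpmf_b = binom.logpmf(kk[None, :], dd[None, :], grid[:, None])
    logpmf_1mb = binom.logpmf(kk[None, :], dd[None, :], 1.0 - grid[:, None])
    mx = np.maximum(logpmf_b, logpmf_1mb)
    mix = mx + np.log(0.5 * np.exp(logpmf_b - mx) + 0.5 * np.exp(logpmf_1mb - mx))
    return mix @ counts


def mirrored_baf_mle(
    ref: np.ndarray, alt: np.ndarray, grid: np.ndarray | None = None
) -> tuple[float, float, float, int]:
    """Two-sided binomial-mixture MLE of the mirrored allele fraction.

    Returns ``(b_hat, se_lo, se_hi, informative_depth)`` with ``b_hat`` in
    [0.5, 1].  Only SNPs with depth >= 2 are informative.  The two standard
    errors are the per-side widths of the 1-sigma profile-likelihood
    interval: the folded likelihood is flat toward 0.5 (zero Fisher
    information at the fold), so the lower-side error is typically much
    wider than the upper-side one for near-balanced segments; a symmetric
    SE would overstate the evidence against allelic balance.
    """
    if grid is None:
        grid = BAF_GRID
    loglik = baf_profile_loglik(ref, alt, grid)
    if loglik is None:
        return np.nan, np.nan, np.nan, 0
    depth = np.asarray(ref, dtype=int) + np.asarray(alt, dtype=int)
    d = depth[depth >= 2]
    i = int(np.argmax(loglik))
    b_hat = float(grid[i])
    inside = grid[loglik >= loglik[i] - 0.5]  # 1-sigma profile interval
    se_lo = float(b_hat - inside.min()) if len(inside) > 1 else 0.01
    se_hi = float(inside.max() - b_hat) if len(inside) > 1 else 0.01
    se_lo = float(np.hypot(max(se_lo, 0.005), BAF_SE_FLOOR))
    se_hi = float(np.hypot(max(se_hi, 0.005), BAF_SE_FLOOR))
    info_depth = int(d.sum())
    return b_hat, se_lo, se_hi, info_depth


def _looks_heterogeneous(ref: np.ndarray, alt: np.ndarray, min_side: int = 20) -> bool:
    """Positional changepoint test on folded allele fractions.

    True when the best single split of the informative SNPs' folded
    deviations gains more than ``HET_GUARD_MULT * var(z) * log(n)``,
    i.e. the segment very likely mixes two allelic states.
    """
    depth = np.asarray(ref) + np.asarray(alt)
    keep = depth >= 2
    if keep.sum() < 2 * min_side:
        return False
    z = np.abs(np.asarray(alt)[keep] / depth[keep] - 0.5)
    var = float(np.var(z))
    if var < 1e-12:
        return False
    csum = np.concatenate([[0.0], np.cumsum(z)])
    csum2 = np.concatenate([[0.0], np.cumsum(z**2)])
    _, gain = _best_split(csum, csum2, 0, len(z), min_side)
    return gain > HET_GUARD_MULT * var * np.log(len(z))


def aggregate_segment_baf(
    segments: pd.DataFrame,
    snps: pd.DataFrame,
    min_snps: int = DEFAULT_MIN_SNPS,
    min_total_depth: int = DEFAULT_MIN_TOTAL_DEPTH,
    het_guard: bool = True,
) -> pd.DataFrame:
    """Attach a pooled mirrored BAF to each segment.

    SNPs are assigned to segments by coordinate overlap.  A segment's BAF is
    missing (NaN) when it covers fewer than ``min_snps`` SNPs, their pooled
    depth is below ``min_total_depth``, or (with ``het_guard``) the
    segment's folded allele fractions look allelically heterogeneous --
    e.g. a copy-neutral LOH block sharing the segment with balanced
    sequence, invisible to logR.  A pooled estimate over such a mixture
    would be confidently wrong, so the segment keeps depth information only.
    """
    out = segments.copy().reset_index(drop=True)
    out["mirrored_baf"] = np.nan
    out["baf_se"] = np.nan
    out["baf_se_lo"] = np.nan
    out["baf_se_hi"] = np.nan
    out["n_snps"] = 0
    # in-memory only: folded-BAF profile log-likelihood per segment, used by
    # the fitter as an exact deviance term; dropped by the SEG writer
    out["_baf_loglik"] = None
    out["_baf_loglik"] = out["_baf_loglik"].astype(object)
    if len(snps) == 0:
        return out
    for chrom, seg_grp in out.groupby("chrom", sort=False):
        chrom_snps = snps[snps["chrom"] == chrom]
        if len(chrom_snps) == 0:
            continue
        pos0 = chrom_snps["pos"].to_numpy() - 1  # to 0-based
        starts = seg_grp["start"].to_numpy()
        ends = seg_grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos0, side="right") - 1
        valid = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        for local_i, seg_i in enumerate(seg_grp.index):
            sel = valid & (idx == local_i)
            if not sel.any():
                continue
            ref = chrom_snps["ref_count"].to_numpy()[sel]
            alt = chrom_snps["alt_count"].to_numpy()[sel]
            n = int(sel.sum())
            pooled_depth = int(ref.sum() + alt.sum())
            out.loc[seg_i, "n_snps"] = n
            if n < min_snps or pooled_depth < min_total_depth:
                continue
            if het_guard and _looks_heterogeneous(ref, alt):
                continue
            b, se_lo, se_hi, info = mirrored_baf_mle(ref, alt)
            if np.isfinite(b):
                out.loc[seg_i, "mirrored_baf"] = b
                out.loc[seg_i, "baf_se"] = (se_lo + se_hi) / 2.0
                out.loc[seg_i, "baf_se_lo"] = se_lo
                out.loc[seg_i, "baf_se_hi"] = se_hi
                out.at[seg_i, "_baf_loglik"] = baf_profile_loglik(ref, alt)
    return out
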