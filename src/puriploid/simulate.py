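"""Synthetic tumor--normal admixture profiles with known truth.

A bulk tumor specimen is modelled as a mixture of normal diploid cells and
tumor cells at purity ``rho``.  The tumor genome is piecewise constant in
allele-specific copy number: each segment carries an integer major/minor
state ``(nA, nB)`` and, optionally, a single subclone so that only a clonal
fraction ``f`` of tumor cells carry the altered state while the remainder
keep the baseline (diploid, or tetraploid after a whole-genome duplication).

Read-depth is emulated at the level of fixed-width genomic bins: the
expected tumor count in a bin is proportional to a multiplicative GC bias
times the mixture copy number ``2(1-rho) + rho*n_eff``, scaled so that the
genome-wide mean count matches the configured coverage.  Heterozygous-SNP
allele counts are binomial draws whose success probability follows the same
admixture, with the alternate allele landing on the major or minor
haplotype at random per SNP.

Everything is deterministic under a fixed seed; independent substreams are
derived for segments, bins and SNPs so the outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "TruthProfile",
    "SimConfig",
    "simulate_truth_profile",
    "simulate_bin_counts",
    "simulate_allele_counts",
    "DEFAULT_EVENT_WEIGHTS",
    "WGD_EVENT_WEIGHTS",
]

DEFAULT_CHROM_LENGTH = 60_000_000
#: copy-state catalogue for events on a diploid baseline: state -> weight
DEFAULT_EVENT_WEIGHTS = {
    (1, 0): 0.25,  # hemizygous deletion
    (2, 0): 0.15,  # copy-neutral LOH
    (2, 1): 0.35,  # single-copy gain
    (3, 1): 0.15,  # unbalanced double gain
    (3, 2): 0.10,  # balanced-ish gain
}
#: events on a genome-doubled (2,2) baseline.  States with nB = 0 (deep
#: loss, post-WGD copy-neutral LOH) are the observable anchors of genome
#: doubling: without them a doubled profile is analytically equivalent to a
#: lower-ploidy one.  Both are common in genome-doubled tumors.
WGD_EVENT_WEIGHTS = {
    (2, 1): 0.25,  # post-WGD single-copy loss
    (2, 0): 0.10,  # deep biallelic loss
    (4, 0): 0.10,  # post-WGD copy-neutral LOH
    (3, 1): 0.10,
    (3, 2): 0.20,  # post-WGD gain
    (4, 2): 0.15,
    (5, 2): 0.10,
}


@dataclass(frozen=True)
class Segment:
    """One constant-copy-state genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    nA: int
    nB: int
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if not (self.nA >= self.nB >= 0):
            raise ValueError(f"require nA >= nB >= 0, got ({self.nA},{self.nB})")
        if not (0.0 < self.clonal_fraction <= 1.0):
            raise ValueError("clonal_fraction must be in (0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total(self) -> int:
        return self.nA + self.nB


@dataclass
class TruthProfile:
    """Ground-truth tumor genome: segments, purity, and derived ploidy."""

    segments: list[Segment]
    purity: float
    wgd_applied: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        self._check_tiling()

    def _check_tiling(self) -> None:
        for chrom, segs in self.by_chrom().items():
            for a, b in zip(segs, segs[1:]):
                if b.start != a.end:
                    raise ValueError(f"segments do not tile {chrom}: gap/overlap at {a.end}/{b.start}")

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        for segs in out.values():
            segs.sort(key=lambda s: s.start)
        return out

    @property
    def tumor_ploidy(self) -> float:
        """Length-weighted mean total copy number of the tumor cells."""
        lengths = np.array([s.length for s in self.segments], dtype=float)
        totals = np.array([s.total for s in self.segments], dtype=float)
        return float(np.sum(lengths * totals) / np.sum(lengths))

    @property
    def base_state(self) -> tuple[int, int]:
        return (2, 2) if self.wgd_applied else (1, 1)

    def effective_total(self, seg: Segment) -> float:
        """Tumor-cell mean total copies, mixing subclone with the baseline."""
        f = seg.clonal_fraction
        base = sum(self.base_state)
        return f * seg.total + (1.0 - f) * base


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-emulation parameters.

    ``mean_coverage`` is reads-per-base; with ``read_length`` it sets the
    expected read count per bin to ``mean_coverage * bin_size / read_length``.
    ``gc_bias_coefficients`` are polynomial coefficients c0, c1, c2, ... of the
    multiplicative bias ``sum_k c_k (gc - 0.45)^k`` (clipped to stay positive).
    ``noise_overdispersion`` > 0 switches Poisson counts to gamma-Poisson
    (negative binomial) with variance ``mu * (1 + phi * mu)``.
    """

    mean_coverage: float = 0.5
    bin_size: int = 100_000
    read_length: int = 100
    n_het_snps_per_mb: float = 150.0
    gc_bias_coefficients: tuple[float, ...] = (1.0, 0.6, -1.5)
    noise_overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage < 0.1:
            raise ValueError("mean_coverage must be >= 0.1x")
        if self.bin_size < 1000:
            raise ValueError("bin_size must be >= 1000 bp")
        if self.n_het_snps_per_mb <= 0 or self.read_length <= 0:
            raise ValueError("densities must be positive")
        if self.noise_overdispersion < 0:
            raise ValueError("noise_overdispersion must be >= 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream]))


def simulate_truth_profile(
    n_chroms: int,
    purity: float,
    event_rate: float,
    wgd: bool = False,
    subclone_fraction: float | None = None,
    seed: int = 0,
    *,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    event_weights: dict[tuple[int, int], float] | None = None,
    min_event_length: int = 5_000_000,
    max_event_length: int = 30_000_000,
    subclone_f_range: tuple[float, float] = (0.3, 0.8),
) -> TruthProfile:
    """Draw a segment-level tumor genome with known purity and ploidy.

    Each chromosome receives ``Poisson(event_rate)`` copy-number events with
    uniformly placed breakpoints (rounded to a 100 kb lattice); later events
    overwrite earlier ones where they overlap.  The baseline state is (1,1),
    or (2,2) when ``wgd`` is set.  If ``subclone_fraction`` is given, that
    fraction of altered segments is marked subclonal with a clonal fraction
    drawn uniformly from ``subclone_f_range``.
    """
    if not (0.0 <= purity <= 1.0):
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")

    rng = _rng(seed, 0)
    base = (2, 2) if wgd else (1, 1)
    weights = event_weights if event_weights is not None else (
        WGD_EVENT_WEIGHTS if wgd else DEFAULT_EVENT_WEIGHTS
    )
    states = list(weights)
    probs = np.array([weights[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    lattice = 100_000

    segments: list[Segment] = []
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        n_events = rng.poisson(event_rate)
        # per-position state, run-length encoded over atomic intervals
        cuts = {0, chrom_length}
        events = []
        for _ in range(n_events):
            length = int(rng.uniform(min_event_length, max_event_length))
            length = max(lattice, (length // lattice) * lattice)
            length = min(length, chrom_length)
            start = int(rng.uniform(0, chrom_length - length))
            start = (start // lattice) * lattice
            state = states[rng.choice(len(states), p=probs)]
            events.append((start, start + length, state))
            cuts.add(start)
            cuts.add(start + length)
        bounds = sorted(cuts)
        for a, b in zip(bounds, bounds[1:]):
            state = base
            for s, e, st in events:  # later events overwrite earlier
                if s <= a and b <= e:
                    state = st
            segments.append(Segment(chrom, a, b, state[0], state[1]))

    # merge adjacent equal-state segments for a minimal tiling
    merged: list[Segment] = []
    for seg in segments:
        if merged and merged[-1].chrom == seg.chrom and (
            (merged[-1].nA, merged[-1].nB) == (seg.nA, seg.nB)
        ):
            prev = merged.pop()
            merged.append(Segment(seg.chrom, prev.start, seg.end, seg.nA, seg.nB))
        else:
            merged.append(seg)

    if subclone_fraction is not None:
        if not (0.0 <= subclone_fraction <= 1.0):
            raise ValueError("subclone_fraction must be in [0, 1]")
        altered = [i for i, s in enumerate(merged) if (s.nA, s.nB) != base]
        n_sub = int(round(subclone_fraction * len(altered)))
        if n_sub > 0:
            chosen = rng.choice(len(altered), size=n_sub, replace=False)
            for j in sorted(chosen):
                i = altered[j]
                f = float(rng.uniform(*subclone_f_range))
                merged[i] = dataclasses.replace(merged[i], clonal_fraction=f)

    return TruthProfile(segments=merged, purity=purity, wgd_applied=wgd)


def _gc_bias(gc: np.ndarray, coefficients: tuple[float, ...]) -> np.ndarray:
    x = gc - 0.45
    bias = np.zeros_like(gc, dtype=float)
    for k, c in enumerate(coefficients):
        bias += c * x**k
    return np.clip(bias, 0.05, None)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.clip(mu, 1e-12, None)
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        return rng.poisson(lam)
    return rng.poisson(mu)


def _bin_table(truth: TruthProfile, cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, segs in truth.by_chrom().items():
        length = segs[-1].end
        starts = np.arange(0, length, cfg.bin_size)
        ends = np.minimum(starts + cfg.bin_size, length)
        seg_starts = np.array([s.start for s in segs])
        idx = np.searchsorted(seg_starts, starts, side="right") - 1
        n_eff = np.array([truth.effective_total(segs[i]) for i in idx])
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "n_eff": n_eff}))
    return pd.concat(rows, ignore_index=True)


def simulate_bin_counts(truth: TruthProfile, cfg: SimConfig) -> pd.DataFrame:
    """Draw per-bin tumor and normal read counts.

    Returns a BED-like frame: chrom, start, end, gc, tumor_count,
    normal_count.  Tumor means are proportional to
    ``gc_bias(gc) * (2(1-rho) + rho*n_eff)`` and normal means to
    ``gc_bias(gc) * 2``, each rescaled so the genome-wide mean count equals
    ``mean_coverage * bin_size / read_length`` (both samples sequenced to the
    same target depth).
    """
    if not truth.segments:
        raise ValueError("truth profile has no segments")
    bins = _bin_table(truth, cfg)
    rng = _rng(cfg.seed, 1)
    gc = np.clip(rng.normal(0.45, 0.06, size=len(bins)), 0.30, 0.65)
    bias = _gc_bias(gc, cfg.gc_bias_coefficients)

    rho = truth.purity
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    target = cfg.mean_coverage * cfg.bin_size / cfg.read_length
    size_frac = widths / cfg.bin_size

    mix = 2.0 * (1.0 - rho) + rho * bins["n_eff"].to_numpy()
    mu_t = bias * mix
    mu_t *= target / np.average(mu_t, weights=widths) if mu_t.mean() > 0 else 1.0
    mu_n = bias * 2.0
    mu_n *= target / np.average(mu_n, weights=widths)

    tumor = _draw_counts(rng, mu_t * size_frac, cfg.noise_overdispersion)
    normal = _draw_counts(rng, mu_n * size_frac, cfg.noise_overdispersion)
    out = bins[["chrom", "start", "end"]].copy()
    out["gc"] = np.round(gc, 4)
    out["tumor_count"] = tumor
    out["normal_count"] = normal
    return out


def simulate_allele_counts(truth: TruthProfile, cfg: SimConfig) -> pd.DataFrame:
    """Draw heterozygous-SNP ref/alt counts in the tumor sample.

    Per SNP the sequencing depth is Poisson with per-base mean
    ``mean_coverage`` scaled by the local copy-state mixture, and the alt
    count is binomial with success probability following the admixture of
    normal and tumor haplotypes; the alt allele is assigned to the major or
    minor tumor haplotype with probability 1/2 independently per SNP.
    Returns a frame: chrom, pos (1-based), ref_count, alt_count.
    """
    if not truth.segments:
        raise ValueError("truth profile has no segments")
    rng = _rng(cfg.seed, 2)
    rho = truth.purity
    base_hap = truth.base_state[0] / 1  # per-haplotype baseline copies (1 or 2)
    base_tot = sum(truth.base_state)

    # genome-wide mean mixture, for depth normalization consistent with bins
    lengths = np.array([s.length for s in truth.segments], dtype=float)
    mixes = 2.0 * (1.0 - rho) + rho * np.array([truth.effective_total(s) for s in truth.segments])
    mean_mix = float(np.average(mixes, weights=lengths))

    frames = []
    for seg, mix in zip(truth.segments, mixes):
        n_snps = rng.poisson(cfg.n_het_snps_per_mb * seg.length / 1e6)
        if n_snps == 0:
            continue
        # sample with replacement and dedupe: collisions are negligible at
        # realistic SNP densities and this stays O(n_snps) on long segments
        pos = np.unique(rng.integers(0, seg.length, size=n_snps)) + seg.start
        n_snps = len(pos)
        depth_mean = cfg.mean_coverage * mix / mean_mix if mean_mix > 0 else cfg.mean_coverage
        depth = rng.poisson(depth_mean, size=n_snps)
        f = seg.clonal_fraction
        denom = (1.0 - rho) * 2.0 + rho * (f * seg.total + (1.0 - f) * base_tot)
        p = {}
        for hap, n_hap in (("A", seg.nA), ("B", seg.nB)):
            num = (1.0 - rho) * 1.0 + rho * (f * n_hap + (1.0 - f) * base_hap)
            p[hap] = num / denom if denom > 0 else 0.5
        on_major = rng.random(n_snps) < 0.5
        p_alt = np.where(on_major, p["A"], p["B"])
        alt = rng.binomial(depth, p_alt)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": seg.chrom,
                    "pos": pos + 1,  # 1-based on disk and in memory
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "ref_count", "alt_count"])
    return pd.concat(frames, ignore_index=True)
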