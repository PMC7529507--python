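"""Joint purity/ploidy/subclonality inference from a segment profile.

The forward model is the standard tumor--normal admixture: a segment with
total tumor copies ``n`` in a sample of purity ``rho`` has expected depth
ratio proportional to ``2(1-rho) + rho*n``, and a heterozygous SNP on a
segment with allele-specific state ``(nA, nB)`` has expected mirrored
B-allele fraction ``((1-rho) + rho*nA) / (2(1-rho) + rho*(nA+nB))``.  Since
the observed logR is median-centered, the model carries a scale parameter
``psi`` (the copy number at the centering point); the reported tumor ploidy
is always recomputed as the length-weighted mean of the assigned integer
states, so it does not depend on the centering convention.

Fitting is an exhaustive grid search over (rho, psi): for every grid point
each segment is assigned the integer state minimizing a length-weighted,
variance-scaled squared residual in (logR, mirrored BAF), and candidates
are ranked by the weighted mean residual.  The grid objective is an
explicit, swappable stand-in for a full likelihood; its seam is
``score_candidate``.

Two well-known pathologies are handled explicitly:

* *Whole-genome-duplication aliasing*: the profiles of ``(rho, psi, S)``
  and ``(rho/(2-rho), 2*psi, 2*S)`` are analytically identical, so a
  doubled solution is selected only when it beats every lower-ploidy
  candidate by more than a score margin (parsimony rule).
* *Quiet genomes*: with no somatic copy-number aberrations purity is
  unidentifiable; the fitter abstains rather than guess, mirroring the
  behavior of DNA-based purity callers on such samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CandidateSolution",
    "PurityCall",
    "Thresholds",
    "expected_logr",
    "expected_baf",
    "aliased_purity",
    "score_candidate",
    "fit_grid",
    "select_solution",
    "assess_confidence",
    "infer_subclonal_fraction",
    "call_segments",
    "PURITY_GRID",
    "PLOIDY_GRID",
    "DEFAULT_MAX_COPIES",
    "DEFAULT_WGD_MARGIN",
]

PURITY_GRID = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
PLOIDY_GRID = np.round(np.arange(1.2, 6.0 + 1e-9, 0.05), 2)
DEFAULT_MAX_COPIES = 8
#: relative score margin within which the lowest-ploidy candidate is
#: preferred among refined candidates
DEFAULT_WGD_MARGIN = 0.05
#: relative margin for the shift-alias descent: the admixture model has an
#: exact degeneracy (rho, psi, S) == (rho', psi+2, S+(1,1)), broken only by
#: allele-floor states (nB = 0); a candidate whose exact shifted-down image
#: scores within this margin is replaced by that image (parsimony), while
#: genuinely duplicated genomes are protected by floor blockers whose cost
#: far exceeds it
SHIFT_ALIAS_MARGIN = 0.35
#: logR dispersion floor on the coarse grid (absorbs the 0.05 psi-step
#: quantization) and after local refinement (residual GC wiggle only)
LOGR_SE_FLOOR = 0.02
LOGR_SE_FLOOR_FINE = 0.01
#: weight of the karyotype complexity prior: each copy step away from the
#: diploid state (1,1) adds this much to a segment's cost.  A mild
#: regularizer against noise-chasing exotic states; the WGD alias itself is
#: resolved by the irreducibility test in ``select_solution``.
DEFAULT_STATE_PRIOR_WEIGHT = 0.05
#: minimum fit-cost of the best exact-multiple state restriction for a
#: high-ploidy solution to be retained (see ``reducibility_gap``).  Exact
#: doubled images restrict at negligible cost (< ~1); genuine duplicated
#: genomes cost >~15 via their allele-floor anchors; a single subclonal
#: segment absorbed by the finer doubled lattice costs a few units and must
#: not block the descent
DEFAULT_IRREDUCIBILITY_THRESHOLD = 5.0
#: per-segment residual above which the unrestricted fit considers the
#: segment un-modelable as a clonal integer state (subclonal); such
#: segments are excluded from alias-evidence tests
SUBCLONAL_EVIDENCE_CUTOFF = 12.0
#: robust cap on a single segment's contribution to the fit score: a
#: segment at a subclonal (non-integer) copy number is a model violation,
#: not evidence against the whole solution, and must not drag the global
#: fit or trip the poor-fit abstention on its own.  Alias-evidence tests
#: (reducibility, shift descent blockers) run uncapped.
SEGMENT_RESIDUAL_CAP = 50.0
#: weight of the copy-space parsimony term relative to the chi-square
#: evidence terms
COPY_SPACE_WEIGHT = 3.0
#: quasi-likelihood dispersion of the segment-level allelic deviance:
#: pooled-BAF estimates scatter beyond their nominal binomial errors
#: (residual heterogeneity, folding), so deviances are tempered by this
#: factor before entering the objective
BAF_DISPERSION = 3.0
#: raw deviance against allelic balance above which a segment counts as a
#: confident allelic aberration in the quiet-genome statistic; the null
#: (boundary chi-square mixture) essentially never exceeds this
QUIET_ALLELIC_DEV = 12.0
NEG_INF_LOGR = -30.0  # sentinel for log2(0); far below any observable logR


def expected_logr(n_total, purity, tumor_ploidy):
    """Expected centered log2 depth ratio of a segment with ``n_total`` copies.

    ``log2((2(1-rho) + rho*n) / (2(1-rho) + rho*psi))``; at rho=0 this is 0
    for every state (no tumor signal).  A zero numerator (rho=1, n=0) maps
    to a large negative sentinel for the caller to handle.
    """
    n_total = np.asarray(n_total, dtype=float)
    rho = float(purity)
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"purity must be in [0, 1], got {rho}")
    if rho > 0 and tumor_ploidy <= 0:
        raise ValueError("tumor_ploidy must be positive when purity > 0")
    num = 2.0 * (1.0 - rho) + rho * n_total
    den = 2.0 * (1.0 - rho) + rho * float(tumor_ploidy)
    with np.errstate(divide="ignore"):
        out = np.where(num > 0, np.log2(np.maximum(num, 1e-300) / den), NEG_INF_LOGR)
    return out if out.ndim else float(out)


def expected_baf(nA, nB, purity):
    """Expected mirrored B-allele fraction of state ``(nA, nB)`` at ``purity``.

    Returns ``max(b, 1-b)`` with ``b = ((1-rho) + rho*nB) / (2(1-rho) +
    rho*(nA+nB))``; always in [0.5, 1].
    """
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    if np.any(nB > nA) or np.any(nB < 0):
        raise ValueError("require nA >= nB >= 0")
    rho = float(purity)
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"purity must be in [0, 1], got {rho}")
    den = 2.0 * (1.0 - rho) + rho * (nA + nB)
    if np.any(den <= 0):
        raise ValueError("total copy number 0 at purity 1: BAF undefined")
    b = ((1.0 - rho) + rho * nB) / den
    out = np.maximum(b, 1.0 - b)
    return out if out.ndim else float(out)


def aliased_purity(purity: float) -> float:
    """Purity at which the genome-doubled profile (2*psi, 2*S) is identical.

    Solves ``2(1-rho)/rho = (1-rho')/rho'`` giving ``rho' = rho/(2-rho)``.
    """
    return purity / (2.0 - purity)


def _state_table(max_copies: int) -> np.ndarray:
    """Integer states (nA, nB) with nA >= nB >= 0 and 1 <= nA+nB <= max_copies.

    The homozygous-deletion state (0,0) is excluded: segments here are
    megabase-scale, and total loss of both copies over such spans is not
    viable.  Keeping it would also let genome-doubled profiles be re-encoded
    two copies lower (every state shifted down), destroying the main
    observable signature of whole-genome duplication.
    """
    states = [
        (t - b, b)
        for t in range(1, max_copies + 1)
        for b in range(t // 2 + 1)
    ]
    return np.array(states, dtype=int)


@dataclass
class CandidateSolution:
    """One (purity, scale) grid point with its best integer state assignment."""

    purity: float
    tumor_ploidy: float  # length-weighted mean of assigned total copies
    scale_ploidy: float  # grid psi entering the logR denominator
    fit_score: float
    states: np.ndarray  # (n_segments, 2) assigned (nA, nB)
    clonal_fraction: np.ndarray  # (n_segments,) all ones at this stage
    fraction_genome_aberrant: float
    segment_residuals: np.ndarray  # per-segment minimized residual (unweighted)


@dataclass
class Thresholds:
    """Abstention thresholds; calibrated on simulated low-pass profiles."""

    quiet_aberrant_fraction: float = 0.01
    flatness_fraction: float = 0.05
    poor_fit_score: float = 15.0
    subclone_residual: float = 9.0


@dataclass
class PurityCall:
    """Final per-sample call; ``purity`` is None iff the fitter abstained."""

    purity: float | None
    ploidy: float | None
    abstained: bool
    abstain_reason: str  # quiet_genome | poor_fit | insufficient_data | none
    runner_up_score_gap: float
    fit_score: float
    fraction_genome_aberrant: float
    segments: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abstained != (self.purity is None):
            raise ValueError("abstained must mirror missing purity")
        if (self.abstain_reason == "none") == self.abstained:
            raise ValueError("abstain_reason must be 'none' iff not abstained")


def _prepare_arrays(segments: pd.DataFrame, logr_floor: float = LOGR_SE_FLOOR):
    if len(segments) == 0:
        raise ValueError("insufficient data: no segments")
    L = segments["mean_logr"].to_numpy(dtype=float)
    sl = segments.get("logr_se", pd.Series(np.full(len(segments), 0.05))).to_numpy(dtype=float)
    sl = np.clip(np.nan_to_num(sl, nan=0.05), 1e-3, None)
    # systematic dispersion floor: long segments have tiny sampling SEs, but
    # residual GC wiggle and grid quantization put a floor on achievable
    # logR agreement; the floor is wider on the coarse first-pass grid than
    # after local (rho, psi) refinement
    sl = np.hypot(sl, logr_floor)
    B = segments["mirrored_baf"].to_numpy(dtype=float) if "mirrored_baf" in segments else np.full(len(segments), np.nan)
    sb = segments.get("baf_se", pd.Series(np.full(len(segments), 0.02))).to_numpy(dtype=float)
    # per-side SEs from the profile likelihood; fall back to the symmetric SE
    sb_lo = segments.get("baf_se_lo", pd.Series(sb)).to_numpy(dtype=float)
    sb_hi = segments.get("baf_se_hi", pd.Series(sb)).to_numpy(dtype=float)
    sb_lo = np.where(np.isfinite(sb_lo), sb_lo, sb)
    sb_hi = np.where(np.isfinite(sb_hi), sb_hi, sb)
    sb_lo = np.clip(np.nan_to_num(sb_lo, nan=0.02), 5e-3, None)
    sb_hi = np.clip(np.nan_to_num(sb_hi, nan=0.02), 5e-3, None)
    # exact profile log-likelihood curves, present when the profile came
    # straight from the preprocessing step (not via a SEG round-trip)
    if "_baf_loglik" in segments.columns:
        ll = list(segments["_baf_loglik"])
    else:
        ll = [None] * len(segments)
    w = segments["n_bins"].to_numpy(dtype=float)
    w = w / w.sum()
    return L, sl, B, sb_lo, sb_hi, ll, w


def _grid_surface(segments, purity_grid, ploidy_grid, max_copies,
                  state_prior_weight=None, state_mask=None,
                  logr_floor=LOGR_SE_FLOOR, use_mix_interval=True,
                  residual_cap=SEGMENT_RESIDUAL_CAP):
    """Vectorized grid evaluation of the composite objective.

    Each segment is scored, at every (purity, scale) grid point and for
    its best integer state, as the sum of (a) a variance-scaled squared
    logR residual (evidence: rejects models that absorb real signal as
    noise), (b) a tempered allelic deviance under the segment's folded
    binomial-mixture profile likelihood, and (c) a copy-space parsimony
    term -- the squared distance between the back-transformed real-valued
    copy number and the integer state.  The back-transform amplifies noise
    by ~1/purity, so degenerate low-purity fits and genome-doubled fits
    (whose noise doubles while integer spacing stays at one copy) pay for
    their flexibility without ad hoc rules.

    Returns (score[R,P], state_idx[S,R,P], states, ploidy_from_states[R,P],
    frac_aberrant[R,P], residuals[S,R,P]) with R purity and P scale points.
    """
    L, sl, B, sb_lo, sb_hi, ll, w = _prepare_arrays(segments, logr_floor)
    states = _state_table(max_copies)
    if state_mask is not None:
        states = states[state_mask]
    ntot = states.sum(axis=1).astype(float)
    rho = np.asarray(purity_grid, dtype=float)[:, None]  # R x 1
    psi = np.asarray(ploidy_grid, dtype=float)[None, :]  # 1 x P
    den = 2.0 * (1.0 - rho) + rho * psi  # R x P
    # e_baf depends on rho only: S_states x R
    r = rho[:, 0][None, :]
    den_b = 2.0 * (1.0 - r) + r * ntot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = ((1.0 - r) + r * states[:, 1][:, None]) / den_b
    e_baf = np.where(den_b > 0, np.maximum(b, 1.0 - b), 0.5)

    S = len(L)
    R, P = rho.shape[0], psi.shape[1]
    score = np.zeros((R, P))
    ploidy_states = np.zeros((R, P))
    frac_ab = np.zeros((R, P))
    state_idx = np.empty((S, R, P), dtype=np.int16)
    residuals = np.empty((S, R, P))
    aberrant = (states[:, 0] != 1) | (states[:, 1] != 1)
    if state_prior_weight is None:
        state_prior_weight = DEFAULT_STATE_PRIOR_WEIGHT
    # copy number of the balanced baseline clone at each scale point; a
    # baseline must be a (k,k) state, so its total is the nearest even value
    base_total = np.clip(2.0 * np.round(psi[0] / 2.0), 2, max_copies)  # P
    # mild karyotype complexity prior (copy^2 units): each copy step away
    # from the scale's own balanced baseline is taxed, regularizing against
    # noise-chasing exotic states.  Measuring from the local baseline (not
    # from diploid) keeps the prior from tilting the ploidy choice itself.
    base_half = base_total[None, :] / 2.0  # 1 x P
    prior = state_prior_weight * (
        np.abs(states[:, 0, None] - base_half) + np.abs(states[:, 1, None] - base_half)
    )  # Sstates x P
    from .preprocess import BAF_GRID

    with np.errstate(divide="ignore"):
        num = 2.0 * (1.0 - rho) + rho * np.arange(max_copies + 1)[:, None, None]
        e_logr = (
            np.where(num > 0, np.log2(np.maximum(num, 1e-300)), NEG_INF_LOGR)
            - np.log2(den)
        )  # (n+1) x R x P
    for i in range(S):
        # evidence term: variance-scaled squared logR residual
        d = (L[i] - e_logr[ntot.astype(int)]) ** 2 / sl[i] ** 2  # Sstates x R x P
        # parsimony term: distance to the integer state in copy space;
        # the back-transform amplifies noise by ~1/purity, penalizing
        # degenerate low-purity and genome-doubled representations
        t_raw = (2.0 ** L[i] * den - 2.0 * (1.0 - rho)) / rho  # R x P
        d = d + COPY_SPACE_WEIGHT * (
            (t_raw[None, :, :] - ntot[:, None, None]) ** 2 + prior[:, None, :]
        )
        if ll[i] is not None:
            # allelic evidence: deviance of the expected BAF under the
            # segment's folded binomial-mixture profile likelihood,
            # tempered by a quasi-likelihood dispersion factor (segment
            # BAF estimates scatter beyond their nominal binomial errors)
            mx = np.max(ll[i])
            dev = 2.0 * (mx - np.interp(e_baf, BAF_GRID, ll[i]))  # Sstates x R
            # copy-neutral states (total equal to the baseline copy number)
            # can mix with the balanced baseline at any subclonal fraction
            # without moving logR, so any pooled BAF in [0.5, e_baf] is
            # reachable; score those states against the best point of the
            # interval (cumulative-max likelihood) instead of the endpoint
            if use_mix_interval:
                dev_int = 2.0 * (
                    mx - np.interp(e_baf, BAF_GRID, np.maximum.accumulate(ll[i]))
                )
                neutral = ntot[:, None, None] == base_total[None, None, :]
                dev3 = np.where(neutral, dev_int[:, :, None], dev[:, :, None])
            else:
                dev3 = dev[:, :, None]
            d = d + dev3 / BAF_DISPERSION
        elif np.isfinite(B[i]):
            # SEG-file path: quadratic approximation with asymmetric
            # profile-likelihood errors (wider toward the 0.5 fold)
            sb = np.where(e_baf < B[i], sb_lo[i], sb_hi[i])
            d = d + ((B[i] - e_baf) ** 2 / sb**2)[:, :, None] / BAF_DISPERSION
        k = np.argmin(d, axis=0)
        state_idx[i] = k
        res = np.take_along_axis(d, k[None, :, :], axis=0)[0]
        if residual_cap is not None:
            res = np.minimum(res, residual_cap)
        residuals[i] = res
        score += w[i] * res
        ploidy_states += w[i] * ntot[k]
        frac_ab += w[i] * aberrant[k]
    return score, state_idx, states, ploidy_states, frac_ab, residuals


def score_candidate(
    segments: pd.DataFrame,
    purity: float,
    tumor_ploidy: float,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> CandidateSolution:
    """Best integer state assignment at a single (purity, scale) point.

    Per segment the state minimizing the variance-scaled squared residual in
    (logR, BAF) is chosen; the BAF term is dropped where the segment's
    mirrored BAF is missing.  ``fit_score`` is the length-weighted mean of
    the minimized residuals.
    """
    if max_copies < 2:
        raise ValueError("max_copies must be >= 2")
    score, sidx, states, pl, fa, res = _grid_surface(
        segments, [purity], [tumor_ploidy], max_copies
    )
    return CandidateSolution(
        purity=float(purity),
        tumor_ploidy=float(pl[0, 0]),
        scale_ploidy=float(tumor_ploidy),
        fit_score=float(score[0, 0]),
        states=states[sidx[:, 0, 0]],
        clonal_fraction=np.ones(len(segments)),
        fraction_genome_aberrant=float(fa[0, 0]),
        segment_residuals=res[:, 0, 0],
    )


def fit_grid(
    segments: pd.DataFrame,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> list[CandidateSolution]:
    """Exhaustive grid search; candidates sorted by fit score ascending.

    Ties are broken deterministically by lower scale psi, then higher
    purity.
    """
    purity_grid = PURITY_GRID if purity_grid is None else np.asarray(purity_grid, dtype=float)
    ploidy_grid = PLOIDY_GRID if ploidy_grid is None else np.asarray(ploidy_grid, dtype=float)
    if len(purity_grid) == 0 or len(ploidy_grid) == 0:
        raise ValueError("purity and ploidy grids must be non-empty")
    score, sidx, states, pl, fa, res = _grid_surface(
        segments, purity_grid, ploidy_grid, max_copies
    )
    R, P = score.shape
    rho_flat = np.repeat(purity_grid, P)
    psi_flat = np.tile(ploidy_grid, R)
    order = np.lexsort((-rho_flat, psi_flat, score.ravel()))
    candidates = []
    for flat in order:
        i, j = divmod(flat, P)
        candidates.append(
            CandidateSolution(
                purity=float(purity_grid[i]),
                tumor_ploidy=float(pl[i, j]),
                scale_ploidy=float(ploidy_grid[j]),
                fit_score=float(score[i, j]),
                states=states[sidx[:, i, j]],
                clonal_fraction=np.ones(sidx.shape[0]),
                fraction_genome_aberrant=float(fa[i, j]),
                segment_residuals=res[:, i, j],
            )
        )
    return candidates


def reducibility_gap(
    segments: pd.DataFrame,
    candidate: CandidateSolution,
    k: int = 2,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> float:
    """Score cost of forcing the candidate onto exact k-fold copy states.

    The genome-doubled image of any solution uses only states with both
    alleles even, so a candidate that loses almost nothing when restricted
    to such states is expressible at 1/k of its ploidy (at the aliased
    purity) and carries no evidence for genome doubling.  Genuine post-WGD
    genomes contain states like (2,1) -- odd minor allele -- whose even
    approximations misfit badly, making this gap large.
    """
    full_states = _state_table(max_copies)
    mask = (full_states[:, 0] % k == 0) & (full_states[:, 1] % k == 0)
    point = ([candidate.purity], [candidate.scale_ploidy])
    # the copy-neutral mixture interval is disabled here: the gap must
    # measure pure integer-state fit, not subclonal-mixture concessions
    r_res = _grid_surface(
        segments, *point, max_copies, state_mask=mask,
        logr_floor=LOGR_SE_FLOOR_FINE, use_mix_interval=False, residual_cap=None,
    )[5][:, 0, 0]
    f_res = _grid_surface(
        segments, *point, max_copies,
        logr_floor=LOGR_SE_FLOOR_FINE, use_mix_interval=False, residual_cap=None,
    )[5][:, 0, 0]
    # segments the unrestricted fit itself cannot place on an integer state
    # (subclonal copy numbers) carry no reliable evidence about lattice
    # parity and are excluded from the gap
    w = segments["n_bins"].to_numpy(dtype=float)
    w = w / w.sum()
    usable = f_res <= SUBCLONAL_EVIDENCE_CUTOFF
    return float(np.sum(w[usable] * (r_res[usable] - f_res[usable])))


def select_solution(
    candidates: list[CandidateSolution],
    wgd_score_margin: float = DEFAULT_WGD_MARGIN,
    segments: pd.DataFrame | None = None,
    max_copies: int = DEFAULT_MAX_COPIES,
    irreducibility_threshold: float = DEFAULT_IRREDUCIBILITY_THRESHOLD,
) -> CandidateSolution:
    """Parsimony rule for the whole-genome-duplication alias.

    Among candidates within ``wgd_score_margin`` (relative) of the best
    score, the lowest tumor ploidy is preferred.  When ``segments`` are
    supplied the pick is then walked down the alias ladder: while the
    current solution can be expressed with exact k-fold copy states (k = 2
    or 3) at a fit cost below ``irreducibility_threshold`` -- i.e. nothing
    in the data demands the duplicated karyotype -- the best candidate at
    substantially lower ploidy is taken instead.  A higher-ploidy solution
    therefore survives only when it decisively beats every lower-ploidy
    representation.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best = candidates[0].fit_score
    cut = best * (1.0 + wgd_score_margin) + 1e-12
    eligible = [c for c in candidates if c.fit_score <= cut]
    pick = min(
        eligible, key=lambda c: (c.tumor_ploidy, c.scale_ploidy, -c.purity, c.fit_score)
    )
    if segments is None:
        return pick
    while True:
        gaps = [
            reducibility_gap(segments, pick, k=k, max_copies=max_copies)
            for k in (2, 3)
        ]
        if min(gaps) > irreducibility_threshold:
            return pick
        lower = [c for c in candidates if c.tumor_ploidy <= 0.75 * pick.tumor_ploidy]
        if not lower:
            return pick
        pick = min(lower, key=lambda c: (c.fit_score, c.scale_ploidy, -c.purity))


def assess_confidence(
    best: CandidateSolution,
    runner_up: CandidateSolution | None,
    thresholds: Thresholds | None = None,
    score_by_purity: np.ndarray | None = None,
) -> PurityCall:
    """Turn the selected candidate into a call, abstaining on weak signal.

    Abstains with ``quiet_genome`` when almost no genome is aberrant or the
    score profile across the purity grid is flat (purity unidentifiable);
    with ``poor_fit`` when even the best candidate fits badly.
    """
    th = thresholds or Thresholds()
    gap = (runner_up.fit_score - best.fit_score) if runner_up is not None else np.inf
    quiet = best.fraction_genome_aberrant < th.quiet_aberrant_fraction
    if score_by_purity is not None and len(score_by_purity) > 1:
        rng_ = float(np.max(score_by_purity) - np.min(score_by_purity))
        med = float(np.median(score_by_purity))
        if rng_ < th.flatness_fraction * max(med, 1e-12):
            quiet = True
    if quiet:
        return PurityCall(
            purity=None, ploidy=None, abstained=True, abstain_reason="quiet_genome",
            runner_up_score_gap=float(gap), fit_score=best.fit_score,
            fraction_genome_aberrant=best.fraction_genome_aberrant,
        )
    if best.fit_score > th.poor_fit_score:
        return PurityCall(
            purity=None, ploidy=None, abstained=True, abstain_reason="poor_fit",
            runner_up_score_gap=float(gap), fit_score=best.fit_score,
            fraction_genome_aberrant=best.fraction_genome_aberrant,
        )
    return PurityCall(
        purity=best.purity, ploidy=best.tumor_ploidy, abstained=False,
        abstain_reason="none", runner_up_score_gap=float(gap),
        fit_score=best.fit_score,
        fraction_genome_aberrant=best.fraction_genome_aberrant,
    )


def infer_subclonal_fraction(
    segments: pd.DataFrame,
    solution: CandidateSolution,
    thresholds: Thresholds | None = None,
) -> np.ndarray:
    """Clonal fraction per segment, refining poorly fitting integer states.

    For a segment whose integer residual exceeds the threshold, the
    effective copy number is recovered by inverting the admixture model at
    the called (purity, scale); the clonal fraction mixes the adjacent
    altered integer with the baseline-side integer:
    ``n_eff = f*n_alt + (1-f)*n_base``.  Segments already fitting an
    integer state keep clonal fraction 1.
    """
    th = thresholds or Thresholds()
    rho = solution.purity
    psi = solution.scale_ploidy
    den = 2.0 * (1.0 - rho) + rho * psi
    L = segments["mean_logr"].to_numpy(dtype=float)
    base_total = 4 if solution.tumor_ploidy > 3.0 else 2
    f_out = np.ones(len(segments))
    for i in range(len(segments)):
        if solution.segment_residuals[i] <= th.subclone_residual:
            continue
        n_eff = (2.0 ** L[i] * den - 2.0 * (1.0 - rho)) / rho if rho > 0 else np.nan
        if not np.isfinite(n_eff) or n_eff < 0:
            continue
        n_lo = int(np.floor(n_eff))
        n_hi = n_lo + 1
        if abs(n_eff - round(n_eff)) < 1e-9:
            continue  # sits on an integer: clonal
        # baseline side is the adjacent integer closer to the genome baseline
        if abs(n_lo - base_total) <= abs(n_hi - base_total):
            n_base, n_alt = n_lo, n_hi
        else:
            n_base, n_alt = n_hi, n_lo
        if n_alt == n_base:
            continue
        f = (n_eff - n_base) / (n_alt - n_base)
        if 0.0 < f <= 1.0:
            f_out[i] = float(f)
    return f_out


def call_segments(
    segments: pd.DataFrame,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    max_copies: int = DEFAULT_MAX_COPIES,
    wgd_score_margin: float = DEFAULT_WGD_MARGIN,
    thresholds: Thresholds | None = None,
) -> PurityCall:
    """Full inference on a segment profile: grid fit, alias resolution,
    confidence assessment and subclonal refinement.

    The returned call carries the input segments annotated with assigned
    ``nA``, ``nB`` and ``clonal_fraction`` (also for abstained calls, where
    they reflect the selected but unreported candidate).
    """
    purity_grid = PURITY_GRID if purity_grid is None else np.asarray(purity_grid, dtype=float)
    ploidy_grid = PLOIDY_GRID if ploidy_grid is None else np.asarray(ploidy_grid, dtype=float)
    score, sidx, states, pl, fa, res = _grid_surface(
        segments, purity_grid, ploidy_grid, max_copies
    )
    R, P = score.shape
    rho_flat = np.repeat(purity_grid, P)
    psi_flat = np.tile(ploidy_grid, R)
    score_flat = score.ravel()
    pl_flat = pl.ravel()
    order = np.lexsort((-rho_flat, psi_flat, score_flat))

    def _refine(flat: int) -> CandidateSolution:
        # local re-fit around a coarse seed with fine steps and the tight
        # logR floor: competing aliased and shifted solutions differ by
        # ~0.01-0.03 in logR, below the coarse-grid quantization
        i, j = divmod(flat, P)
        r0, p0 = purity_grid[i], ploidy_grid[j]
        rg = np.clip(np.arange(r0 - 0.015, r0 + 0.0151, 0.0025), 0.02, 1.0)
        pg = np.arange(max(p0 - 0.06, 1.0), p0 + 0.0601, 0.004)
        s2, x2, st2, pl2, fa2, res2 = _grid_surface(
            segments, rg, pg, max_copies, logr_floor=LOGR_SE_FLOOR_FINE
        )
        a, b = np.unravel_index(np.argmin(s2), s2.shape)
        return CandidateSolution(
            purity=float(rg[a]),
            tumor_ploidy=float(pl2[a, b]),
            scale_ploidy=float(pg[b]),
            fit_score=float(s2[a, b]),
            states=st2[x2[:, a, b]],
            clonal_fraction=np.ones(x2.shape[0]),
            fraction_genome_aberrant=float(fa2[a, b]),
            segment_residuals=res2[:, a, b],
        )

    def _shift_down(cand: CandidateSolution) -> CandidateSolution | None:
        # exact shift alias: same observables two copies lower, at the
        # purity solving 2(1-rho')/rho' = 2(1-rho)/rho + 2
        rho0, psi0 = cand.purity, cand.scale_ploidy
        if psi0 - 2.0 < 1.0 or rho0 <= 0:
            return None
        c = 2.0 * (1.0 - rho0) / rho0
        rho_d = 2.0 / (4.0 + c)
        rg = np.clip(np.arange(rho_d - 0.01, rho_d + 0.0101, 0.0025), 0.02, 1.0)
        pg = np.arange(max(psi0 - 2.0 - 0.03, 1.0), psi0 - 2.0 + 0.0301, 0.004)
        s2, x2, st2, pl2, fa2, res2 = _grid_surface(
            segments, rg, pg, max_copies, logr_floor=LOGR_SE_FLOOR_FINE
        )
        a, b = np.unravel_index(np.argmin(s2), s2.shape)
        return CandidateSolution(
            purity=float(rg[a]),
            tumor_ploidy=float(pl2[a, b]),
            scale_ploidy=float(pg[b]),
            fit_score=float(s2[a, b]),
            states=st2[x2[:, a, b]],
            clonal_fraction=np.ones(x2.shape[0]),
            fraction_genome_aberrant=float(fa2[a, b]),
            segment_residuals=res2[:, a, b],
        )

    # seeds: the best coarse point of every half-copy ploidy band
    bands: dict[int, int] = {}
    for f in order:
        key = int(round(pl_flat[f] * 2))
        if key not in bands:
            bands[key] = int(f)
    refined = sorted((_refine(f) for f in bands.values()),
                     key=lambda c: (c.fit_score, c.scale_ploidy, -c.purity))
    best_score = refined[0].fit_score
    cut = best_score * (1.0 + wgd_score_margin) + 1e-12
    eligible = [c for c in refined if c.fit_score <= cut]
    chosen = min(
        eligible,
        key=lambda c: (c.tumor_ploidy, c.scale_ploidy, -c.purity, c.fit_score),
    )
    # walk down the alias ladders while the data carry no evidence for the
    # duplicated karyotype: exact k-fold reducibility (doubling/tripling)
    # and the exact shift-by-two degeneracy (see SHIFT_ALIAS_MARGIN)
    while True:
        gaps = [
            reducibility_gap(segments, chosen, k=k, max_copies=max_copies)
            for k in (2, 3)
        ]
        if min(gaps) <= DEFAULT_IRREDUCIBILITY_THRESHOLD:
            lower = [c for c in refined if c.tumor_ploidy <= 0.75 * chosen.tumor_ploidy]
            if lower:
                nxt = min(lower, key=lambda c: (c.fit_score, c.scale_ploidy, -c.purity))
                if nxt is not chosen:
                    chosen = nxt
                    continue
        down = _shift_down(chosen)
        if down is not None and down.fit_score <= chosen.fit_score * (1.0 + SHIFT_ALIAS_MARGIN):
            chosen = down
            continue
        break
    runner = next((c for c in refined if c is not chosen), None)
    score_by_purity = score.min(axis=1)
    # quiet-genome statistic: genome fraction whose assigned state differs
    # from the baseline in total copies (visible in logR) or is confidently
    # allelically unbalanced.  Copy-neutral "partial LOH" assignments driven
    # by small folding flukes of balanced segments do not count.
    L_, sl_, B_, sblo_, sbhi_, ll_, w_ = _prepare_arrays(segments)
    from .preprocess import BAF_GRID

    base_t = float(np.clip(2.0 * round(chosen.scale_ploidy / 2.0), 2, max_copies))
    e_base = expected_logr(base_t, chosen.purity, chosen.scale_ploidy)
    fa_eff = 0.0
    for i in range(len(w_)):
        nA_, nB_ = chosen.states[i]
        # a total-copy aberration only counts when the segment's logR
        # deviates confidently from the baseline expectation; a degenerate
        # low-purity solution can label noise-level segments with aberrant
        # integers without any such deviation
        if nA_ + nB_ != base_t and abs(L_[i] - e_base) > 3.0 * sl_[i]:
            fa_eff += w_[i]
        elif nA_ != nB_ and ll_[i] is not None:
            dev0 = 2.0 * (np.max(ll_[i]) - np.interp(0.5, BAF_GRID, ll_[i]))
            if dev0 > QUIET_ALLELIC_DEV:
                fa_eff += w_[i]
    chosen.fraction_genome_aberrant = float(fa_eff)
    call = assess_confidence(chosen, runner, thresholds, score_by_purity)

    annotated = segments.copy().reset_index(drop=True)
    annotated["nA"] = chosen.states[:, 0]
    annotated["nB"] = chosen.states[:, 1]
    if not call.abstained:
        annotated["clonal_fraction"] = infer_subclonal_fraction(
            annotated, chosen, thresholds
        )
    else:
        annotated["clonal_fraction"] = 1.0
    call.segments = annotated
    return call
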