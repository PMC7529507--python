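"""Concordance statistics between tumor-purity estimators.

Given a samples x methods purity matrix, this module quantifies how the
estimators relate: pairwise-complete correlation with Ward-clustered method
ordering, a one-way ANOVA of purity across methods, per-sample agreement
classification of molecular consensus estimates against pathology
(concordant within a tolerance, joint under-/over-estimation, or
discordant) with an exact binomial test of the under- vs over-estimation
direction, purity stratification by gene mutation status (rank-sum tests,
BH-adjusted), purity-vs-VAF correlation per gene, and a feature screen
counting, per molecular feature, how many purity estimators it correlates
with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConcordanceReport",
    "correlation_matrix",
    "order_methods",
    "intermethod_anova",
    "classify_agreement",
    "binomial_direction_test",
    "agreement_summary",
    "stratify_by_mutation",
    "vaf_purity_correlation",
    "feature_purity_screen",
    "correlate_covariates",
    "bh_adjust",
    "DEFAULT_AGREEMENT_TOL",
    "DEFAULT_MIN_MUT",
    "DEFAULT_MIN_MUT_VAF",
    "DEFAULT_RHO_MIN",
    "DEFAULT_FDR_MAX",
]

DEFAULT_AGREEMENT_TOL = 0.15
DEFAULT_MIN_MUT = 4  # "more than three" mutant samples
DEFAULT_MIN_MUT_VAF = 11  # "more than ten" mutant carriers
DEFAULT_RHO_MIN = 0.3
DEFAULT_FDR_MAX = 0.01
EXACT_RANKSUM_MAX_N = 50


@dataclass
class ConcordanceReport:
    """Correlation structure and agreement statistics for a purity matrix."""

    r: pd.DataFrame
    n: pd.DataFrame
    method: str = "pearson"
    ordering: list[str] | None = None
    anova_f: float | None = None
    anova_p: float | None = None


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini--Hochberg step-up adjustment, returned in input order.

    NaNs are passed through and excluded from the family size.
    """
    p = np.asarray(p_values, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def correlation_matrix(
    matrix: pd.DataFrame, method: str = "pearson", min_pairs: int = 3
) -> ConcordanceReport:
    """Pairwise-complete correlation between estimation methods.

    Cells with fewer than ``min_pairs`` complete pairs are reported missing;
    the matrix is symmetric with unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    r = matrix.corr(method=method, min_periods=min_pairs)
    notna = matrix.notna().astype(float)
    n = notna.T @ notna
    np.fill_diagonal(r.values, 1.0)
    return ConcordanceReport(r=r, n=n.astype(int), method=method)


def order_methods(report: ConcordanceReport) -> list[str]:
    """Ward-linkage ordering of methods on distance 1 - R.

    Methods are pre-sorted by name so tied merges resolve deterministically.
    """
    r = report.r.sort_index(axis=0).sort_index(axis=1)
    names = list(r.columns)
    if len(names) == 1:
        return names
    if r.isna().any().any():
        raise ValueError("correlation matrix has missing cells; cannot cluster")
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    return [names[i] for i in leaves_list(z)]


def intermethod_anova(matrix: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of purity values with method as the group factor."""
    groups = [matrix[c].dropna().to_numpy() for c in matrix.columns]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need at least two methods with >= 2 values each")
    grand = np.concatenate(groups)
    if np.ptp(grand) < 1e-15:
        # every value identical: no between- or within-group variation
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(f), float(p)


def classify_agreement(
    pathology: float, dna: float, mrna: float, tol: float = DEFAULT_AGREEMENT_TOL
) -> str:
    """Classify a sample's molecular estimates against pathology.

    concordant: both within ``tol`` of pathology; underestimate /
    overestimate: both beyond ``tol`` in the same direction; discordant
    otherwise.  All three estimates must be present.
    """
    for v in (pathology, dna, mrna):
        if v is None or not np.isfinite(v):
            raise ValueError("all three estimates must be present")
    if abs(dna - pathology) <= tol and abs(mrna - pathology) <= tol:
        return "concordant"
    if dna < pathology - tol and mrna < pathology - tol:
        return "underestimate"
    if dna > pathology + tol and mrna > pathology + tol:
        return "overestimate"
    return "discordant"


def binomial_direction_test(n_ue: int, n_oe: int) -> float:
    """Two-sided exact binomial test of UE vs OE direction at p=1/2."""
    if n_ue < 0 or n_oe < 0 or n_ue + n_oe < 1:
        raise ValueError("need at least one UE or OE sample")
    return float(stats.binomtest(n_ue, n_ue + n_oe, 0.5).pvalue)


def agreement_summary(
    pathology: pd.Series,
    dna: pd.Series,
    mrna: pd.Series,
    tol: float = DEFAULT_AGREEMENT_TOL,
) -> dict:
    """Classify all samples with complete triples and test UE vs OE.

    Returns class labels per sample, class fractions, and the binomial
    p-value over the samples deviating jointly in one direction.
    """
    df = pd.DataFrame({"pathology": pathology, "dna": dna, "mrna": mrna}).dropna()
    classes = df.apply(
        lambda row: classify_agreement(row["pathology"], row["dna"], row["mrna"], tol),
        axis=1,
    )
    counts = classes.value_counts()
    n_ue = int(counts.get("underestimate", 0))
    n_oe = int(counts.get("overestimate", 0))
    p = binomial_direction_test(n_ue, n_oe) if (n_ue + n_oe) else np.nan
    return {
        "classes": classes,
        "n_eligible": len(df),
        "fractions": (counts / max(len(df), 1)).to_dict(),
        "n_ue": n_ue,
        "n_oe": n_oe,
        "binomial_p": p,
    }


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when tie-free and small, else normal
    approximation with mid-ranks and tie-corrected variance."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(x), len(y)) <= EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def stratify_by_mutation(
    purity: pd.Series,
    mutations: pd.DataFrame,
    min_mut: int = DEFAULT_MIN_MUT,
) -> pd.DataFrame:
    """Purity in mutant vs wild-type samples, per gene.

    ``mutations`` has columns (sample, gene).  Genes with fewer than
    ``min_mut`` mutant samples (among samples with purity) are flagged
    untested (no p-value).  log2fc is the difference in mean purity on the
    log2 scale; BH adjustment runs across tested genes only.
    """
    purity = purity.dropna()
    rows = []
    for gene, grp in mutations.groupby("gene", sort=True):
        mut_samples = set(grp["sample"]) & set(purity.index)
        mut = purity.loc[sorted(mut_samples)].to_numpy()
        wt = purity.drop(index=sorted(mut_samples)).to_numpy()
        tested = len(mut) >= min_mut and len(wt) >= 1
        log2fc = (
            float(np.log2(mut.mean()) - np.log2(wt.mean()))
            if len(mut) and len(wt) and mut.mean() > 0 and wt.mean() > 0
            else np.nan
        )
        rows.append(
            {
                "gene": gene,
                "n_mut": len(mut),
                "n_wt": len(wt),
                "tested": tested,
                "log2fc": log2fc,
                "wilcoxon_p": _ranksum_p(mut, wt) if tested else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_adjusted_p"] = bh_adjust(out["wilcoxon_p"])
    return out


def vaf_purity_correlation(
    purity: pd.Series,
    mutations: pd.DataFrame,
    min_mut: int = DEFAULT_MIN_MUT_VAF,
) -> pd.DataFrame:
    """Pearson correlation between purity and VAF across mutant carriers.

    ``mutations`` has columns (sample, gene, vaf).  Genes with fewer than
    ``min_mut`` carriers (with purity present) are excluded; zero-variance
    VAF yields a missing correlation.  BH adjustment runs across computed
    correlations.
    """
    if "vaf" not in mutations.columns:
        raise ValueError("mutations table needs a 'vaf' column")
    bad = mutations["vaf"].dropna()
    if len(bad) and ((bad < 0).any() or (bad > 1).any()):
        raise ValueError("VAF values must lie in [0, 1]")
    purity = purity.dropna()
    rows = []
    for gene, grp in mutations.groupby("gene", sort=True):
        grp = grp.dropna(subset=["vaf"])
        carriers = grp[grp["sample"].isin(purity.index)]
        if len(carriers) < min_mut:
            continue
        p = purity.loc[carriers["sample"]].to_numpy()
        v = carriers["vaf"].to_numpy(dtype=float)
        if np.ptp(v) < 1e-15 or np.ptp(p) < 1e-15:
            r, pv = np.nan, np.nan
        else:
            r, pv = stats.pearsonr(p, v)
        rows.append({"gene": gene, "n_mut": len(carriers), "vaf_pearson_r": r, "p": pv})
    out = pd.DataFrame(rows, columns=["gene", "n_mut", "vaf_pearson_r", "p"])
    out["fdr_adjusted_p"] = bh_adjust(out["p"]) if len(out) else np.nan
    return out


def feature_purity_screen(
    features: pd.DataFrame,
    estimators: pd.DataFrame,
    rho_min: float = DEFAULT_RHO_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_overlap: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count, per feature, how many purity estimators it correlates with.

    ``features`` is features x samples; ``estimators`` is samples x
    estimators (e.g. pathology, DNA, mRNA, miRNA).  Spearman correlation is
    computed per (feature, estimator) over their shared non-missing
    samples; BH adjustment runs within each estimator across features; a
    pair is significant iff |rho| > ``rho_min`` and adjusted p < ``fdr_max``.
    Returns the tidy per-pair table and the histogram of per-feature
    significant-estimator counts (0..n_estimators).
    """
    records = []
    for est in estimators.columns:
        evals = estimators[est].dropna()
        common = [s for s in features.columns if s in evals.index]
        sub = features[common]
        ev = evals.loc[common].to_numpy(dtype=float)
        for feat, vals in sub.iterrows():
            v = vals.to_numpy(dtype=float)
            mask = np.isfinite(v)
            if mask.sum() < min_overlap:
                records.append((feat, est, np.nan, np.nan, mask.sum()))
                continue
            x, y = v[mask], ev[mask]
            if np.ptp(x) < 1e-15 or np.ptp(y) < 1e-15:
                records.append((feat, est, np.nan, np.nan, mask.sum()))
                continue
            rho, p = stats.spearmanr(x, y)
            records.append((feat, est, rho, p, mask.sum()))
    pairs = pd.DataFrame(records, columns=["feature", "estimator", "rho", "p", "n"])
    pairs["fdr_adjusted_p"] = np.nan
    for est in estimators.columns:
        sel = pairs["estimator"] == est
        pairs.loc[sel, "fdr_adjusted_p"] = bh_adjust(pairs.loc[sel, "p"])
    pairs["significant"] = (
        (pairs["rho"].abs() > rho_min) & (pairs["fdr_adjusted_p"] < fdr_max)
    ).fillna(False)
    tested = pairs.dropna(subset=["rho"])["feature"].unique()
    counts = (
        pairs[pairs["feature"].isin(tested)]
        .groupby("feature")["significant"]
        .sum()
        .astype(int)
    )
    hist = counts.value_counts().reindex(range(len(estimators.columns) + 1), fill_value=0)
    hist.index.name = "n_significant_estimators"
    return pairs, hist


def correlate_covariates(
    matrix: pd.DataFrame, covariates: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate each purity method with each per-sample covariate.

    Thin wrapper over pairwise-complete correlation for covariate tables
    such as (ar_score, pga, snv_count) consumed as given.
    """
    joined = matrix.join(covariates, how="inner")
    report = correlation_matrix(joined, method=method)
    return report.r.loc[matrix.columns, covariates.columns]
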