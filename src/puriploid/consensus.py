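"""Consensus purity estimates across observers and estimation methods.

Pathology reviews arrive as per-observer purity *ranges* (optionally for a
top and a bottom tissue section).  Each range is snapped to the decile grid
(multiples of 0.1, half-up rounding), collapsed to the midpoint of the
snapped range, and the per-sample point estimate is the median across all
available reviews.

Molecular estimators are grouped by analyte (DNA-based vs mRNA-based), and
the per-sample consensus for an analyte is the median over the non-missing
values of its methods.  Missingness is never imputed: a failed or abstained
call stays missing, because for DNA-based methods it carries signal (quiet
genomes).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ANALYTE_MAP",
    "snap_to_decile",
    "collapse_pathology_range",
    "collapse_pathology_table",
    "consensus_estimate",
    "consensus_table",
    "build_purity_matrix",
]

#: analyte -> methods eligible for that analyte's consensus
DEFAULT_ANALYTE_MAP: dict[str, list[str]] = {
    "DNA": ["ABSOLUTE", "ASCAT", "CLONET", "INTEGER", "OncoSNP", "lowpass"],
    "mRNA": ["DeMix", "ISOpure"],
}


def snap_to_decile(x: float) -> float:
    """Round a purity fraction to the nearest decile, half up (0.55 -> 0.6)."""
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"purity must be in [0, 1], got {x}")
    return math.floor(x * 10.0 + 0.5 + 1e-9) / 10.0


def collapse_pathology_range(reviews: pd.DataFrame) -> float:
    """Collapse one sample's multiobserver purity ranges to a point estimate.

    Each review's (range_lo, range_hi) endpoints are snapped to deciles, the
    review contributes the midpoint of its snapped range, and the sample
    estimate is the median across reviews (both sections, when present).
    Returns NaN for an empty review table.
    """
    if len(reviews) == 0:
        return np.nan
    points = []
    for lo, hi in zip(reviews["range_lo"], reviews["range_hi"]):
        if lo > hi:
            raise ValueError(f"range_lo {lo} > range_hi {hi}")
        slo, shi = snap_to_decile(float(lo)), snap_to_decile(float(hi))
        points.append((slo + shi) / 2.0)
    return float(np.median(points))


def collapse_pathology_table(reviews: pd.DataFrame) -> pd.Series:
    """Per-sample pathology point estimates from a full review table."""
    return reviews.groupby("sample", sort=True).apply(
        collapse_pathology_range, include_groups=False
    ).rename("pathology")


def consensus_estimate(
    matrix: pd.DataFrame,
    sample: str,
    analyte: str,
    analyte_map: dict[str, list[str]] | None = None,
) -> float:
    """Median purity over the analyte's methods for one sample.

    NaN iff every mapped method is missing for the sample; unknown analyte
    raises.
    """
    amap = DEFAULT_ANALYTE_MAP if analyte_map is None else analyte_map
    if analyte not in amap:
        raise ValueError(f"unknown analyte {analyte!r}; known: {sorted(amap)}")
    methods = [m for m in amap[analyte] if m in matrix.columns]
    if not methods:
        return np.nan
    vals = matrix.loc[sample, methods].astype(float).dropna()
    return float(vals.median()) if len(vals) else np.nan


def consensus_table(
    matrix: pd.DataFrame, analyte_map: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Per-sample consensus values for every analyte in the map."""
    amap = DEFAULT_ANALYTE_MAP if analyte_map is None else analyte_map
    out = {}
    for analyte, methods in amap.items():
        cols = [m for m in methods if m in matrix.columns]
        if cols:
            out[analyte] = matrix[cols].median(axis=1, skipna=True)
        else:
            out[analyte] = pd.Series(np.nan, index=matrix.index)
    return pd.DataFrame(out, index=matrix.index)


def build_purity_matrix(method_values: dict[str, pd.Series]) -> pd.DataFrame:
    """Outer-join per-method purity series into a samples x methods matrix.

    Abstained/failed calls must already be NaN in the input series; they
    stay missing.  A duplicated sample within a method is an error.
    """
    columns = {}
    for method, series in method_values.items():
        s = pd.Series(series, dtype=float)
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise ValueError(f"duplicate sample {dup!r} for method {method!r}")
        bad = s.dropna()
        if len(bad) and ((bad < 0).any() or (bad > 1).any()):
            raise ValueError(f"method {method!r} has purity values outside [0, 1]")
        columns[method] = s
    matrix = pd.DataFrame(columns)
    matrix.index.name = "sample"
    return matrix.sort_index()
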