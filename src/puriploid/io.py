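"""Readers and writers for the plain-text formats used across the package.

Conventions
-----------
* Binned coverage is BED-like TSV with 0-based half-open coordinates:
  ``chrom  start  end  gc  tumor_count  normal_count``.
* Allele counts are TSV with 1-based positions:
  ``chrom  pos  ref_count  alt_count``.
* Segment profiles are SEG-style TSV with 1-based *inclusive* coordinates on
  disk (community convention); they are converted to the package's internal
  0-based half-open representation at the I/O boundary.
* Missing values are written as ``NA``.

All writers are deterministic given identical in-memory state (fixed float
formatting, no timestamps).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "read_bins",
    "write_bins",
    "read_snps",
    "write_snps",
    "read_seg",
    "write_seg",
    "read_truth",
    "write_truth",
    "read_purity_matrix",
    "write_purity_matrix",
    "read_pathology",
    "read_analyte_map",
    "write_purity_call",
    "read_purity_call",
]

NA = "NA"


class ValidationError(ValueError):
    """Malformed or inconsistent input, with offending line numbers."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _check_sorted_nonoverlapping(df: pd.DataFrame, path) -> None:
    # line numbers: header is line 1, first record line 2
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lines = grp.index.to_numpy() + 2
        bad = np.where(np.asarray(ends) <= np.asarray(starts))[0]
        if len(bad):
            raise ValidationError(f"{path}: line {lines[bad[0]]}: end <= start on {chrom}")
        if len(grp) > 1:
            prev_end = ends[:-1]
            nxt_start = starts[1:]
            bad = np.where(nxt_start < prev_end)[0]
            if len(bad):
                i = bad[0]
                raise ValidationError(
                    f"{path}: lines {lines[i]} and {lines[i + 1]}: "
                    f"overlapping or unsorted intervals on {chrom}"
                )


def read_bins(path) -> pd.DataFrame:
    """Read binned tumor/normal coverage (BED-like, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "start", "end", "gc", "tumor_count", "normal_count"], path)
    gc = df["gc"].to_numpy(dtype=float)
    bad = np.where((gc < 0) | (gc > 1))[0]
    if len(bad):
        raise ValidationError(f"{path}: line {bad[0] + 2}: gc={gc[bad[0]]} outside [0, 1]")
    for col in ("tumor_count", "normal_count"):
        vals = df[col].to_numpy()
        bad = np.where(vals < 0)[0]
        if len(bad):
            raise ValidationError(f"{path}: line {bad[0] + 2}: negative {col}")
    _check_sorted_nonoverlapping(df, path)
    return df


def write_bins(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "gc", "tumor_count", "normal_count"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_snps(path) -> pd.DataFrame:
    """Read heterozygous-SNP allele counts (1-based positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "pos", "ref_count", "alt_count"], path)
    for col in ("ref_count", "alt_count"):
        vals = df[col].to_numpy()
        bad = np.where(vals < 0)[0]
        if len(bad):
            raise ValidationError(f"{path}: line {bad[0] + 2}: negative {col}")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        lines = grp.index.to_numpy() + 2
        bad = np.where(np.diff(pos) < 0)[0]
        if len(bad):
            raise ValidationError(f"{path}: line {lines[bad[0] + 1]}: unsorted position on {chrom}")
    return df


def write_snps(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "ref_count", "alt_count"]].to_csv(path, sep="\t", index=False)


SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "mean_logr", "mirrored_baf", "n_snps"]
_SEG_OPTIONAL = ["nA", "nB", "clonal_fraction", "baf_se", "baf_se_lo", "baf_se_hi", "logr_se"]


def write_seg(profile: pd.DataFrame, path, sample: str = "sample") -> None:
    """Write a segment profile as SEG-style TSV (1-based inclusive on disk)."""
    out = profile.copy()
    if "sample" not in out.columns:
        out.insert(0, "sample", sample)
    out["start"] = out["start"].astype(int) + 1  # to 1-based inclusive
    out["end"] = out["end"].astype(int)
    cols = SEG_COLUMNS + [c for c in _SEG_OPTIONAL if c in out.columns]
    out = out[cols]
    out.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")


def read_seg(path) -> pd.DataFrame:
    """Read a SEG-style TSV back into the internal 0-based representation."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=[NA])
    _require_columns(df, SEG_COLUMNS, path)
    bad = np.where(df["end"].to_numpy() < df["start"].to_numpy())[0]
    if len(bad):
        raise ValidationError(f"{path}: line {bad[0] + 2}: end < start (1-based inclusive)")
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    _check_sorted_nonoverlapping(df, path)
    return df


def write_truth(truth, path) -> None:
    """Write a TruthProfile sidecar TSV (segments plus purity/ploidy header)."""
    with open(path, "w") as fh:
        fh.write(f"#purity\t{truth.purity:.6g}\n")
        fh.write(f"#tumor_ploidy\t{truth.tumor_ploidy:.9g}\n")
        fh.write(f"#wgd_applied\t{int(truth.wgd_applied)}\n")
        fh.write("chrom\tstart\tend\tnA\tnB\tclonal_fraction\n")
        for s in truth.segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.nA}\t{s.nB}\t{s.clonal_fraction:.6g}\n")


def read_truth(path):
    """Read the truth sidecar back into a TruthProfile."""
    from .simulate import Segment, TruthProfile

    meta = {}
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                meta[key] = val
            elif header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    segments = [
        Segment(r[0], int(r[1]), int(r[2]), int(r[3]), int(r[4]), float(r[5])) for r in rows
    ]
    return TruthProfile(
        segments=segments,
        purity=float(meta["purity"]),
        wgd_applied=bool(int(meta.get("wgd_applied", "0"))),
    )


def read_purity_matrix(path) -> pd.DataFrame:
    """Read a samples x methods purity matrix (first column ``sample``)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={"sample": str})
    if df.columns[0] != "sample":
        raise ValidationError(f"{path}: first column must be 'sample'")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample {dup!r}")
    df = df.set_index("sample")
    vals = df.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
        raise ValidationError(f"{path}: purity values outside [0, 1]")
    return df


def write_purity_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=NA, float_format="%.6g", index_label="sample")


def read_pathology(path) -> pd.DataFrame:
    """Read a multiobserver pathology table: sample, observer, section, range_lo, range_hi."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "observer": str, "section": str})
    _require_columns(df, ["sample", "observer", "section", "range_lo", "range_hi"], path)
    lo = df["range_lo"].to_numpy(dtype=float)
    hi = df["range_hi"].to_numpy(dtype=float)
    bad = np.where((lo < 0) | (hi > 1) | (lo > hi))[0]
    if len(bad):
        raise ValidationError(f"{path}: line {bad[0] + 2}: invalid purity range")
    return df


def read_analyte_map(path) -> dict[str, list[str]]:
    """Read an analyte -> method-list map from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: analyte map must be a mapping of analyte to method list")
    out = {}
    for analyte, methods in data.items():
        if not isinstance(methods, list):
            raise ValidationError(f"{path}: methods for {analyte!r} must be a list")
        out[str(analyte)] = [str(m) for m in methods]
    return out


def write_purity_call(call, path, sample: str = "sample") -> None:
    """Write a one-line purity-call TSV."""
    fields = [
        ("sample", sample),
        ("purity", NA if call.purity is None else f"{call.purity:.6g}"),
        ("ploidy", NA if call.ploidy is None else f"{call.ploidy:.6g}"),
        ("abstained", int(call.abstained)),
        ("reason", call.abstain_reason),
        ("score", f"{call.fit_score:.6g}"),
        ("score_gap", f"{call.runner_up_score_gap:.6g}"),
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(k for k, _ in fields) + "\n")
        fh.write("\t".join(str(v) for _, v in fields) + "\n")


def read_purity_call(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={"sample": str, "reason": str})
    return df.iloc[0]
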