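"""Per-site allele frequencies and sliding-window genome profiles.

The canonical windowing is a 1 Mb window advanced in 50 kb steps. A
chromosome of length L >= W carries floor((L - W) / s) + 1 windows (the last
partial window is dropped); shorter chromosomes get a single window covering
the whole chromosome. Window means are unweighted over the marker sites
inside [start, start + W); windows with fewer than ``min_markers`` informative
sites are reported as missing rather than zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    AlleleCountTable,
    GenomeLayout,
    ValidationError,
    VariantSet,
)

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 50_000
DEFAULT_MIN_MARKERS = 10


def window_starts(length: int, window: int = DEFAULT_WINDOW,
                  step: int = DEFAULT_STEP) -> tuple[np.ndarray, np.ndarray]:
    """Window (start, end) arrays for one chromosome, 0-based half-open."""
    if window <= 0 or step <= 0:
        raise ValidationError("window and step must be positive")
    if length >= window:
        n = (length - window) // step + 1
        starts = np.arange(n, dtype=np.int64) * step
        ends = starts + window
    else:
        starts = np.array([0], dtype=np.int64)
        ends = np.array([length], dtype=np.int64)
    return starts, ends


class WindowProfile:
    """Per-chromosome sliding-window summaries.

    Backed by a DataFrame with columns ``chrom, start, end, n_markers,
    mean_af, depth_sum, n_covered, mean_norm_cov, snp_density`` (absent
    metrics are simply missing columns). Missing values are NaN.
    """

    def __init__(self, df: pd.DataFrame, window: int, step: int,
                 min_markers: int = DEFAULT_MIN_MARKERS):
        self.df = df.reset_index(drop=True)
        self.window = int(window)
        self.step = int(step)
        self.min_markers = int(min_markers)

    def __len__(self) -> int:
        return len(self.df)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom].reset_index(drop=True)

    def genome_mean_af(self) -> float:
        """Unweighted mean of non-missing window allele frequencies."""
        vals = self.df["mean_af"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    def merge(self, other: "WindowProfile") -> "WindowProfile":
        """Join two profiles computed on the same windowing."""
        if (self.window, self.step) != (other.window, other.step):
            raise ValidationError("profiles use different windowings")
        keys = ["chrom", "start", "end"]
        extra = [c for c in other.df.columns if c not in self.df.columns]
        df = self.df.merge(other.df[keys + extra], on=keys, how="left")
        return WindowProfile(df, self.window, self.step, self.min_markers)

    def __repr__(self) -> str:
        return f"WindowProfile({len(self)} windows, W={self.window}, s={self.step})"


def site_af(counts: AlleleCountTable, min_depth: int = 1) -> pd.DataFrame:
    """Per-site allele frequency alt/(ref+alt), oriented so 0 is the
    reference-founder allele.

    Rows with depth below ``min_depth`` get NaN (missing), not zero. Returns
    sample, chrom, pos, depth, af.
    """
    df = counts.df.copy()
    depth = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, df["alt_count"] / np.maximum(depth, 1), np.nan)
    af = np.where(depth >= min_depth, af, np.nan)
    df["depth"] = depth
    df["af"] = af
    return df[["sample", "chrom", "pos", "depth", "af"]]


def _window_reduce(sites: pd.DataFrame, layout: GenomeLayout, window: int, step: int,
                   value_col: str | None) -> pd.DataFrame:
    """Count sites and sum a value per window via prefix sums.

    ``sites`` must have chrom/pos; rows with NaN in ``value_col`` count as
    sites with coverage for n_total but not for n_valid/value_sum.
    """
    frames = []
    for chrom, length in layout.chromosomes:
        sub = sites[sites["chrom"] == chrom].sort_values("pos", kind="mergesort")
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        starts, ends = window_starts(length, window, step)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        out = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                            "n_total": hi - lo})
        if value_col is not None:
            vals = sub[value_col].to_numpy(dtype=float)
            valid = ~np.isnan(vals)
            cs_val = np.concatenate([[0.0], np.cumsum(np.where(valid, vals, 0.0))])
            cs_n = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
            out["value_sum"] = cs_val[hi] - cs_val[lo]
            out["n_valid"] = cs_n[hi] - cs_n[lo]
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def window_af(sites: pd.DataFrame, layout: GenomeLayout,
              window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
              min_markers: int = DEFAULT_MIN_MARKERS) -> WindowProfile:
    """Sliding-window mean allele frequency for one sample.

    ``sites`` is the output of :func:`site_af` (or any frame with chrom,
    pos, af). The window mean is the unweighted mean of non-missing site
    AFs; windows with fewer than ``min_markers`` such sites are missing.
    """
    red = _window_reduce(sites, layout, window, step, "af")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_af = np.where(red["n_valid"] >= max(min_markers, 1),
                           red["value_sum"] / np.maximum(red["n_valid"], 1), np.nan)
    df = red[["chrom", "start", "end"]].copy()
    df["n_markers"] = red["n_valid"]
    df["mean_af"] = mean_af
    return WindowProfile(df, window, step, min_markers)


def window_coverage(sites: pd.DataFrame, layout: GenomeLayout,
                    window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> WindowProfile:
    """Normalized read coverage per window, computed at marker sites.

    Per-window mean depth divided by the genome-wide median of window mean
    depths, so the genome-wide median of the output is 1. Empty windows are
    missing.
    """
    sites = sites.copy()
    if "depth" not in sites.columns:
        raise ValidationError("sites frame needs a 'depth' column")
    red = _window_reduce(sites, layout, window, step, "depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_depth = np.where(red["n_valid"] > 0,
                              red["value_sum"] / np.maximum(red["n_valid"], 1), np.nan)
    med = np.nanmedian(mean_depth) if np.isfinite(mean_depth).any() else np.nan
    if not np.isfinite(med) or med == 0:
        raise ValidationError("cannot normalize coverage: zero or undefined median depth")
    df = red[["chrom", "start", "end"]].copy()
    df["n_covered"] = red["n_valid"]
    df["mean_norm_cov"] = mean_depth / med
    return WindowProfile(df, window, step)


def window_snp_density(variants: VariantSet, layout: GenomeLayout,
                       window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
                       flag_threshold: float | None = None) -> WindowProfile:
    """SNP density per window (SNPs/Mb), used to flag wild-introgression
    candidate regions when a threshold is supplied."""
    sites = variants.df[["chrom", "pos"]].copy()
    red = _window_reduce(sites, layout, window, step, None)
    df = red[["chrom", "start", "end"]].copy()
    width = (df["end"] - df["start"]).to_numpy(dtype=float)
    df["snp_density"] = red["n_total"] * (1e6 / width)
    if flag_threshold is not None:
        df["introgression_flag"] = df["snp_density"] >= flag_threshold
    return WindowProfile(df, window, step)


def profile_sample(counts: AlleleCountTable, marker_positions: pd.DataFrame,
                   layout: GenomeLayout,
                   window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
                   min_markers: int = DEFAULT_MIN_MARKERS,
                   min_depth: int = 1) -> WindowProfile:
    """Joint AF + coverage profile for a single sample at marker sites.

    ``marker_positions`` (chrom, pos) restricts the count rows to diagnostic
    marker sites before windowing.
    """
    if len(counts.samples) != 1:
        raise ValidationError("profile_sample expects counts for exactly one sample")
    keyed = counts.df.merge(marker_positions[["chrom", "pos"]].drop_duplicates(),
                            on=["chrom", "pos"], how="inner")
    sub = AlleleCountTable(keyed)
    sites = site_af(sub, min_depth=min_depth)
    prof = window_af(sites, layout, window, step, min_markers)
    cov = window_coverage(sites, layout, window, step)
    return prof.merge(cov)
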