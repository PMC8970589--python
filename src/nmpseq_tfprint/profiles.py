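"""Metaprofiles around binding sites and TSSs, heatmaps, width estimates.

Aggregation pools raw lesion counts across features per motif-relative
position and only then forms the normalised ratio (ratio of pooled counts),
which is robust to per-site sparsity at single-nucleotide resolution; a
mean-of-per-feature-ratios variant is available for comparison. Windows
tile outward from the origin so position 0 always sits on a window
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import NormalizedProfile, ratio_of_counts, window_average
from .track import LesionTrack


@dataclass
class MetaProfile:
    """Feature-aligned average signal on a symmetric relative-position axis."""

    offsets: np.ndarray
    value: np.ndarray
    n: np.ndarray  # contributing feature count per offset/window
    masked: np.ndarray
    window: int = 1
    overlay: Optional[np.ndarray] = None  # e.g. scaled nucleosome density
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "relative_position": self.offsets,
                "value": self.value,
                "n": self.n,
                "masked": self.masked.astype(int),
            }
        )
        if self.overlay is not None:
            df["overlay"] = self.overlay
        return df

    def at(self, offset: int) -> float:
        idx = np.where(self.offsets == offset)[0]
        if len(idx) == 0:
            raise KeyError(f"offset {offset} not on profile axis")
        return float(self.value[idx[0]])


def _features_frame(features: pd.DataFrame) -> pd.DataFrame:
    """Normalise site or gene tables to (chrom, origin, strand)."""
    if "midpoint" in features.columns:
        origin = features["midpoint"]
    elif "tss" in features.columns:
        origin = features["tss"]
    else:
        raise ValueError("features need a 'midpoint' or 'tss' column")
    return pd.DataFrame(
        {
            "chrom": features["chrom"],
            "origin": origin.astype(int),
            "strand": features["strand"],
        }
    )


def pooled_counts(
    track: LesionTrack, features: pd.DataFrame, flank: int = 500
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum strand-combined counts across features per oriented offset.

    Returns ``(offsets, pooled, n_features)`` with offsets -flank..flank;
    positions outside a chromosome contribute nothing and reduce the
    feature count at that offset.
    """
    feats = _features_frame(features)
    offsets = np.arange(-flank, flank + 1)
    pooled = np.zeros(len(offsets), dtype=np.int64)
    nfeat = np.zeros(len(offsets), dtype=np.int64)
    for feat in feats.itertuples():
        counts = track.counts[feat.chrom].sum(axis=0)
        L = len(counts)
        sign = 1 if feat.strand == "+" else -1
        pos = feat.origin + sign * offsets
        ok = (pos >= 0) & (pos < L)
        pooled[ok] += counts[pos[ok]]
        nfeat[ok] += 1
    return offsets, pooled, nfeat


def aggregate_values(
    values: Mapping[str, np.ndarray], features: pd.DataFrame, flank: int = 500
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean of a per-position value track across oriented features.

    ``values`` maps chrom -> (L,) float array; NaNs are treated as missing.
    Returns ``(offsets, mean, n_contributing)``.
    """
    feats = _features_frame(features)
    offsets = np.arange(-flank, flank + 1)
    total = np.zeros(len(offsets), dtype=float)
    nfeat = np.zeros(len(offsets), dtype=np.int64)
    for feat in feats.itertuples():
        arr = np.asarray(values[feat.chrom], dtype=float)
        L = len(arr)
        sign = 1 if feat.strand == "+" else -1
        pos = feat.origin + sign * offsets
        ok = (pos >= 0) & (pos < L)
        vals = np.full(len(offsets), np.nan)
        vals[ok] = arr[pos[ok]]
        use = np.isfinite(vals)
        total[use] += vals[use]
        nfeat += use
    with np.errstate(invalid="ignore"):
        mean = np.where(nfeat > 0, total / np.maximum(nfeat, 1), np.nan)
    return offsets, mean, nfeat


def _finalize(
    offsets: np.ndarray,
    values: np.ndarray,
    masked: np.ndarray,
    nfeat: np.ndarray,
    window: int,
    meta: dict,
    overlay: Optional[np.ndarray] = None,
) -> MetaProfile:
    prof = NormalizedProfile(offsets, values, nfeat, masked)
    prof = window_average(prof, window)
    out = MetaProfile(
        offsets=prof.positions,
        value=prof.value,
        n=prof.n,
        masked=prof.masked,
        window=window,
        meta=meta,
    )
    if overlay is not None:
        oprof = window_average(
            NormalizedProfile(offsets, overlay, nfeat, ~np.isfinite(overlay)), window
        )
        out.overlay = oprof.value
    return out


def site_metaprofile(
    numerator: LesionTrack,
    denominator: LesionTrack,
    sites: pd.DataFrame,
    flank: int = 500,
    window: int = 5,
    kind: str = "ratio",
    min_den: int = 1,
    spike: Optional[float] = None,
    method: str = "pooled",
) -> MetaProfile:
    """Normalised metaprofile around oriented binding-site midpoints.

    ``kind="ratio"`` gives the damage-formation profile (numerator =
    cellular, denominator = naked DNA; libraries depth-scaled, mean over the
    plotted span rescaled to 1.0). ``kind="remaining"`` gives the fraction
    of remaining damage (numerator = time point, denominator = 0 hr; raw
    counts, optional spike factor). ``method="per_feature"`` averages
    per-site ratios instead of pooling counts first.
    """
    if kind not in ("ratio", "remaining"):
        raise ValueError("kind must be 'ratio' or 'remaining'")
    if sites.empty:
        raise ValueError("no sites supplied")
    if method == "pooled":
        offsets, num, nfeat = pooled_counts(numerator, sites, flank)
        _, den, _ = pooled_counts(denominator, sites, flank)
        values, masked = ratio_of_counts(
            num,
            den,
            min_den=min_den,
            num_total=max(num.sum(), 1) if kind == "ratio" else None,
            den_total=max(den.sum(), 1) if kind == "ratio" else None,
            rescale_mean_one=(kind == "ratio"),
            spike=spike,
        )
    elif method == "per_feature":
        mat_num = feature_offset_counts(numerator, sites, flank)
        mat_den = feature_offset_counts(denominator, sites, flank)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(mat_den >= min_den, mat_num / mat_den, np.nan)
        if spike is not None:
            ratios *= spike
        offsets = np.arange(-flank, flank + 1)
        nfeat = np.isfinite(ratios).sum(axis=0)
        with np.errstate(invalid="ignore"):
            values = np.nanmean(np.where(np.isfinite(ratios), ratios, np.nan), axis=0)
        masked = nfeat == 0
        if kind == "ratio":
            mean = np.nanmean(values)
            if np.isfinite(mean) and mean > 0:
                values = values / mean
    else:
        raise ValueError("method must be 'pooled' or 'per_feature'")
    if not (~masked).any():
        raise ValueError("no site overlaps usable signal")
    return _finalize(
        offsets, values, masked, nfeat, window,
        {"kind": kind, "flank": flank, "method": method, "n_features": len(sites)},
    )


def tss_metaprofile(
    numerator: LesionTrack,
    denominator: LesionTrack,
    genes: pd.DataFrame,
    flank: int = 500,
    window: int = 5,
    kind: str = "remaining",
    min_den: int = 1,
    spike: Optional[float] = None,
) -> MetaProfile:
    """As :func:`site_metaprofile` with the TSS as origin, oriented by gene
    strand (negative offsets = promoter/upstream)."""
    feats = genes.rename(columns={"tss": "tss"})
    return site_metaprofile(
        numerator,
        denominator,
        feats.assign(midpoint=feats["tss"]),
        flank=flank,
        window=window,
        kind=kind,
        min_den=min_den,
        spike=spike,
    )


def nucleosome_overlay(
    coverage: Mapping[str, np.ndarray],
    features: pd.DataFrame,
    flank: int = 500,
    window: int = 5,
) -> np.ndarray:
    """Feature-aligned nucleosome density, scaled to [0, 1] for plotting."""
    if not coverage or all(np.asarray(v).sum() == 0 for v in coverage.values()):
        raise ValueError("empty coverage track")
    offsets, mean, nfeat = aggregate_values(coverage, features, flank)
    prof = window_average(
        NormalizedProfile(offsets, mean, nfeat, ~np.isfinite(mean)), window
    )
    vals = prof.value
    top = np.nanmax(vals)
    if top > 0:
        vals = vals / top
    return vals


def feature_offset_counts(
    track: LesionTrack, features: pd.DataFrame, flank: int = 500
) -> np.ndarray:
    """(n_features, 2*flank+1) strand-summed counts, NaN outside the chromosome."""
    feats = _features_frame(features)
    offsets = np.arange(-flank, flank + 1)
    out = np.full((len(feats), len(offsets)), np.nan)
    for i, feat in enumerate(feats.itertuples()):
        counts = track.counts[feat.chrom].sum(axis=0)
        L = len(counts)
        sign = 1 if feat.strand == "+" else -1
        pos = feat.origin + sign * offsets
        ok = (pos >= 0) & (pos < L)
        out[i, ok] = counts[pos[ok]]
    return out


def gene_heatmap(
    track_t: LesionTrack,
    track_0: LesionTrack,
    links: pd.DataFrame,
    flank: int = 500,
    window: int = 5,
    min_initial: int = 1,
) -> pd.DataFrame:
    """Per-gene remaining-damage rows on the TSS-relative axis.

    One row per linked gene, window-averaged, ordered by the absolute
    site-to-TSS distance, longest first (so genes whose binding site sits
    far from the TSS appear at the top of the rendered heatmap). The row
    index is ``gene_id``; masked cells are NaN.
    """
    if links.empty:
        raise ValueError("empty link set")
    genes = links.rename(columns={"gene_strand": "strand"})
    feats = genes.assign(midpoint=genes["tss"])
    mat_t = feature_offset_counts(track_t, feats, flank)
    mat_0 = feature_offset_counts(track_0, feats, flank)
    offsets = np.arange(-flank, flank + 1)
    win_id = np.floor_divide(offsets, window)
    ids = np.unique(win_id)
    rows = np.full((len(feats), len(ids)), np.nan)
    for k, wid in enumerate(ids):
        cols = win_id == wid
        num = np.nansum(mat_t[:, cols], axis=1)
        den = np.nansum(mat_0[:, cols], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[:, k] = np.where(den >= min_initial, num / den, np.nan)
    df = pd.DataFrame(rows, index=genes["gene_id"], columns=ids * window)
    order = genes["distance"].abs().sort_values(ascending=False, kind="stable").index
    return df.loc[genes.loc[order, "gene_id"]]


@dataclass
class InhibitionWidth:
    """Extent of the repair-inhibited (or formation-suppressed) region."""

    left: int
    right: int
    width: int
    flagged: bool = False  # True when no position passed the threshold


def inhibition_width(
    profile: MetaProfile,
    baseline_span: Tuple[int, int] = (300, 500),
    threshold_frac: float = 0.2,
    kind: str = "peak",
) -> InhibitionWidth:
    """Width of the contiguous region around the origin beyond baseline.

    The baseline is the mean profile value over offsets whose magnitude
    lies in ``baseline_span``. For remaining-damage profiles
    (``kind="peak"``) the region is where value >= baseline *
    (1 + threshold_frac); for formation dips (``kind="dip"``) where value
    <= baseline * (1 - threshold_frac). The returned boundaries are the
    outermost offsets of the contiguous run containing the origin; a flat
    profile yields width 0, flagged.
    """
    lo, hi = baseline_span
    offs = np.asarray(profile.offsets)
    vals = np.asarray(profile.value, dtype=float)
    base_sel = (np.abs(offs) >= lo) & (np.abs(offs) <= hi) & ~profile.masked
    if not base_sel.any():
        raise ValueError("baseline span does not overlap the profile")
    baseline = float(np.mean(vals[base_sel]))
    if kind == "peak":
        passing = vals >= baseline * (1 + threshold_frac)
    elif kind == "dip":
        passing = vals <= baseline * (1 - threshold_frac)
    else:
        raise ValueError("kind must be 'peak' or 'dip'")
    passing &= ~profile.masked

    # window (or position) containing offset 0
    inside = (offs <= 0) & (0 < offs + profile.window)
    idx0_candidates = np.where(inside)[0]
    if len(idx0_candidates) == 0:
        idx0_candidates = [int(np.argmin(np.abs(offs)))]
    i0 = int(idx0_candidates[0])
    if not passing[i0]:
        return InhibitionWidth(0, 0, 0, flagged=True)
    li = i0
    while li - 1 >= 0 and passing[li - 1]:
        li -= 1
    ri = i0
    while ri + 1 < len(offs) and passing[ri + 1]:
        ri += 1
    left = int(offs[li])
    right = int(offs[ri]) + profile.window - 1
    return InhibitionWidth(left, right, right - left, flagged=False)


def window_significance(
    values_a: np.ndarray,
    values_b: np.ndarray,
    offsets: Optional[np.ndarray] = None,
    window: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window two-sample t-tests with Benjamini-Hochberg correction.

    ``values_a`` / ``values_b`` are (features x positions) matrices of
    feature-level values for two conditions (NaN = missing). Positions are
    tiled into non-overlapping windows anchored at offset 0; per window the
    feature means are compared by Welch's t-test and p-values adjusted for
    the number of windows.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    npos = values_a.shape[1]
    if offsets is None:
        offsets = np.arange(npos)
    offsets = np.asarray(offsets)
    win_id = np.floor_divide(offsets, window)
    ids = np.unique(win_id)
    rows = []
    for wid in ids:
        cols = win_id == wid
        a = np.nanmean(values_a[:, cols], axis=1)
        b = np.nanmean(values_b[:, cols], axis=1)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("insufficient observations in a window")
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.allclose(
            a.mean(), b.mean()
        ):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "window_start": int(wid) * window,
                "statistic": float(stat),
                "p": float(p),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    df["significant"] = df["p_adj"] < alpha
    return df
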