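"""Damage-formation ratios, remaining-damage fractions, windows, replicates.

Two normalisations drive the whole analysis. The formation ratio divides
cellular lesion counts by a naked-DNA control to cancel sequence-intrinsic
damage propensity, then rescales so the mean over the analysis region is
exactly 1.0. The remaining fraction divides counts at a repair time point
by the initial (0 hr) counts; values near 1 mean unrepaired DNA. Both mask
positions whose denominator is too sparse rather than smoothing, and both
can be averaged in non-overlapping windows (5 bp by default) tiled outward
from the feature-relative origin.

Depth handling for the remaining fraction: by default counts are used raw,
which is exact whenever library read counts are proportional to surviving
lesions (true of the simulator's per-lesion read emission, and of real
libraries prepared and sequenced identically). When a spike-in factor (the
ratio of spike lesion reads, 0 hr over time t) is supplied, each library is
first scaled to its own total and the fraction multiplied by the spike
factor, which restores the absolute repair scale from the spike; a plain
total-count rescaling is available via ``scale="total"`` but erases the
genome-wide repair signal and is intended only for shape comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .track import LesionTrack

Region = Tuple[str, int, int]  # chrom, start, end (0-based half-open)


@dataclass
class NormalizedProfile:
    """Per-position (or per-window) dimensionless signal with masking.

    ``positions`` are feature-relative or genomic coordinates; ``value`` the
    ratio; ``n`` the number of underlying positions contributing; ``masked``
    flags positions with no usable value (value is NaN there). ``window`` is
    the averaging width in bp (1 = single-nucleotide).
    """

    positions: np.ndarray
    value: np.ndarray
    n: np.ndarray
    masked: np.ndarray
    window: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.value = np.asarray(self.value, dtype=float)
        self.n = np.asarray(self.n)
        self.masked = np.asarray(self.masked, dtype=bool)

    @property
    def exceeds_one(self) -> np.ndarray:
        """Unmasked values above 1 (noise flag for remaining fractions)."""
        return (~self.masked) & (self.value > 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_position": self.positions,
                "value": self.value,
                "n": self.n,
                "masked": self.masked.astype(int),
            }
        )


def _region_counts(track: LesionTrack, regions: Optional[Sequence[Region]]):
    """Concatenated strand-summed counts over the region set (whole genome if None)."""
    if regions is None:
        regions = [(c, 0, track.chrom_length(c)) for c in track.chroms]
    pos_list: List[np.ndarray] = []
    cnt_list: List[np.ndarray] = []
    labels: List[Tuple[str, int]] = []
    for chrom, start, end in regions:
        if end <= start:
            raise ValueError("empty region")
        counts = track.counts[chrom][:, start:end].sum(axis=0)
        cnt_list.append(counts)
        pos_list.append(np.arange(start, end))
        labels.append((chrom, start))
    return regions, np.concatenate(pos_list), np.concatenate(cnt_list)


def ratio_of_counts(
    num: np.ndarray,
    den: np.ndarray,
    min_den: int = 1,
    num_total: Optional[float] = None,
    den_total: Optional[float] = None,
    rescale_mean_one: bool = True,
    spike: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Masked, optionally depth-scaled and mean-one rescaled count ratio.

    Core primitive shared by position-wise and pooled-metaprofile paths.
    Returns ``(values, masked)``; masked entries are NaN.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    masked = den < min_den
    values = np.full(num.shape, np.nan)
    nt = 1.0 if num_total is None else float(num_total)
    dt = 1.0 if den_total is None else float(den_total)
    if nt <= 0 or dt <= 0:
        raise ValueError("library totals must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        values[~masked] = (num[~masked] / nt) / (den[~masked] / dt)
    if spike is not None:
        if spike <= 0:
            raise ValueError("spike factor must be positive")
        values *= spike
    if rescale_mean_one:
        mean = np.nanmean(values) if (~masked).any() else np.nan
        if np.isfinite(mean) and mean > 0:
            values /= mean
    return values, masked


def damage_ratio(
    cellular: LesionTrack,
    naked: LesionTrack,
    regions: Optional[Sequence[Region]] = None,
    min_naked: int = 1,
) -> NormalizedProfile:
    """Naked-DNA-normalised damage-formation profile, scaled to mean 1.0.

    Per position the cellular and naked counts (strands summed) are divided
    after scaling each library by its total within the region set; positions
    with fewer than ``min_naked`` naked counts are masked; the unmasked mean
    over the region set is rescaled to exactly 1.0.
    """
    if min_naked < 1:
        raise ValueError("min_naked must be >= 1")
    regions, pos_c, cnum = _region_counts(cellular, regions)
    _, _, cden = _region_counts(naked, regions)
    values, masked = ratio_of_counts(
        cnum,
        cden,
        min_den=min_naked,
        num_total=max(cnum.sum(), 1),
        den_total=max(cden.sum(), 1),
        rescale_mean_one=True,
    )
    return NormalizedProfile(
        positions=pos_c,
        value=values,
        n=(~masked).astype(int),
        masked=masked,
        meta={"kind": "formation", "min_naked": min_naked},
    )


def remaining_fraction(
    track_t: LesionTrack,
    track_0: LesionTrack,
    spike: Optional[float] = None,
    regions: Optional[Sequence[Region]] = None,
    min_initial: int = 1,
    scale: str = "none",
) -> NormalizedProfile:
    """Fraction of remaining damage: time-point counts over 0 hr counts.

    ``spike`` is the spike-in lesion-read ratio (0 hr over t); when given,
    both libraries are scaled to their totals and the ratio multiplied by
    the spike factor. Values above 1 are reported as-is (see
    ``NormalizedProfile.exceeds_one``), never clipped.
    """
    if scale not in ("none", "total"):
        raise ValueError("scale must be 'none' or 'total'")
    regions, pos, cnum = _region_counts(track_t, regions)
    _, _, cden = _region_counts(track_0, regions)
    if cden.sum() == 0:
        raise ValueError("no initial (0 hr) signal in the analysis region")
    use_totals = spike is not None or scale == "total"
    values, masked = ratio_of_counts(
        cnum,
        cden,
        min_den=min_initial,
        num_total=max(cnum.sum(), 1) if use_totals else None,
        den_total=max(cden.sum(), 1) if use_totals else None,
        rescale_mean_one=False,
        spike=spike,
    )
    return NormalizedProfile(
        positions=pos,
        value=values,
        n=(~masked).astype(int),
        masked=masked,
        meta={"kind": "remaining", "spike": spike, "scale": scale},
    )


def window_average(profile: NormalizedProfile, w: int = 5) -> NormalizedProfile:
    """Non-overlapping window means anchored at the profile origin.

    Windows tile outward from position 0 (offsets 0..w-1, then w..2w-1,
    mirrored on the negative side), so the origin always sits on a window
    boundary. Each window's value is the mean of its unmasked member
    positions; all-masked windows stay masked. ``w=1`` is the identity.
    """
    if w <= 0:
        raise ValueError("window width must be >= 1")
    if w == 1:
        return profile
    pos = np.asarray(profile.positions, dtype=np.int64)
    win_id = np.floor_divide(pos, w)
    order = np.argsort(win_id, kind="stable")
    ids, starts = np.unique(win_id[order], return_index=True)
    out_pos, out_val, out_n, out_mask = [], [], [], []
    bounds = np.append(starts, len(pos))
    for k, wid in enumerate(ids):
        idx = order[bounds[k] : bounds[k + 1]]
        vals = profile.value[idx]
        msk = profile.masked[idx]
        out_pos.append(wid * w)
        if (~msk).any():
            out_val.append(float(np.mean(vals[~msk])))
            out_n.append(int(np.sum(profile.n[idx][~msk])))
            out_mask.append(False)
        else:
            out_val.append(np.nan)
            out_n.append(0)
            out_mask.append(True)
    return NormalizedProfile(
        positions=np.array(out_pos),
        value=np.array(out_val),
        n=np.array(out_n),
        masked=np.array(out_mask),
        window=w,
        meta=dict(profile.meta),
    )


def replicate_correlation(
    track_a: LesionTrack, track_b: LesionTrack, bin: int = 50
) -> float:
    """Pearson r between depth-normalised binned counts of two replicates.

    Counts are summed over strands, binned into ``bin``-bp tiles, each
    library divided by its total, and r computed over jointly nonzero bins.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if set(track_a.chroms) != set(track_b.chroms):
        raise ValueError("replicates must share a genome")
    va, vb = [], []
    for chrom in track_a.chroms:
        ca = track_a.counts[chrom].sum(axis=0)
        cb = track_b.counts[chrom].sum(axis=0)
        nbin = len(ca) // bin
        if nbin == 0:
            continue
        va.append(ca[: nbin * bin].reshape(nbin, bin).sum(axis=1))
        vb.append(cb[: nbin * bin].reshape(nbin, bin).sum(axis=1))
    if not va:
        raise ValueError("fewer than 2 usable bins")
    a = np.concatenate(va).astype(float)
    b = np.concatenate(vb).astype(float)
    joint = (a > 0) & (b > 0)
    if joint.sum() < 2:
        raise ValueError("fewer than 2 usable bins")
    a = a[joint] / a[joint].sum()
    b = b[joint] / b[joint].sum()
    return float(stats.pearsonr(a, b)[0])
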