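"""TF binding-site filtering, orientation, stratification, TSS linkage.

Binding-site tables are plain DataFrames (chrom, start, end, strand,
occupancy, ...); genes are single-TSS tables (gene_id, chrom, tss, strand).
Sites are retained only if their interval carries the canonical motif
(IUPAC match on either strand), oriented by the match strand, and split
into high/low occupancy classes. Target genes are assigned by nearest-TSS
search within a distance cutoff, with both genes linked at divergent
promoters.
"""

from __future__ import annotations

import re
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .simulate import IUPAC_CODES
from .track import complement, revcomp

SITE_COLUMNS = ["chrom", "start", "end", "midpoint", "strand", "occupancy", "motif_seq"]

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(motif: str) -> str:
    """Reverse complement honouring degenerate IUPAC codes (R<->Y, K<->M, ...)."""
    return motif.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    """Compiled regex equivalent of an IUPAC motif (uppercase DNA)."""
    parts = []
    for letter in motif.upper():
        try:
            allowed = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r}") from None
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile("".join(parts))


def motif_midpoint(start: int, end: int, strand: str) -> int:
    """Genomic coordinate of the left-of-center motif column on the motif strand."""
    m = (end - start - 1) // 2
    return start + m if strand == "+" else (end - 1) - m


def filter_by_motif(
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    motif: str,
    slop: int = 0,
) -> pd.DataFrame:
    """Retain sites whose interval matches the motif on either strand.

    The sequence searched is the site interval widened by ``slop`` bases on
    each side. A forward-strand match is preferred; otherwise the reverse
    complement is tried. Among multiple hits the one whose midpoint lies
    closest to the reported interval midpoint wins. Matched sites are
    re-coordinated to the motif hit (start/end/midpoint/strand/motif_seq);
    non-matching sites are excluded.
    """
    fwd = iupac_regex(motif)
    rev = iupac_regex(iupac_revcomp(motif))
    mlen = len(motif)
    rows = []
    for site in sites.itertuples():
        seq_full = genome[site.chrom].upper()
        lo = max(0, int(site.start) - slop)
        hi = min(len(seq_full), int(site.end) + slop)
        segment = seq_full[lo:hi]
        center = (int(site.start) + int(site.end) - 1) / 2
        hits = []  # (distance to reported center, preference, start, strand)
        for pref, pat in ((0, fwd), (1, rev)):
            for m in pat.finditer(segment):
                start = lo + m.start()
                mid = start + (mlen - 1) / 2
                hits.append((abs(mid - center), pref, start, "+" if pref == 0 else "-"))
        if not hits:
            continue
        _, _, start, strand = min(hits)
        end = start + mlen
        matched = seq_full[start:end]
        rows.append(
            {
                "chrom": site.chrom,
                "start": start,
                "end": end,
                "midpoint": motif_midpoint(start, end, strand),
                "strand": strand,
                "occupancy": getattr(site, "occupancy", np.nan),
                "motif_seq": matched if strand == "+" else revcomp(matched),
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def stratify_occupancy(
    sites: pd.DataFrame, threshold: float = 10.0, low_inclusive: bool = True
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Exact partition into high- and low-occupancy site sets.

    High is occupancy strictly above the threshold; the boundary value
    itself is low-occupancy (set ``low_inclusive=False`` to move it to the
    high class).
    """
    if sites["occupancy"].isna().any():
        raise ValueError("occupancy missing on some sites")
    if low_inclusive:
        high_mask = sites["occupancy"] > threshold
    else:
        high_mask = sites["occupancy"] >= threshold
    return (
        sites[high_mask].reset_index(drop=True),
        sites[~high_mask].reset_index(drop=True),
    )


def link_to_tss(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 300,
) -> pd.DataFrame:
    """Link each site to its nearest gene TSS within ``max_dist`` bp.

    For every site the closest TSS on the same chromosome is linked if
    within the cutoff. When the site sits between two divergently
    transcribed genes (left neighbour on ``-`` pointing away leftward,
    right neighbour on ``+`` pointing away rightward) and both TSSs are in
    range, both genes are linked; exact distance ties are also both kept.
    Each gene is retained once (its nearest site). The signed distance is
    TSS minus site midpoint in gene orientation.
    """
    if genes.empty:
        raise ValueError("empty gene set")
    if genes["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    links = []

    def signed_distance(tss: int, mid: int, strand: str) -> int:
        d = int(tss) - int(mid)
        return d if strand == "+" else -d

    for si, site in enumerate(sites.itertuples()):
        sub = genes[genes["chrom"] == site.chrom]
        if sub.empty:
            continue
        mid = int(site.midpoint)
        dist = (sub["tss"] - mid).abs()
        nearest = dist.min()
        chosen = set(sub.index[dist == nearest])  # equidistant ties: keep both
        # divergent-promoter rule: nearest flanking TSSs pointing away
        left = sub[sub["tss"] <= mid]
        right = sub[sub["tss"] >= mid]
        if not left.empty and not right.empty:
            li = (left["tss"] - mid).abs().idxmin()
            ri = (right["tss"] - mid).abs().idxmin()
            if (
                li != ri
                and left.loc[li, "strand"] == "-"
                and right.loc[ri, "strand"] == "+"
                and abs(int(left.loc[li, "tss"]) - mid) <= max_dist
                and abs(int(right.loc[ri, "tss"]) - mid) <= max_dist
            ):
                chosen.update([li, ri])
        for gi in chosen:
            gene = genes.loc[gi]
            if abs(int(gene["tss"]) - mid) > max_dist:
                continue
            links.append(
                {
                    "site_index": si,
                    "gene_id": gene["gene_id"],
                    "chrom": site.chrom,
                    "site_midpoint": mid,
                    "tss": int(gene["tss"]),
                    "gene_strand": gene["strand"],
                    "distance": signed_distance(gene["tss"], mid, gene["strand"]),
                }
            )
    out = pd.DataFrame(
        links,
        columns=[
            "site_index", "gene_id", "chrom", "site_midpoint",
            "tss", "gene_strand", "distance",
        ],
    )
    if out.empty:
        return out
    # one entry per target gene: keep the closest site
    out["absdist"] = out["distance"].abs()
    out = (
        out.sort_values(["gene_id", "absdist", "site_index"])
        .drop_duplicates("gene_id", keep="first")
        .drop(columns="absdist")
        .reset_index(drop=True)
    )
    return out


def orient_relative(
    position, site, origin_shift: int = 0
):
    """Motif-relative signed offset(s) of genomic position(s) at a site.

    The offset is (position - midpoint), sign-flipped for ``-`` strand sites
    so profiles always read 5'->3' along the motif strand. ``origin_shift``
    relocates position 0 (e.g. onto the first G of GGGTAA for Reb1-style
    numbering on the GGGTAA-bearing strand).
    """
    position = np.asarray(position)
    strand = site["strand"] if isinstance(site, (dict, pd.Series)) else site.strand
    mid = site["midpoint"] if isinstance(site, (dict, pd.Series)) else site.midpoint
    sign = 1 if strand == "+" else -1
    return sign * (position - int(mid)) - origin_shift


def invert_orient(offset, site, origin_shift: int = 0):
    """Inverse of :func:`orient_relative`: offset back to genomic coordinate."""
    offset = np.asarray(offset)
    strand = site["strand"] if isinstance(site, (dict, pd.Series)) else site.strand
    mid = site["midpoint"] if isinstance(site, (dict, pd.Series)) else site.midpoint
    sign = 1 if strand == "+" else -1
    return int(mid) + sign * (offset + origin_shift)


def non_lesion_positions(motif: str, base: str = "G") -> Dict[int, bool]:
    """Motif columns that can never host a lesion of the given base class.

    A base-``G`` lesion occurs wherever either strand reads G, i.e. at G or
    C genome positions; a motif column whose IUPAC letter allows only bases
    from the complementary-exclusive pair (A/T for G lesions, G/C for A
    lesions) is marked True (mask it, and asterisk it in single-nucleotide
    plots).
    """
    base = base.upper()
    if base not in "ACGT":
        raise ValueError("base must be one of A, C, G, T")
    lesionable = {base, complement(base)}
    offsets = {}
    m = (len(motif) - 1) // 2
    for i, letter in enumerate(motif.upper()):
        allowed = set(IUPAC_CODES[letter])
        offsets[i - m] = allowed.isdisjoint(lesionable)
    return offsets
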