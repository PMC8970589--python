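"""Single-nucleotide lesion calling from aligned-read 5' ends.

The damage-mapping chemistry ligates an adaptor at the cleaved lesion site,
so the sequenced read starts one nucleotide downstream of the lesion on the
opposing strand: for a ``+`` strand read whose 5' end maps at x the lesion
sits at x-1 on the ``-`` strand, and for a ``-`` strand read at y it sits
at y+1 on the ``+`` strand. In ``cpd`` mode the two upstream nucleotides on
the opposing strand form the putative dipyrimidine lesion, keyed by its
5'-most base on the lesion strand.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .track import LesionTrack, complement_bytes

NMP_CLASSES = ("A", "C", "G", "T")
DIPYRIMIDINES = frozenset({"TT", "TC", "CT", "CC"})


def infer_lesions(
    reads: pd.DataFrame,
    genome: Mapping[str, str],
    mode: str = "nmp",
) -> LesionTrack:
    """Map read 5' ends to lesion positions, strands and base identities.

    Parameters
    ----------
    reads
        DataFrame with columns ``chrom``, ``five_prime_pos`` (0-based
        coordinate of the 5'-most aligned base) and ``strand``.
    genome
        chrom -> sequence mapping covering every read chromosome.
    mode
        ``"nmp"`` (single-base lesion) or ``"cpd"`` (dinucleotide lesion).

    Reads whose upstream position(s) fall outside the chromosome are dropped
    and tallied on ``track.dropped``, so that total counts plus drops equal
    the input read count.
    """
    if mode not in ("nmp", "cpd"):
        raise ValueError(f"unknown mode {mode!r}")
    track = LesionTrack(genome, mode=mode)
    unknown = set(reads["chrom"].unique()) - set(genome)
    if unknown:
        raise KeyError(f"reads reference unknown chromosome(s): {sorted(unknown)}")
    bad = set(reads["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"malformed strand value(s): {sorted(bad)}")

    for chrom, grp in reads.groupby("chrom", sort=False):
        L = len(genome[chrom])
        pos = grp["five_prime_pos"].to_numpy(dtype=np.int64)
        if ((pos < 0) | (pos >= L)).any():
            raise ValueError(f"read 5' end outside chromosome {chrom}")
        is_plus = (grp["strand"] == "+").to_numpy()

        # lesion coordinate: x-1 on '-' for + reads, y+1 on '+' for - reads
        lesion_pos = np.where(is_plus, pos - 1, pos + 1)
        lesion_idx = np.where(is_plus, 1, 0)  # strand row of the lesion
        if mode == "nmp":
            ok = (lesion_pos >= 0) & (lesion_pos < L)
        else:
            # the dinucleotide needs a second upstream base: x-2 for + reads,
            # y+2 for - reads, with the track keyed at the 5'-most lesion base
            second = np.where(is_plus, pos - 2, pos + 2)
            ok = (lesion_pos >= 0) & (lesion_pos < L) & (second >= 0) & (second < L)
        track.dropped += int((~ok).sum())
        track.add_at(chrom, lesion_pos[ok], lesion_idx[ok])
    return track


def base_composition(track: LesionTrack) -> Dict[str, float]:
    """Fraction of lesion-assigned reads per lesion base (nmp tracks).

    Raises ``ValueError`` on an empty track: no data to summarise.
    """
    if track.mode != "nmp":
        raise ValueError("base_composition is defined for nmp tracks")
    totals = {b: 0 for b in NMP_CLASSES}
    for chrom in track.chroms:
        bases = track.lesion_base_bytes(chrom)
        counts = track.counts[chrom]
        for b in NMP_CLASSES:
            totals[b] += int(counts[bases == ord(b)].sum())
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("empty lesion track")
    return {b: totals[b] / grand for b in NMP_CLASSES}


def select_class(
    track: LesionTrack, label: Union[str, Iterable[str]]
) -> LesionTrack:
    """Restrict a track to one lesion class, counts unchanged where retained.

    For nmp tracks ``label`` is a single base (``"G"`` keeps putative 7meG,
    ``"A"`` putative 3meA, ...). For cpd tracks it is a dinucleotide or a
    set of dinucleotides (e.g. the four dipyrimidines).
    """
    out = track.copy()
    out.dropped = 0
    if track.mode == "nmp":
        if not (isinstance(label, str) and label.upper() in NMP_CLASSES):
            raise ValueError(f"unknown nmp lesion class {label!r}")
        want = ord(label.upper())
        for chrom in out.chroms:
            bases = out.lesion_base_bytes(chrom)
            out.counts[chrom] = np.where(bases == want, out.counts[chrom], 0)
        return out

    labels = {label.upper()} if isinstance(label, str) else {l.upper() for l in label}
    for lab in labels:
        if len(lab) != 2 or any(c not in "ACGT" for c in lab):
            raise ValueError(f"unknown cpd lesion class {lab!r}")
    wanted = {tuple(lab.encode("ascii")) for lab in labels}
    for chrom in out.chroms:
        dinucs = out.lesion_dinuc_bytes(chrom)
        keep = np.zeros(dinucs.shape[:2], dtype=bool)
        for a, b in wanted:
            keep |= (dinucs[..., 0] == a) & (dinucs[..., 1] == b)
        out.counts[chrom] = np.where(keep, out.counts[chrom], 0)
    return out


def lesion_table(track: LesionTrack) -> pd.DataFrame:
    """Long-format nonzero lesion records (chrom, pos, strand, base/dinuc, count)."""
    rows = []
    for chrom in track.chroms:
        counts = track.counts[chrom]
        if track.mode == "nmp":
            bases = track.lesion_base_bytes(chrom)
        else:
            dinucs = track.lesion_dinuc_bytes(chrom)
        for si, strand in enumerate("+-"):
            nz = np.nonzero(counts[si])[0]
            for p in nz:
                label = (
                    chr(bases[si, p])
                    if track.mode == "nmp"
                    else bytes(dinucs[si, p]).decode("ascii")
                )
                rows.append((chrom, int(p), strand, label, int(counts[si, p])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "lesion", "count"])
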