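"""Strand-specific per-base lesion count tracks.

The :class:`LesionTrack` is the pipeline's central currency: for every
chromosome it holds an integer count matrix of shape ``(2, L)`` — row 0 the
``+`` strand, row 1 the ``-`` strand — alongside the reference sequence, so
that every counted position knows the identity of the damaged base on the
lesion strand (the reference base on ``+``, its complement on ``-``).

Coordinates are 0-based throughout; BED/bedGraph round-trips are handled in
:mod:`nmpseq_tfprint.io`.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping

import numpy as np

STRANDS = ("+", "-")
STRAND_INDEX = {"+": 0, "-": 1}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level complement lookup for vectorised work on b"ACGT" arrays
_COMP_BYTES = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_BYTES[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def seq_to_bytes(seq: str) -> np.ndarray:
    """Sequence as a uint8 array of ASCII codes (vector-friendly)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def complement_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP_BYTES[arr]


class LesionTrack:
    """Per-chromosome, per-strand, per-position lesion counts.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence string. The track keeps an
        upper-cased copy; counts are validated against its lengths.
    mode
        ``"nmp"`` for single-base N-methylpurine lesions, ``"cpd"`` for
        dinucleotide UV lesions (track keyed by the 5'-most base of the
        dinucleotide on the lesion strand).
    """

    def __init__(self, genome: Mapping[str, str], mode: str = "nmp"):
        if mode not in ("nmp", "cpd"):
            raise ValueError(f"unknown mode {mode!r}")
        self.genome: Dict[str, str] = {c: str(s).upper() for c, s in genome.items()}
        self.mode = mode
        self.counts: Dict[str, np.ndarray] = {
            c: np.zeros((2, len(s)), dtype=np.int64) for c, s in self.genome.items()
        }
        self.dropped = 0  # reads/lesions lost at chromosome edges

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        genome: Mapping[str, str],
        counts: Mapping[str, np.ndarray],
        mode: str = "nmp",
    ) -> "LesionTrack":
        track = cls(genome, mode=mode)
        for chrom, arr in counts.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.shape != track.counts[chrom].shape:
                raise ValueError(f"count shape mismatch on {chrom}")
            if (arr < 0).any():
                raise ValueError("lesion counts must be non-negative")
            track.counts[chrom] = arr.copy()
        return track

    def copy(self) -> "LesionTrack":
        new = LesionTrack(self.genome, mode=self.mode)
        new.counts = {c: a.copy() for c, a in self.counts.items()}
        new.dropped = self.dropped
        return new

    # -- basic queries -------------------------------------------------------
    @property
    def chroms(self) -> Iterable[str]:
        return self.genome.keys()

    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    def add_at(self, chrom: str, positions: np.ndarray, strand_idx: np.ndarray) -> None:
        """Accumulate one count per (position, strand index) pair."""
        np.add.at(self.counts[chrom], (strand_idx, positions), 1)

    def seq_bytes(self, chrom: str) -> np.ndarray:
        return seq_to_bytes(self.genome[chrom])

    def lesion_base_bytes(self, chrom: str) -> np.ndarray:
        """(2, L) array: base identity on the lesion strand at each position."""
        fwd = self.seq_bytes(chrom)
        return np.vstack([fwd, complement_bytes(fwd)])

    def lesion_dinuc_bytes(self, chrom: str) -> np.ndarray:
        """(2, L, 2) array of dinucleotides read 5'->3' on each strand.

        On ``+`` the dinucleotide keyed at p covers genome p, p+1; on ``-`` it
        covers p, p-1 (5'->3' on the minus strand runs leftward). Edge keys
        (last position on ``+``, first on ``-``) are zero-filled and never
        carry counts.
        """
        fwd = self.seq_bytes(chrom)
        rev = complement_bytes(fwd)
        L = len(fwd)
        out = np.zeros((2, L, 2), dtype=np.uint8)
        if L >= 2:
            out[0, : L - 1, 0] = fwd[: L - 1]
            out[0, : L - 1, 1] = fwd[1:]
            out[1, 1:, 0] = rev[1:]
            out[1, 1:, 1] = rev[:-1]
        return out

    # -- comparisons ---------------------------------------------------------
    def equals(self, other: "LesionTrack") -> bool:
        if set(self.chroms) != set(other.chroms) or self.mode != other.mode:
            return False
        return all(np.array_equal(self.counts[c], other.counts[c]) for c in self.chroms)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - thin alias
        if not isinstance(other, LesionTrack):
            return NotImplemented
        return self.equals(other)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LesionTrack mode={self.mode} chroms={len(self.counts)} "
            f"total={self.total()} dropped={self.dropped}>"
        )
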