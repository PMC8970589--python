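"""Plain-file interchange: FASTA, BED6(+1), bedGraph, TSV tables, manifests.

Every pipeline stage reads and writes ordinary text formats so any stage
can be run against externally produced inputs (aligned-read BED files,
reference FASTA, published binding-site and TSS tables) without code
changes. Coordinates follow the usual conventions: BED and bedGraph are
0-based half-open on disk, matching the package's internal coordinates.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .track import LesionTrack


# -- genome -----------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA into memory via the faidx index (created if absent)."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path))
    try:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    finally:
        fasta.close()


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# -- reads ------------------------------------------------------------------

def read_reads_bed(path, five_prime: bool = True) -> pd.DataFrame:
    """BED6 of aligned reads -> (chrom, five_prime_pos, strand).

    With ``five_prime=True`` (default) the 5' end is derived from the
    interval by strand (start for ``+``, end-1 for ``-``); BED files that
    already store single-base 5' ends work identically.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str},
        comment="#",
    )
    if five_prime:
        pos = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    else:
        pos = df["start"].to_numpy()
    return pd.DataFrame(
        {"chrom": df["chrom"], "five_prime_pos": pos.astype(np.int64), "strand": df["strand"]}
    )


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["five_prime_pos"],
            "end": reads["five_prime_pos"] + 1,
            "name": ".",
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def reads_from_bam(path) -> pd.DataFrame:
    """5' ends of mapped reads in a BAM/SAM file (requires an index for BAM)."""
    import pysam

    rows = {"chrom": [], "five_prime_pos": [], "strand": []}
    with pysam.AlignmentFile(str(path)) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows["chrom"].append(aln.reference_name)
            if aln.is_reverse:
                rows["five_prime_pos"].append(aln.reference_end - 1)
                rows["strand"].append("-")
            else:
                rows["five_prime_pos"].append(aln.reference_start)
                rows["strand"].append("+")
    return pd.DataFrame(rows)


# -- lesion tracks (strand-split bedGraph) ----------------------------------

def write_track_bedgraph(track: LesionTrack, prefix) -> Dict[str, Path]:
    """Write a lesion track as a plus/minus bedGraph pair (nonzero runs)."""
    paths = {}
    for si, label in ((0, "plus"), (1, "minus")):
        path = Path(f"{prefix}.{label}.bg")
        with open(path, "w") as fh:
            for chrom in track.chroms:
                counts = track.counts[chrom][si]
                nz = np.nonzero(counts)[0]
                if len(nz) == 0:
                    continue
                # merge adjacent equal-count positions into runs
                breaks = np.where(
                    (np.diff(nz) != 1) | (np.diff(counts[nz]) != 0)
                )[0]
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks, [len(nz) - 1]])
                for s, e in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{nz[s]}\t{nz[e] + 1}\t{counts[nz[s]]}\n"
                    )
        paths[label] = path
    return paths


def read_track_bedgraph(
    plus_path, minus_path, genome: Mapping[str, str], mode: str = "nmp"
) -> LesionTrack:
    track = LesionTrack(genome, mode=mode)
    for si, path in ((0, plus_path), (1, minus_path)):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str}, comment="#",
        )
        for row in df.itertuples():
            track.counts[row.chrom][si, row.start : row.end] += int(row.value)
    return track


def read_coverage_bedgraph(path, genome: Mapping[str, str]) -> Dict[str, np.ndarray]:
    """Unstranded coverage bedGraph -> chrom -> (L,) float array."""
    out = {c: np.zeros(len(s)) for c, s in genome.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str}, comment="#",
    )
    for row in df.itertuples():
        out[row.chrom][row.start : row.end] += float(row.value)
    return out


# -- sites / genes / links --------------------------------------------------

def read_sites_bed(path) -> pd.DataFrame:
    """BED6+1 site table: name unused, score unused, column 7 = occupancy."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str},
    )
    if df.shape[1] < 6:
        raise ValueError("site BED needs at least 6 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5],
            "occupancy": df[6].astype(float) if df.shape[1] > 6 else np.nan,
        }
    )
    from .sites import motif_midpoint

    out["midpoint"] = [
        motif_midpoint(s, e, st) for s, e, st in zip(out["start"], out["end"], out["strand"])
    ]
    return out


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["start"],
            "end": sites["end"],
            "name": sites.get("motif_seq", "."),
            "score": 0,
            "strand": sites["strand"],
            "occupancy": sites["occupancy"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# -- run manifest -----------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    config: dict,
    seed: int,
    outputs: Mapping[str, Path],
    counters: Optional[Mapping[str, int]] = None,
) -> dict:
    from . import __version__

    manifest = {
        "tool": "nmpseq-tfprint",
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "outputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in sorted(outputs.items())
        },
        "counters": dict(counters or {}),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
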