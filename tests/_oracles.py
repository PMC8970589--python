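"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the operation's definition, with no
shared code paths with the package (plain Python loops and string ops), so
agreement is a genuine cross-check.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def brute_revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq.upper()))


def brute_infer_nmp(reads, genome: Dict[str, str]):
    """Lesion calls per the rule: the single nucleotide immediately upstream
    of the read 5' end, on the opposing strand. Returns ({(chrom,pos,strand):
    count}, dropped)."""
    calls: Dict[Tuple[str, int, str], int] = {}
    dropped = 0
    for chrom, pos, strand in reads:
        L = len(genome[chrom])
        if strand == "+":
            lesion_pos, lesion_strand = pos - 1, "-"
        else:
            lesion_pos, lesion_strand = pos + 1, "+"
        if 0 <= lesion_pos < L:
            key = (chrom, lesion_pos, lesion_strand)
            calls[key] = calls.get(key, 0) + 1
        else:
            dropped += 1
    return calls, dropped


def brute_infer_cpd(reads, genome: Dict[str, str]):
    """Dinucleotide lesion calls: the two nucleotides immediately upstream of
    the 5' end on the opposing strand, keyed by the 5'-most lesion base."""
    calls: Dict[Tuple[str, int, str], int] = {}
    dropped = 0
    for chrom, pos, strand in reads:
        L = len(genome[chrom])
        if strand == "+":
            # upstream of a + read: pos-1 then pos-2; lesion on '-' strand,
            # whose 5'->3' runs right-to-left, so the 5'-most base is pos-1
            ok = pos - 2 >= 0
            key_pos, lesion_strand = pos - 1, "-"
        else:
            ok = pos + 2 <= L - 1
            key_pos, lesion_strand = pos + 1, "+"
        if ok:
            key = (chrom, key_pos, lesion_strand)
            calls[key] = calls.get(key, 0) + 1
        else:
            dropped += 1
    return calls, dropped


def brute_lesion_base(genome: Dict[str, str], chrom: str, pos: int, strand: str) -> str:
    base = genome[chrom][pos].upper()
    return base if strand == "+" else COMP[base]


def brute_lesion_dinuc(genome: Dict[str, str], chrom: str, pos: int, strand: str) -> str:
    seq = genome[chrom].upper()
    if strand == "+":
        return seq[pos : pos + 2]
    return COMP[seq[pos]] + COMP[seq[pos - 1]]


def brute_iupac_match(seq: str, motif: str) -> bool:
    seq = seq.upper()
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC_SETS[m.upper()] for b, m in zip(seq, motif))


def brute_motif_sites(genome: Dict[str, str], motif: str) -> List[Tuple[str, int, str]]:
    """All (chrom, start, strand) where the motif matches either strand."""
    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for start in range(len(seq) - len(motif) + 1):
            window = seq[start : start + len(motif)]
            if brute_iupac_match(window, motif):
                hits.append((chrom, start, "+"))
            if brute_iupac_match(brute_revcomp(window), motif):
                hits.append((chrom, start, "-"))
    return hits


def brute_link_to_tss(sites, genes, max_dist: int = 300):
    """Nearest-TSS linkage with equidistant ties and the divergent-promoter
    rule; one entry per gene (closest site). ``sites`` is a list of
    (chrom, midpoint); ``genes`` a list of (gene_id, chrom, tss, strand).
    Returns {gene_id: (site_index, signed_distance)}."""
    per_site = []
    for si, (chrom, mid) in enumerate(sites):
        cands = [(gi, g) for gi, g in enumerate(genes) if g[1] == chrom]
        if not cands:
            per_site.append(set())
            continue
        dists = [abs(g[2] - mid) for _, g in cands]
        dmin = min(dists)
        chosen = {cands[i][0] for i, d in enumerate(dists) if d == dmin}
        lefts = [(gi, g) for gi, g in cands if g[2] <= mid]
        rights = [(gi, g) for gi, g in cands if g[2] >= mid]
        if lefts and rights:
            lgi, lg = min(lefts, key=lambda t: abs(t[1][2] - mid))
            rgi, rg = min(rights, key=lambda t: abs(t[1][2] - mid))
            if (
                lgi != rgi
                and lg[3] == "-"
                and rg[3] == "+"
                and abs(lg[2] - mid) <= max_dist
                and abs(rg[2] - mid) <= max_dist
            ):
                chosen |= {lgi, rgi}
        per_site.append({gi for gi in chosen if abs(genes[gi][2] - mid) <= max_dist})

    result = {}
    for si, (chrom, mid) in enumerate(sites):
        for gi in per_site[si]:
            gene_id, _, tss, strand = genes[gi]
            d = tss - mid if strand == "+" else mid - tss
            prev = result.get(gene_id)
            if prev is None or abs(d) < abs(prev[1]) or (
                abs(d) == abs(prev[1]) and si < prev[0]
            ):
                result[gene_id] = (si, d)
    return result
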