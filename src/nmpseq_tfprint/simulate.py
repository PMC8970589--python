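"""Synthetic NMP-seq generator with planted ground truth.

Emulates the statistical structure of an alkylation damage-mapping
experiment in yeast-like sequence: base-dependent methylation rates
(7meG at G >> 3meA at A >> C/T), suppression of damage inside occupied
transcription-factor motifs with optional position-specific hotspots,
first-order repair whose rate is reduced inside bound motifs (plus flank)
and near nucleosome dyads, and read emission by the exact inverse of the
5'-end lesion-inference rule, so the full downstream pipeline can be tested
against planted parameters.

Every sampled quantity is driven by a :class:`numpy.random.Generator`
derived from the config seed; identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .track import STRAND_INDEX, LesionTrack, revcomp

IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: MMS methylation propensities per base per exposure. The ordering
#: G >> A >> C ~ T mirrors the dominance of 7meG over 3meA over minor
#: pyrimidine lesions; the absolute scale only sets relative read shares
#: because libraries are sampled to a target depth.
DEFAULT_BASE_DAMAGE_RATE: Dict[str, float] = {
    "G": 0.020, "A": 0.004, "C": 0.001, "T": 0.0005,
}


def _motif_offsets(motif: str) -> np.ndarray:
    """Motif-relative offsets of motif columns, origin at the left-of-center base."""
    m = (len(motif) - 1) // 2
    return np.arange(len(motif)) - m


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults: a 100 kb chromosome at yeast-like 38% GC carrying 600
    Abf1-style motifs (``CGTNNNNNRNKA``), half occupied (occupancy 20) and
    half weakly bound (occupancy 5, below the bound/unbound threshold of
    10); occupied motifs suppress damage to 0.3x across the motif columns;
    background repair 0.5/hr, reduced 10-fold inside occupied motifs +-15 bp
    and 2-fold within 20 bp of nucleosome dyads (165 bp lattice, excluded
    from an 80 bp half-width depletion window around each site); libraries
    of 1e6 expected reads at 0, 1, 2 hr.
    """

    genome_length: int = 100_000
    gc_content: float = 0.38
    n_sites: int = 600
    motif: str = "CGTNNNNNRNKA"
    occupancy_values: Optional[Sequence[float]] = None
    occupancy_high: float = 20.0
    occupancy_low: float = 5.0
    occupancy_threshold: float = 10.0
    base_damage_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_DAMAGE_RATE)
    )
    suppression_core: float = 0.3
    suppression_profile: Optional[Mapping[int, float]] = None
    hotspot_profile: Mapping[int, float] = field(default_factory=dict)
    repair_rate_background: float = 0.5
    repair_inhibition: float = 0.1
    repair_inhibition_flank: int = 15
    repair_inhibition_profile: Optional[Mapping[int, float]] = None
    nucleosome_spacing: int = 165
    nucleosome_dyad_inhibition: float = 0.5
    dyad_halfwidth: int = 20
    ndr_halfwidth: int = 80
    timepoints: Sequence[float] = (0.0, 1.0, 2.0)
    depth: float = 1_000_000.0
    min_gap: int = 30
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        for letter in self.motif.upper():
            if letter not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC letter {letter!r} in motif")
        for base, rate in self.base_damage_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"base_damage_rate[{base}] outside [0, 1]")
        for name, prof in (
            ("suppression_profile", self.effective_suppression_profile()),
            ("repair_inhibition_profile", self.effective_repair_profile()),
            ("hotspot_profile", dict(self.hotspot_profile)),
        ):
            for off, mult in prof.items():
                if not np.isfinite(mult) or mult < 0:
                    raise ValueError(f"{name}[{off}] must be finite and >= 0")
        for off, mult in self.effective_suppression_profile().items():
            if mult > 1:
                raise ValueError("suppression multipliers must lie in [0, 1]")
        if not 0.0 <= self.nucleosome_dyad_inhibition:
            raise ValueError("nucleosome_dyad_inhibition must be >= 0")
        if min(self.timepoints) < 0:
            raise ValueError("timepoints must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    # -- derived condition profiles -----------------------------------------
    def effective_suppression_profile(self) -> Dict[int, float]:
        """Occupied-site damage multipliers keyed by motif-relative offset."""
        if self.suppression_profile is not None:
            return dict(self.suppression_profile)
        return {int(o): self.suppression_core for o in _motif_offsets(self.motif)}

    def effective_repair_profile(self) -> Dict[int, float]:
        """Occupied-site repair multipliers, motif span widened by the flank."""
        if self.repair_inhibition_profile is not None:
            return dict(self.repair_inhibition_profile)
        offs = _motif_offsets(self.motif)
        lo = int(offs.min()) - self.repair_inhibition_flank
        hi = int(offs.max()) + self.repair_inhibition_flank
        return {o: self.repair_inhibition for o in range(lo, hi + 1)}

    def effective_occupancies(self) -> np.ndarray:
        if self.occupancy_values is not None:
            occ = np.asarray(self.occupancy_values, dtype=float)
            if len(occ) != self.n_sites:
                raise ValueError("occupancy_values length must equal n_sites")
            if (occ <= 0).any():
                raise ValueError("occupancies must be positive")
            return occ
        occ = np.full(self.n_sites, self.occupancy_low, dtype=float)
        occ[::2] = self.occupancy_high  # alternate bound / weakly bound
        return occ

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class SimTruth:
    """Planted ground truth recorded while simulating.

    ``p_cellular`` / ``p_naked`` are the exact per-position per-strand
    Poisson means used (depth-scaled); ``repair_rate`` the per-position
    first-order rate (1/hr, shared by both strands); ``sites`` the planted
    site table with the occupied flag; ``dyads`` nucleosome dyad coordinates.
    """

    p_cellular: Dict[str, np.ndarray]
    p_naked: Dict[str, np.ndarray]
    repair_rate: Dict[str, np.ndarray]
    sites: pd.DataFrame
    dyads: Dict[str, np.ndarray]
    config: SimConfig

    def survival(self, t: float) -> Dict[str, np.ndarray]:
        """Expected surviving fraction exp(-k t) per position."""
        return {c: np.exp(-k * t) for c, k in self.repair_rate.items()}


# ---------------------------------------------------------------------------
# genome and sites


def generate_genome(length: int, gc: float, seed: int) -> str:
    """Random i.i.d. sequence of ``length`` bases with expected GC fraction ``gc``."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return bases.tobytes().decode("ascii")


def _expand_motif(motif: str, rng: np.random.Generator) -> str:
    """One concrete realisation of an IUPAC motif, degenerate columns uniform."""
    return "".join(
        letter if len(IUPAC_CODES[letter]) == 1
        else IUPAC_CODES[letter][rng.integers(len(IUPAC_CODES[letter]))]
        for letter in motif.upper()
    )


def plant_sites(
    genome: str,
    motif: str,
    n: int,
    occupancies: Sequence[float],
    min_gap: int,
    seed: int,
    chrom: str = "chrSim",
    occupancy_threshold: float = 10.0,
) -> Tuple[str, pd.DataFrame]:
    """Write ``n`` concrete motif instances into the genome, random strand.

    Placements are non-overlapping with at least ``min_gap`` bases between
    motif intervals. The returned table records, per site: chrom, start, end
    (0-based half-open), genomic midpoint (the left-of-center motif column on
    the motif strand), motif strand, occupancy, the concrete motif-strand
    sequence, and the occupied flag (occupancy > threshold).
    """
    motif = motif.upper()
    if len(occupancies) != n:
        raise ValueError("occupancies length must equal n")
    mlen = len(motif)
    if n * (mlen + min_gap) > len(genome):
        raise ValueError("cannot place sites: genome too short for n and min_gap")
    rng = np.random.default_rng(seed)
    seq = list(genome.upper())
    taken = np.zeros(len(genome), dtype=bool)
    rows = []
    m = (mlen - 1) // 2
    for i in range(n):
        for _attempt in range(10_000):
            start = int(rng.integers(0, len(genome) - mlen + 1))
            lo = max(0, start - min_gap)
            hi = min(len(genome), start + mlen + min_gap)
            if not taken[lo:hi].any():
                break
        else:
            raise ValueError("cannot place sites respecting min_gap")
        taken[start : start + mlen] = True
        strand = "+" if rng.random() < 0.5 else "-"
        concrete = _expand_motif(motif, rng)
        placed = concrete if strand == "+" else revcomp(concrete)
        seq[start : start + mlen] = list(placed)
        midpoint = start + m if strand == "+" else start + (mlen - 1) - m
        occ = float(occupancies[i])
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + mlen,
                "midpoint": midpoint,
                "strand": strand,
                "occupancy": occ,
                "motif_seq": concrete,
                "occupied": occ > occupancy_threshold,
            }
        )
    sites = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "midpoint", "strand",
            "occupancy", "motif_seq", "occupied",
        ],
    )
    if n > 0:
        sites = sites.sort_values("start", ignore_index=True)
    return "".join(seq), sites


# ---------------------------------------------------------------------------
# damage and repair fields


def _base_rate_field(genome: str, rates: Mapping[str, float]) -> np.ndarray:
    """(2, L) per-strand damage propensity from the base under each strand."""
    from .track import complement_bytes, seq_to_bytes

    lut = np.zeros(256, dtype=float)
    for base, rate in rates.items():
        lut[ord(base.upper())] = rate
    fwd = seq_to_bytes(genome)
    return np.vstack([lut[fwd], lut[complement_bytes(fwd)]])


def _apply_site_profile(
    field_arr: np.ndarray,
    sites: pd.DataFrame,
    profile: Mapping[int, float],
    length: int,
    occupied_only: bool = True,
) -> None:
    """Multiply both strands of ``field_arr`` by site-relative multipliers in place."""
    if not profile:
        return
    offs = np.array(sorted(profile), dtype=int)
    mults = np.array([profile[int(o)] for o in offs], dtype=float)
    for site in sites.itertuples():
        if occupied_only and not site.occupied:
            continue
        sign = 1 if site.strand == "+" else -1
        pos = site.midpoint + sign * offs
        ok = (pos >= 0) & (pos < length)
        field_arr[:, pos[ok]] *= mults[ok]


def place_nucleosomes(config: SimConfig, sites: pd.DataFrame) -> np.ndarray:
    """Dyad coordinates on a regular lattice, cleared around site midpoints."""
    dyads = np.arange(
        config.nucleosome_spacing // 2, config.genome_length, config.nucleosome_spacing
    )
    if len(sites):
        mids = sites["midpoint"].to_numpy()
        near = np.abs(dyads[:, None] - mids[None, :]).min(axis=1) <= config.ndr_halfwidth
        dyads = dyads[~near]
    return dyads


def repair_rate_field(config: SimConfig, sites: pd.DataFrame, dyads: np.ndarray) -> np.ndarray:
    """(L,) first-order repair rate: background x motif inhibition x dyad inhibition."""
    k = np.full(config.genome_length, config.repair_rate_background, dtype=float)
    profile = config.effective_repair_profile()
    if profile and len(sites):
        offs = np.array(sorted(profile), dtype=int)
        mults = np.array([profile[int(o)] for o in offs], dtype=float)
        for site in sites.itertuples():
            if not site.occupied:
                continue
            sign = 1 if site.strand == "+" else -1
            pos = site.midpoint + sign * offs
            ok = (pos >= 0) & (pos < config.genome_length)
            k[pos[ok]] *= mults[ok]
    if config.nucleosome_dyad_inhibition != 1.0 and len(dyads):
        mask = np.zeros(config.genome_length, dtype=bool)
        for d in dyads:
            lo = max(0, d - config.dyad_halfwidth)
            hi = min(config.genome_length, d + config.dyad_halfwidth + 1)
            mask[lo:hi] = True
        k[mask] *= config.nucleosome_dyad_inhibition
    return k


def simulate_lesion_field(
    genome: str,
    sites: pd.DataFrame,
    config: SimConfig,
    seed: Optional[int] = None,
) -> Tuple[LesionTrack, LesionTrack, SimTruth]:
    """Sample cellular (t=0) and naked-DNA lesion tracks plus ground truth.

    Per position/strand the cellular Poisson mean is the base propensity
    times the occupied-site suppression and hotspot multipliers, scaled so
    that the library totals ``config.depth`` reads in expectation; the naked
    control uses the base propensity only.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    L = len(genome)
    if L != config.genome_length:
        config = replace(config, genome_length=L)
    chrom = config.chrom

    p_naked = _base_rate_field(genome, config.base_damage_rate)
    p_cell = p_naked.copy()
    _apply_site_profile(p_cell, sites, config.effective_suppression_profile(), L)
    _apply_site_profile(p_cell, sites, config.hotspot_profile, L)

    lam_cell = p_cell * (config.depth / p_cell.sum()) if p_cell.sum() > 0 else p_cell
    lam_naked = p_naked * (config.depth / p_naked.sum()) if p_naked.sum() > 0 else p_naked

    genome_map = {chrom: genome}
    cellular = LesionTrack.from_counts(genome_map, {chrom: rng.poisson(lam_cell)})
    naked = LesionTrack.from_counts(genome_map, {chrom: rng.poisson(lam_naked)})

    dyads = place_nucleosomes(config, sites)
    truth = SimTruth(
        p_cellular={chrom: lam_cell},
        p_naked={chrom: lam_naked},
        repair_rate={chrom: repair_rate_field(config, sites, dyads)},
        sites=sites,
        dyads={chrom: dyads},
        config=config,
    )
    return cellular, naked, truth


def simulate_repair_timepoint(
    lesions_t0: LesionTrack, truth: SimTruth, t: float, seed: int = 0
) -> LesionTrack:
    """Thin the t=0 lesions by first-order survival exp(-k t).

    Each lesion survives independently, so counts at ``t`` are binomial
    draws from the t=0 counts and never exceed them; ``t=0`` returns an
    identical track.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    rng = np.random.default_rng(seed)
    out = lesions_t0.copy()
    for chrom, counts in out.counts.items():
        surv = np.exp(-truth.repair_rate[chrom] * t)
        out.counts[chrom] = rng.binomial(counts, surv[None, :])
    return out


def simulate_time_course(
    lesions_t0: LesionTrack, truth: SimTruth, timepoints: Sequence[float], seed: int = 0
) -> Dict[float, LesionTrack]:
    """Sequentially thinned time course (per-position counts non-increasing)."""
    times = sorted(float(t) for t in timepoints)
    rng = np.random.default_rng(seed)
    out: Dict[float, LesionTrack] = {}
    prev_t, prev = 0.0, lesions_t0
    for t in times:
        if t == 0.0:
            out[t] = lesions_t0.copy()
            continue
        dt = t - prev_t
        cur = prev.copy()
        for chrom, counts in cur.counts.items():
            surv = np.exp(-truth.repair_rate[chrom] * dt)
            cur.counts[chrom] = rng.binomial(counts, surv[None, :])
        out[t] = cur
        prev_t, prev = t, cur
    return out


# ---------------------------------------------------------------------------
# read emission


def emit_reads(
    lesions: LesionTrack, seed: int = 0
) -> Tuple[pd.DataFrame, int]:
    """Emit one read per lesion, inverse of the 5'-end inference rule.

    A lesion at position p on the ``+`` strand yields a ``-`` strand read
    whose 5' end sits at p-1; a lesion at p on ``-`` yields a ``+`` strand
    read with 5' end at p+1 (so the base immediately upstream of each read's
    5' end, on the opposing strand, is the lesion). Lesions whose paired
    read start would fall outside the chromosome are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    frames = []
    dropped = 0
    for chrom in lesions.chroms:
        counts = lesions.counts[chrom]
        L = counts.shape[1]
        # + strand lesions -> '-' reads at p-1 (valid while p >= 1)
        plus = counts[0]
        dropped += int(plus[0]) if L else 0
        pos_p = np.repeat(np.arange(1, L), plus[1:])
        # - strand lesions -> '+' reads at p+1 (valid while p <= L-2)
        minus = counts[1]
        dropped += int(minus[L - 1]) if L else 0
        pos_m = np.repeat(np.arange(L - 1), minus[: L - 1])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "five_prime_pos": np.concatenate([pos_p - 1, pos_m + 1]),
                    "strand": np.concatenate(
                        [np.full(len(pos_p), "-"), np.full(len(pos_m), "+")]
                    ),
                }
            )
        )
    reads = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "five_prime_pos", "strand"]
    )
    if len(reads):
        reads = reads.iloc[rng.permutation(len(reads))].reset_index(drop=True)
    return reads, dropped


def simulate_experiment(config: SimConfig) -> dict:
    """Full synthetic experiment: genome, sites, fields, time course, reads.

    Returns a dict with keys ``genome``, ``sites``, ``cellular`` (t=0),
    ``naked``, ``truth``, ``timepoints`` (time -> LesionTrack), ``reads``
    (label -> (DataFrame, dropped)) where labels are ``naked`` and ``t<h>``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(4)]
    genome = generate_genome(config.genome_length, config.gc_content, seeds[0])
    genome, sites = plant_sites(
        genome,
        config.motif,
        config.n_sites,
        config.effective_occupancies(),
        config.min_gap,
        seeds[1],
        chrom=config.chrom,
        occupancy_threshold=config.occupancy_threshold,
    )
    cellular, naked, truth = simulate_lesion_field(genome, sites, config, seed=seeds[2])
    course = simulate_time_course(cellular, truth, config.timepoints, seed=seeds[3])
    reads = {"naked": emit_reads(naked, seed=seeds[3] ^ 1)}
    for t, track in course.items():
        reads[f"t{t:g}"] = emit_reads(track, seed=(seeds[3] ^ hash(t)) % (2**31))
    return {
        "genome": {config.chrom: genome},
        "sites": sites,
        "cellular": cellular,
        "naked": naked,
        "truth": truth,
        "timepoints": course,
        "reads": reads,
    }
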