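# Methods

## Lesion inference from read 5′ ends

Damage-mapping chemistry (AAG/APE1 cleavage at the lesion, adaptor
ligation, sequencing from the adaptor) places the read 5′ end one
nucleotide downstream of the lesion on the opposing strand. We therefore
call, for a `+` strand read with 5′ end at 0-based coordinate $x$, a lesion
at $x-1$ on the `-` strand; for a `-` strand read at $y$, a lesion at
$y+1$ on the `+` strand. "Immediately upstream" is read in the read's own
orientation; this convention is pinned operationally by the round-trip
contract with the simulator's read emitter, which is its exact inverse.
The lesion base is the reference base on the lesion strand (complement of
the top strand for `-` lesions): G-class counts are putative 7meG, A-class
putative 3meA. CPD mode takes the two upstream nucleotides instead and
keys the dinucleotide by its 5′-most base on the lesion strand. Reads
whose upstream position leaves the chromosome are dropped and counted, so
retained counts plus drops always equal the input reads. Coordinates are
0-based half-open internally and in BED/bedGraph files. Duplicate reads
are retained: lesion abundance is the signal, and no deduplication is part
of the assay definition.

## Normalisation

**Formation.** Cellular counts are divided position-wise by naked-DNA
counts after scaling each library by its total within the analysis region,
and the profile is rescaled so its unmasked mean is exactly 1.0 (checked
to 1e−9). Positions with fewer than `min_naked` (default 1) naked counts
are masked rather than smoothed — we use no pseudocount, so ratio bias is
controlled by masking alone, and raising `min_naked` can only mask more.
The mean-one region is the full plotted span (feature midpoint ±500 bp
pooled over features), matching the plotted flank extent.

**Repair.** The remaining fraction is count at time $t$ over count at
0 hr. By default counts are used raw: when a library's read count is
proportional to its surviving lesions (exactly true of the simulator,
which emits one read per lesion, and of identically prepared libraries),
the raw ratio is the absolute surviving fraction, whereas rescaling each
library to its own total would force the genome-wide mean to 1 and erase
the repair signal. When a spike-in ratio (spike reads at 0 hr over spike
reads at $t$) is supplied, both libraries are total-scaled and the ratio
multiplied by the spike factor, which restores the absolute scale from the
spike; `scale="total"` gives the shape-only variant. Values above 1 are
reported as-is and flagged, never clipped, so normalisation failures stay
visible.

**Windows.** Non-overlapping windows (default 5 bp) tile outward from the
feature-relative origin (0..4, 5..9, and mirrored), so position 0 always
sits on a window boundary and window identity is deterministic. A window's
value is the unweighted mean of its unmasked members; all-masked windows
stay masked.

**Replicates.** Reproducibility is summarised as Pearson r between
depth-normalised 50 bp-binned counts on jointly nonzero bins.

## Sites, orientation, target genes

Binding-site intervals are retained only if they match the canonical IUPAC
motif (e.g. `CGTNNNNNRNKA` for Abf1, `TTACCC` for Reb1) on either strand,
within a configurable slop (default 0: the source intervals already
localise the motif); the match strand orients the site. The motif origin
is the left-of-center column ((len−1)//2 on the motif strand), giving a
deterministic single-base origin for even-length motifs; a configurable
origin shift supports alternative numbering (e.g. position 0 on the first
G of GGGTAA). Occupancy stratification puts the boundary value in the low
class (high is strictly > 10 by default), with both threshold and
comparator configurable. Motif columns that cannot host the profiled
lesion class (A/T-only columns for G lesions) are identified so
single-nucleotide plots can mask and asterisk them.

Target genes: each site links to its nearest TSS within 300 bp; when the
nearest flanking TSSs on the two sides transcribe away from each other
(divergent promoter) and both are in range, both genes are linked, and
exact distance ties are also both kept (symmetric with the divergent
rule). Each gene is kept once, attached to its closest site. Gene heatmap
rows are ordered by |site-to-TSS distance|, longest first.

## Aggregation

Metaprofiles pool raw counts across features per oriented relative
position and then form the ratio (ratio of pooled counts). At
single-nucleotide resolution most individual sites have 0–5 counts per
position, where per-site ratios are undefined or wildly noisy; pooling
first keeps the estimator well-defined and its Poisson error analytic. A
mean-of-per-feature-ratios option exists for sensitivity checks. The same
machinery aggregates an arbitrary coverage track (e.g. MNase nucleosome
density), scaled to [0, 1] as a plot overlay.

**Inhibition width.** The literature reports inhibited-region widths
descriptively, without an estimator, so the width here is an explicit
operational choice: baseline = mean over |offset| in a flanking span
(default 300–500 bp); the inhibited region is the contiguous run around
the origin where the profile exceeds baseline × (1 + 0.2) (or falls below
baseline × (1 − 0.2) for formation dips); width = right − left in bp. On
noiseless rectangular profiles this returns twice the half-width exactly,
and a profile that never crosses the threshold returns width 0, flagged.
Its outputs are not claimed to equal any published width.

**Per-window tests.** Two conditions are compared per 5 bp window by
Welch's t-test on feature-level window means, with Benjamini–Hochberg
correction across windows (the correction is this package's choice; only
t-tests are inherited from common practice).

## Synthetic generator

The generator emulates the statistical skeleton of the assay, not its
chemistry. Per position and strand, lesions are Poisson with mean
proportional to a per-base damage propensity — defaults G:A:C:T =
0.020:0.004:0.001:0.0005, ordered to reproduce the observed dominance of
G over A read classes (yields ~70% G reads at yeast-like 38% GC) — times,
at occupied sites only, a motif-relative suppression multiplier (default
0.3 across the motif columns) and optional hotspot multipliers; the naked
control uses the base propensity alone. Each library is scaled to an
expected total depth (default 1e6 reads), as sequencing would. Occupancy
acts as a binary occupied flag (occupancy > 10 by default), mirroring the
high/low dichotomy used in practice rather than a continuous binding
model. Repair is first-order: each lesion survives to time $t$ with
probability $e^{-k_i t}$, with $k_i$ = background 0.5/hr × 0.1 inside
occupied motifs ±15 bp × 0.5 within 20 bp of nucleosome dyads. Nucleosomes
sit on a regular 165 bp lattice outside an 80 bp half-width depletion
window around each site — enough to produce the fast-NDR/slow-dyad
pattern without modelling MNase data. Time courses are sequentially
thinned (binomial), so per-position counts are non-increasing in time.
Read emission is the exact inverse of lesion inference; lesions at
chromosome edges whose read would fall outside are dropped and logged,
keeping the round trip exact on the retained set. A single integer seed
makes every output bit-reproducible.

What the generator does **not** emulate: sequence-context damage
chemistry beyond per-base rates, fragment-length and adaptor artifacts,
mappability, replication timing, diploidy, or continuous occupancy.
Passing recovery tests therefore demonstrates that the estimators are
unbiased and correctly propagate counting noise under the stated model —
not that real libraries are free of those artifacts.

## Problem sizes and numerical choices

Recovery checks use a 400 kb chromosome with 600 motifs (300 occupied,
300 weakly bound, ≥200 bp apart so ±100 bp flanks are uncontaminated) at
1e6 reads per library; at these sizes pooled core counts are in the
thousands, putting 3-SD bands at a few percent. Recovery is asserted
against the truth-implied expectation with 3 SDs propagated from pooled
Poisson/binomial counts, evaluated on pooled core statistics (a
per-window 3-SD sweep across ~200 flank windows would fail by
multiplicity alone). Tolerances for exact contracts: mean-one to 1e−9,
round trips and partitions exact. Degenerate inputs are errors, not
guesses: empty gene sets, zero 0 hr signal, windows with <2 observations,
unknown chromosomes and malformed strands all raise.

## Known limitations

Real-data quantities that depend on deposited sequencing runs (absolute
read-class percentages, site counts after filtering against a specific
binding-site release, linked-gene totals) are functions of those inputs;
the pipeline accepts the corresponding file formats directly but ships no
downloaded data. The remaining-fraction depth convention (raw counts
unless a spike is given) is a documented package choice; libraries whose
total yield is not proportional to surviving lesions need the spike-in
path. Multi-mapping reads are neither detected nor filtered — the
pipeline analyses whatever read set it is given.
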