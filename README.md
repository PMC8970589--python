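# nmpseq-tfprint

Single-nucleotide DNA damage mapping and excision-repair analysis at
transcription factor (TF) binding sites, for yeast-style alkylation
(NMP-seq) and UV (CPD-seq) damage-mapping experiments.

TF proteins such as Abf1 and Reb1 sit on their motifs and change both how
DNA damage forms and how fast it is removed. This package turns aligned
sequencing reads from damage-mapping libraries into strand-specific lesion
tracks and asks two questions around every binding site:

- **Formation** — cellular lesion counts divided by counts from
  MMS-treated naked DNA, $r_i = (c_i/T_c)/(n_i/T_n)$, rescaled so the mean
  over the plotted span is 1.0. Values < 1 at the motif mean the bound
  protein shields the DNA from the damaging chemical.
- **Repair** — the fraction of remaining damage
  $f_i(t) = m_i(t)/m_i(0)$ (optionally corrected by a pUC19-style spike-in
  ratio). Under first-order repair $f_i(t) = e^{-k_i t}$, so values near 1
  mean repair is blocked.

Lesions are called from read 5′ ends: the assay ligates an adaptor at the
cleaved lesion, so for a `+` strand read starting at $x$ the lesion is at
$x-1$ on the `-` strand (and symmetrically for `-` reads); the reference
base at that position names the lesion class (G reads ≈ 7-methylguanine,
A reads ≈ 3-methyladenine; CPD mode keys dinucleotides). Profiles are
aggregated by pooling counts across motif-oriented sites (or TSS-aligned
genes) per relative position before taking ratios, averaged in 5 bp
non-overlapping windows tiled outward from the origin.

A fully seeded synthetic generator (`nmpseq_tfprint.simulate`) plants
base-dependent damage rates (G ≫ A ≫ C ≈ T), occupancy-dependent motif
suppression and hotspots, and first-order repair with inhibition inside
bound motifs and near nucleosome dyads — so every stage of the pipeline is
testable against known ground truth.

## Worked example

```bash
nmpseq-tfprint demo --seed 1 --depth 1000000 --out demo_out
# occupied-core formation ratio ~ 0.289 (planted 0.3); outputs in demo_out
```

The demo simulates 400 motifs (half occupied, half weakly bound) on a
300 kb chromosome, emits ~1e6 reads per library (naked control, 0/1/2 hr
repair), re-infers lesions from the reads, and writes formation and
remaining-damage metaprofiles plus a PNG. With seed 1:

- `formation_occupied.tsv`: the naked-normalised ratio is ~1.0 across the
  flanks (e.g. 1.000 at −500) and dips to **0.289** at the motif core —
  recovering the planted 0.3× suppression from reads alone.
- `remaining_occupied_t2.tsv`: after 2 hr the motif core retains **0.90**
  of its initial damage versus **0.42** in the flanks: repair is an order
  of magnitude slower where the factor sits (planted 10× inhibition,
  flanks slowed mildly by the simulated nucleosome lattice).

Each stage is also a standalone subcommand over plain files (BED / FASTA /
bedGraph / TSV), so real aligned-read and binding-site tables drop in
directly: `simulate`, `lesions call`, `normalize ratio|remaining`,
`sites filter|stratify|link`, `profile sites|width`.

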