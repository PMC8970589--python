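"""Metaprofile aggregation, overlays, heatmap ordering, inhibition width,
per-window significance, and end-to-end recovery of planted parameters."""

import numpy as np
import pandas as pd
import pytest

from nmpseq_tfprint import (
    LesionTrack,
    MetaProfile,
    SimConfig,
    gene_heatmap,
    inhibition_width,
    link_to_tss,
    nucleosome_overlay,
    select_class,
    simulate_experiment,
    simulate_repair_timepoint,
    site_metaprofile,
    tss_metaprofile,
    window_significance,
)
from nmpseq_tfprint.profiles import aggregate_values, feature_offset_counts, pooled_counts
from nmpseq_tfprint.simulate import place_nucleosomes


def constant_track(genome, value):
    track = LesionTrack(genome)
    for chrom in track.chroms:
        track.counts[chrom][:, :] = value
    return track


def one_site(mid, strand="+", chrom="c"):
    return pd.DataFrame(
        {"chrom": [chrom], "midpoint": [mid], "strand": [strand],
         "start": [mid - 6], "end": [mid + 6], "occupancy": [20.0]}
    )


class TestSiteMetaprofile:
    def test_constant_signal_gives_flat_profile(self):
        genome = {"c": "ACGT" * 500}
        num = constant_track(genome, 3)
        den = constant_track(genome, 3)
        meta = site_metaprofile(num, den, one_site(1000), flank=100, window=5,
                                kind="remaining")
        assert np.allclose(meta.value[~meta.masked], 1.0)

    def test_single_site_profile_equals_local_series(self):
        rng = np.random.default_rng(0)
        genome = {"c": "ACGT" * 500}
        track = LesionTrack(genome)
        track.counts["c"][0] = rng.integers(1, 10, 2000)
        den = constant_track(genome, 1)
        meta = site_metaprofile(track, den, one_site(1000), flank=50, window=1,
                                kind="remaining", min_den=1)
        local = track.counts["c"].sum(axis=0)[950:1051] / 2.0
        assert np.allclose(meta.value, local)

    def test_minus_strand_site_mirrors_series(self):
        rng = np.random.default_rng(1)
        genome = {"c": "ACGT" * 500}
        track = LesionTrack(genome)
        track.counts["c"][0] = rng.integers(1, 10, 2000)
        den = constant_track(genome, 1)
        plus = site_metaprofile(track, den, one_site(1000, "+"), flank=50,
                                window=1, kind="remaining")
        minus = site_metaprofile(track, den, one_site(1000, "-"), flank=50,
                                 window=1, kind="remaining")
        assert np.allclose(minus.value, plus.value[::-1])

    def test_flip_consistency_genome_reversal(self):
        # reversing the genome and re-orienting all sites mirrors the profile
        config = SimConfig(genome_length=20_000, n_sites=10, depth=100_000, seed=5)
        exp = simulate_experiment(config)
        sites = exp["truth"].sites
        cell, naked = exp["cellular"], exp["naked"]
        L = config.genome_length
        rev_genome = {"chrSim": exp["genome"]["chrSim"][::-1]}
        rev_cell = LesionTrack(rev_genome)
        # reversing swaps strands and mirrors coordinates
        rev_cell.counts["chrSim"] = cell.counts["chrSim"][::-1, ::-1].copy()
        rev_naked = LesionTrack(rev_genome)
        rev_naked.counts["chrSim"] = naked.counts["chrSim"][::-1, ::-1].copy()
        rev_sites = sites.copy()
        rev_sites["midpoint"] = L - 1 - sites["midpoint"]
        rev_sites["strand"] = np.where(sites["strand"] == "+", "-", "+")
        fwd = site_metaprofile(cell, naked, sites, flank=100, window=1)
        rev = site_metaprofile(rev_cell, rev_naked, rev_sites, flank=100, window=1)
        np.testing.assert_allclose(
            fwd.value[~fwd.masked], rev.value[~rev.masked], rtol=1e-12
        )

    def test_pooled_aggregation_is_linear_in_counts(self, small_experiment):
        sites = small_experiment["truth"].sites
        a = small_experiment["cellular"]
        b = small_experiment["naked"]
        combined = a.copy()
        combined.counts = {c: a.counts[c] + b.counts[c] for c in a.chroms}
        _, pa, _ = pooled_counts(a, sites, flank=50)
        _, pb, _ = pooled_counts(b, sites, flank=50)
        _, pc, _ = pooled_counts(combined, sites, flank=50)
        assert np.array_equal(pc, pa + pb)

    def test_formation_dip_recovered_and_low_occupancy_flat(self):
        # the planted occupied-core suppression is recovered within 3 SDs
        # propagated from pooled Poisson counts; weakly-bound sites stay flat
        config = SimConfig(genome_length=200_000, n_sites=200, depth=2_000_000,
                           min_gap=200, seed=31)
        exp = simulate_experiment(config)
        truth = exp["truth"]
        gcell = select_class(exp["cellular"], "G")
        gnaked = select_class(exp["naked"], "G")
        occ = truth.sites[truth.sites["occupied"]]
        unocc = truth.sites[~truth.sites["occupied"]]
        for subset, expected_core in ((occ, 0.3), (unocc, 1.0)):
            meta = site_metaprofile(gcell, gnaked, subset, flank=500, window=1)
            # motif columns span offsets -5..+6 around the left-of-center origin
            core = (meta.offsets >= -5) & (meta.offsets <= 6) & ~meta.masked
            _, pn, _ = pooled_counts(gnaked, subset, flank=500)
            _, pc, _ = pooled_counts(gcell, subset, flank=500)
            ncore = pn[core].sum()
            ccore = pc[core].sum()
            sd = expected_core * np.sqrt(1 / max(ccore, 1) + 1 / ncore)
            core_mean = np.average(meta.value[core], weights=pn[core])
            assert abs(core_mean - expected_core) <= 3 * sd + 0.02 * expected_core

    def test_empty_sites_rejected(self, small_experiment):
        with pytest.raises(ValueError):
            site_metaprofile(
                small_experiment["cellular"], small_experiment["naked"],
                small_experiment["truth"].sites.iloc[:0],
            )


class TestTssMetaprofile:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])

    def test_constant_signal_flat_across_plus_genes(self):
        genome = {"c": "ACGT" * 1000}
        num = constant_track(genome, 2)
        den = constant_track(genome, 2)
        genes = self._genes([(f"g{i}", "c", 500 + 300 * i, "+") for i in range(5)])
        meta = tss_metaprofile(num, den, genes, flank=100, window=5)
        assert np.allclose(meta.value[~meta.masked], 1.0)

    def test_minus_gene_mirrors_local_series(self):
        rng = np.random.default_rng(2)
        genome = {"c": "ACGT" * 1000}
        track = LesionTrack(genome)
        track.counts["c"][0] = rng.integers(1, 9, 4000)
        den = constant_track(genome, 1)
        plus = tss_metaprofile(track, den, self._genes([("g", "c", 2000, "+")]),
                               flank=50, window=1)
        minus = tss_metaprofile(track, den, self._genes([("g", "c", 2000, "-")]),
                                flank=50, window=1)
        assert np.allclose(minus.value, plus.value[::-1])

    def test_planted_upstream_peak_appears_at_minus_100(self):
        # a damage excess planted 100 bp upstream of each TSS (gene-oriented)
        genome = {"c": "ACGT" * 2500}
        den = constant_track(genome, 5)
        num = constant_track(genome, 5)
        genes = self._genes(
            [("gp", "c", 3000, "+"), ("gm", "c", 7000, "-")]
        )
        num.counts["c"][:, 3000 - 100] += 40  # upstream of the + gene
        num.counts["c"][:, 7000 + 100] += 40  # upstream of the - gene
        meta = tss_metaprofile(num, den, genes, flank=300, window=1)
        peak_offset = meta.offsets[np.nanargmax(meta.value)]
        assert peak_offset == -100


class TestNucleosomeOverlay:
    def test_constant_coverage_scales_to_one(self):
        genome_len = 4000
        cov = {"c": np.full(genome_len, 7.0)}
        overlay = nucleosome_overlay(cov, one_site(2000), flank=100, window=5)
        assert np.allclose(overlay[np.isfinite(overlay)], 1.0)

    def test_lattice_with_site_depletion_dips_at_origin(self):
        config = SimConfig(genome_length=30_000, n_sites=12, depth=1000, seed=3)
        exp = simulate_experiment(config)
        sites = exp["truth"].sites
        dyads = place_nucleosomes(config, sites)
        cov = np.zeros(config.genome_length)
        for d in dyads:
            lo, hi = max(0, d - 73), min(config.genome_length, d + 74)
            cov[lo:hi] += 1.0
        overlay = nucleosome_overlay({"chrSim": cov}, sites, flank=400, window=5)
        offsets = np.arange(-400, 401)[::5][: len(overlay)]
        centre = np.abs(offsets) <= 20
        assert np.nanmean(overlay[centre]) < 0.5 * np.nanmax(overlay)

    def test_overlay_length_matches_profile_length(self, small_experiment):
        sites = small_experiment["truth"].sites
        meta = site_metaprofile(small_experiment["cellular"],
                                small_experiment["naked"], sites,
                                flank=200, window=5)
        cov = {"chrSim": np.ones(60_000)}
        overlay = nucleosome_overlay(cov, sites, flank=200, window=5)
        assert len(overlay) == len(meta.value)

    def test_empty_coverage_rejected(self):
        with pytest.raises(ValueError):
            nucleosome_overlay({"c": np.zeros(100)}, one_site(50), flank=10)


class TestGeneHeatmap:
    def _links(self, rows):
        return pd.DataFrame(
            rows,
            columns=["site_index", "gene_id", "chrom", "site_midpoint", "tss",
                     "gene_strand", "distance"],
        )

    def test_rows_ordered_by_distance_descending(self):
        genome = {"c": "ACGT" * 2000}
        t0 = constant_track(genome, 3)
        links = self._links(
            [(0, "near", "c", 1000, 1050, "+", 50),
             (1, "far", "c", 3000, 3250, "+", 250),
             (2, "mid", "c", 5000, 5100, "+", 100)]
        )
        hm = gene_heatmap(t0, t0, links, flank=100, window=5)
        assert list(hm.index) == ["far", "mid", "near"]
        assert np.allclose(hm.to_numpy()[np.isfinite(hm.to_numpy())], 1.0)

    def test_ordering_matches_brute_force_sort(self):
        rng = np.random.default_rng(4)
        genome = {"c": "ACGT" * 3000}
        t0 = constant_track(genome, 2)
        rows = [
            (i, f"g{i}", "c", 500 + 600 * i, 500 + 600 * i + int(d),
             "+" if rng.random() < 0.5 else "-", int(d) * (1 if rng.random() < 0.5 else -1))
            for i, d in enumerate(rng.integers(0, 300, 15))
        ]
        links = self._links(rows)
        hm = gene_heatmap(t0, t0, links, flank=50, window=5)
        expected = [r[1] for r in sorted(rows, key=lambda r: -abs(r[6]))]
        assert list(hm.index) == expected

    def test_row_count_equals_linked_genes(self, small_experiment):
        truth = small_experiment["truth"]
        sites = truth.sites
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(sites))],
                "chrom": "chrSim",
                "tss": (sites["midpoint"] + 150).clip(0, 59_999),
                "strand": "+",
            }
        )
        links = link_to_tss(sites, genes)
        t0 = small_experiment["cellular"]
        t2 = simulate_repair_timepoint(t0, truth, 2.0, seed=1)
        hm = gene_heatmap(t2, t0, links, flank=200, window=5)
        assert len(hm) == len(links)

    def test_empty_links_rejected(self, small_experiment):
        with pytest.raises(ValueError):
            gene_heatmap(small_experiment["cellular"], small_experiment["cellular"],
                         self._links([]), flank=100)


def rect_profile(half_width, flank=200, height=2.0, window=1):
    offsets = np.arange(-flank, flank + 1)
    values = np.ones(len(offsets))
    values[np.abs(offsets) <= half_width] = height
    return MetaProfile(
        offsets=offsets,
        value=values,
        n=np.ones(len(offsets), dtype=int),
        masked=np.zeros(len(offsets), dtype=bool),
        window=window,
    )


class TestInhibitionWidth:
    def test_rectangular_bump_width(self):
        res = inhibition_width(rect_profile(15), baseline_span=(100, 200))
        assert (res.left, res.right, res.width) == (-15, 15, 30)
        assert not res.flagged

    def test_widened_bump_increases_width_by_twice_the_extension(self):
        narrow = inhibition_width(rect_profile(15), baseline_span=(100, 200))
        wide = inhibition_width(rect_profile(25), baseline_span=(100, 200))
        assert wide.width - narrow.width == 20

    def test_flat_profile_width_zero_flagged(self):
        res = inhibition_width(rect_profile(15, height=1.0),
                               baseline_span=(100, 200))
        assert res.width == 0 and res.flagged

    def test_dip_mode_measures_formation_suppression(self):
        prof = rect_profile(10, height=0.3)
        res = inhibition_width(prof, baseline_span=(100, 200), kind="dip")
        assert (res.left, res.right, res.width) == (-10, 10, 20)

    def test_baseline_span_must_overlap(self):
        with pytest.raises(ValueError):
            inhibition_width(rect_profile(15, flank=50), baseline_span=(100, 200))


class TestWindowSignificance:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(6)
        values = rng.normal(1.0, 0.1, size=(30, 50))
        df = window_significance(values, values.copy(), window=5)
        assert np.allclose(df["statistic"], 0.0)
        assert (df["p_adj"] > 0.99).all()

    def test_planted_core_suppression_detected(self):
        # 0.3x suppression at the core in 200 features is detected at FDR 0.05
        rng = np.random.default_rng(7)
        offsets = np.arange(-25, 25)
        base = rng.poisson(20.0, size=(200, 50)).astype(float)
        treated = rng.poisson(
            np.where(np.abs(offsets) <= 6, 6.0, 20.0)[None, :], size=(200, 50)
        ).astype(float)
        df = window_significance(treated, base, offsets=offsets, window=5)
        core = df[df["window_start"].isin([-5, 0, 5])]
        flank = df[df["window_start"].isin([-25, 20])]
        assert core["significant"].all()
        assert not flank["significant"].any()

    def test_permuted_labels_give_uniform_pvalues(self):
        # KS check against U(0,1) on the raw p-values under the null
        rng = np.random.default_rng(8)
        pooled = rng.normal(0.5, 0.2, size=(120, 500))
        labels = rng.permutation(120) < 60
        df = window_significance(pooled[labels], pooled[~labels], window=5)
        from scipy import stats

        ks = stats.kstest(df["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValueError):
            window_significance(np.ones((1, 10)), np.ones((5, 10)), window=5)


def test_feature_offset_counts_respects_bounds():
    genome = {"c": "ACGT" * 30}
    track = constant_track(genome, 1)
    mat = feature_offset_counts(track, one_site(5), flank=10)
    assert np.isnan(mat[0, :5]).all()  # offsets -10..-6 fall off the chromosome
    assert np.nansum(mat[0]) == 2 * 16  # both strands, in-bounds offsets


def test_aggregate_values_handles_nan_positions():
    genome_len = 100
    vals = {"c": np.full(genome_len, 2.0)}
    vals["c"][40:60] = np.nan
    feats = one_site(50)
    offsets, mean, n = aggregate_values(vals, feats, flank=30)
    inside = (offsets >= -10) & (offsets < 10)
    assert (n[inside] == 0).all()
    assert np.allclose(mean[~np.isnan(mean)], 2.0)
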