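"""Synthetic catalog generator: determinism, marginals, planted structure."""

import numpy as np
import pytest
from scipy import stats

from broadscan.motif_scan import ScanParams, drm_pwm, scan
from broadscan.regions import fetch, gc_content
from broadscan.synthetic_data import (
    PlantedMotif,
    SimulationConfig,
    SimulationInfeasibleError,
    breadth_class,
    default_breadth_distribution,
    plant_in_regions,
    random_regions,
    simulate_catalog,
    simulate_enhancers,
    simulate_genome,
    simulate_semipartial_data,
    simulate_tf_table,
    write_catalog,
)
from broadscan.tf_expression import motif_gc


def _small_cfg(**kw):
    defaults = dict(seed=1, n_chromosomes=2, chrom_length=300_000, n_enhancers=400)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_nonpositive_chromosome_length_rejected(self):
        with pytest.raises(ValueError, match="chrom_length"):
            _small_cfg(chrom_length=0)

    def test_breadth_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            _small_cfg(breadth_distribution={1: 0.5, 2: 0.4})

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            PlantedMotif("m", "ACGT", {"broad": -0.1})

    def test_default_breadth_law_anchors(self):
        dist = default_breadth_distribution()
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert dist[1] == pytest.approx(0.15, rel=1e-6)
        assert sum(p for b, p in dist.items() if b > 45) == pytest.approx(0.05)


class TestGenome:
    def test_deterministic_given_seed(self):
        g1 = simulate_genome(_small_cfg())
        g2 = simulate_genome(_small_cfg())
        assert g1 == g2

    def test_gc_fraction_within_binomial_bound(self):
        cfg = SimulationConfig(
            seed=3, n_chromosomes=1, chrom_length=1_000_000, n_enhancers=0,
            planted_motifs=(),
        )
        genome = simulate_genome(cfg)
        # 4 sigma of Binomial(1e6, 0.42)/1e6 is ~0.002
        assert gc_content(genome["chr1"]) == pytest.approx(0.42, abs=0.002)

    def test_pure_gc_background(self):
        cfg = SimulationConfig(
            seed=0, n_chromosomes=1, chrom_length=5000, background_gc=1.0,
            n_enhancers=0, planted_motifs=(),
        )
        genome = simulate_genome(cfg)
        assert set(genome["chr1"]) == {"G", "C"}

    def test_sixmer_counts_near_multinomial_expectation(self):
        from broadscan.spectrum_classifier import kmer_spectrum

        cfg = SimulationConfig(
            seed=11, n_chromosomes=1, chrom_length=4096 * 100,
            background_gc=0.5, n_enhancers=0, planted_motifs=(),
        )
        genome = simulate_genome(cfg)
        counts = kmer_spectrum(genome["chr1"], 6)
        n = 4096 * 100 - 5
        expected = n / 4096
        sigma = np.sqrt(n * (1 / 4096) * (1 - 1 / 4096))
        assert np.all(np.abs(counts - expected) < 5 * sigma)


@pytest.fixture(scope="module")
def catalog():
    return simulate_catalog(_small_cfg())


class TestEnhancers:
    def test_bit_identical_reruns(self, catalog):
        again = simulate_catalog(_small_cfg())
        assert again.genome == catalog.genome
        assert again.truth.equals(catalog.truth)
        assert again.enhancers == catalog.enhancers
        assert again.tf_table.equals(catalog.tf_table)

    def test_enhancers_inside_chromosomes(self, catalog):
        for rec in catalog.enhancers:
            assert 0 <= rec.region.start < rec.region.end
            assert rec.region.end <= len(catalog.genome[rec.region.chrom])

    def test_truth_positions_inside_their_enhancers(self, catalog):
        spans = {r.region.id: r.region for r in catalog.enhancers}
        for row in catalog.truth.itertuples():
            region = spans[row.enhancer_id]
            assert region.start <= row.start and row.end <= region.end

    def test_breadth_one_fraction(self):
        cfg = _small_cfg(seed=5, n_enhancers=2000, chrom_length=1_200_000)
        cat = simulate_enhancers(cfg, simulate_genome(cfg))
        frac = np.mean([r.breadth == 1 for r in cat.enhancers])
        # 3 sigma of Binomial(2000, 0.15)/2000
        assert frac == pytest.approx(0.15, abs=3 * np.sqrt(0.15 * 0.85 / 2000))

    def test_length_increases_with_breadth(self, catalog):
        lengths = [r.region.length for r in catalog.enhancers]
        breadths = [r.breadth for r in catalog.enhancers]
        assert stats.spearmanr(lengths, breadths).statistic > 0

    def test_gc_increases_with_breadth(self):
        cfg = _small_cfg(seed=9, n_enhancers=1000, chrom_length=800_000,
                         gc_breadth_slope=0.0012)
        cat = simulate_enhancers(cfg, simulate_genome(cfg))
        gcs = [gc_content(fetch(cat.genome, r.region)) for r in cat.enhancers]
        breadths = [r.breadth for r in cat.enhancers]
        assert stats.spearmanr(gcs, breadths).statistic > 0

    def test_planted_density_ratio_recovered_from_truth(self):
        motifs = (
            PlantedMotif("GC_DRM", "GCGCGC", {"broad": 2e-3, "narrow": 5e-4}),
        )
        cfg = _small_cfg(
            seed=13, n_enhancers=1500, chrom_length=1_000_000,
            planted_motifs=motifs,
        )
        cat = simulate_enhancers(cfg, simulate_genome(cfg))
        bp = {"broad": 0, "narrow": 0}
        for rec in cat.enhancers:
            cls = breadth_class(rec.breadth, cfg)
            if cls in bp:
                bp[cls] += rec.region.length
        counts = cat.truth.groupby("breadth_class").size()
        dens_broad = counts.get("broad", 0) / bp["broad"]
        dens_narrow = counts.get("narrow", 0) / bp["narrow"]
        ratio = dens_broad / dens_narrow
        # Poisson CI on the observed counts propagated to the ratio
        se = ratio * np.sqrt(1 / counts["broad"] + 1 / counts["narrow"])
        assert abs(ratio - 4.0) < 3 * se

    def test_planted_loci_all_rescanned(self, catalog):
        params = ScanParams(alpha=1 / 4096)  # exact-match regime for GC
        pwm = drm_pwm("GC")
        gc_truth = catalog.truth[catalog.truth.motif == "GC_DRM"]
        assert len(gc_truth) > 0
        for row in gc_truth.itertuples():
            window = catalog.genome[row.chrom][row.start : row.end]
            assert any(h.offset == 0 for h in scan(window, pwm, params))

    def test_infeasible_density_raises(self):
        motifs = (PlantedMotif("GC_DRM", "GCGCGC", {"narrow": 0.2}),)
        cfg = _small_cfg(seed=2, n_enhancers=50, planted_motifs=motifs)
        with pytest.raises(SimulationInfeasibleError):
            simulate_enhancers(cfg, simulate_genome(cfg))

    def test_write_catalog_formats(self, catalog, tmp_path):
        write_catalog(catalog, tmp_path)
        for name in ("genome.fa", "enhancers.bed", "truth.tsv", "tf_table.tsv",
                     "tf_motifs.pfm", "config.json"):
            assert (tmp_path / name).exists()
        from broadscan.motif_scan import read_jaspar_pfms
        from broadscan.regions import read_enhancer_bed

        assert read_enhancer_bed(tmp_path / "enhancers.bed") == catalog.enhancers
        assert len(read_jaspar_pfms(tmp_path / "tf_motifs.pfm")) == len(
            catalog.tf_motifs
        )


class TestTfTable:
    def test_group_gc_means_recovered(self):
        cfg = _small_cfg(tsps_gc_association=0.11, tf_motif_gc_base=0.455)
        table, motifs = simulate_tf_table(cfg)
        per_tf = {}
        for row in table.itertuples():
            vals = [motif_gc(motifs[m]) for m in row.motif_ids.split(",")]
            per_tf[row.tf_name] = (row.breadth_class, np.mean(vals))
        broad = [v for c, v in per_tf.values() if c == "broad"]
        spec = [v for c, v in per_tf.values() if c == "specific"]
        # group SE ~ sd/sqrt(n) ~ 0.07/sqrt(250) ~ 0.005
        assert np.mean(broad) == pytest.approx(0.51, abs=0.02)
        assert np.mean(spec) == pytest.approx(0.40, abs=0.02)

    def test_null_association_rarely_significant(self):
        hits = 0
        n_runs = 60
        for s in range(n_runs):
            cfg = _small_cfg(seed=s, n_tfs=60, tsps_gc_association=0.0)
            table, motifs = simulate_tf_table(cfg)
            broad, spec = [], []
            for row in table.itertuples():
                vals = [motif_gc(motifs[m]) for m in row.motif_ids.split(",")]
                (broad if row.breadth_class == "broad" else spec).append(
                    np.mean(vals)
                )
            if stats.mannwhitneyu(broad, spec).pvalue < 0.05:
                hits += 1
        assert hits <= 0.10 * n_runs + 3  # ~type-I rate at alpha 0.05

    def test_tsps_ranges_by_class(self):
        table, _ = simulate_tf_table(_small_cfg())
        assert (table.tsps >= 0).all()
        assert (table[table.breadth_class == "broad"].tsps < 1).all()
        assert (table[table.breadth_class == "specific"].tsps >= 1).all()


class TestHelpers:
    def test_random_regions_nonoverlapping(self, small_genome):
        regs = random_regions(small_genome, 200, 600, seed=5)
        by_chrom: dict = {}
        for r in regs:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_plant_in_regions_truth_is_verbatim(self, small_genome):
        regs = random_regions(small_genome, 50, 600, seed=6)
        genome, truth = plant_in_regions(
            small_genome, regs, "GCGCGC", density=5e-3, seed=7
        )
        assert len(truth) > 0
        for row in truth.itertuples():
            assert genome[row.chrom][row.start : row.end] == "GCGCGC"

    def test_semipartial_generator_population_structure(self):
        df = simulate_semipartial_data(200_000, sr2=0.1, seed=3)
        r = np.corrcoef(df.gc, df.cpg)[0, 1]
        assert r == pytest.approx(0.5, abs=0.01)
        with pytest.raises(ValueError):
            simulate_semipartial_data(100, sr2=0.9, seed=0, r2_shared=0.3)
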