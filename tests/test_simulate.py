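import numpy as np
import pytest

from bsascan.simulate import (
    GeneticMapSpec,
    SimulationConfig,
    Site,
    emit_vcf,
    form_bulks,
    haldane_r,
    place_sites,
    simulate_dataset,
    simulate_f2,
    simulate_pool_reads,
    true_pool_freq,
    write_dataset,
)
from bsascan.variants import read_vcf


class TestGeneticMapSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            GeneticMapSpec(("chr1",), (0,))
        with pytest.raises(ValueError):
            GeneticMapSpec(("chr1",), (100,), recomb_rate=-1.0)
        with pytest.raises(ValueError):
            GeneticMapSpec(("chr1",), (100,), suppressed_intervals=(("chr1", 50, 200, 0.1),))
        with pytest.raises(ValueError):
            GeneticMapSpec(("chr1",), (100,), suppressed_intervals=(("chrX", 1, 50, 0.1),))

    def test_map_distance_plain(self):
        gmap = GeneticMapSpec(("chr1",), (10_000_000,), recomb_rate=2.0)
        assert gmap.map_distance_cM("chr1", 1_000_000, 3_000_000) == pytest.approx(4.0)

    def test_map_distance_suppressed(self):
        gmap = GeneticMapSpec(
            ("chr1",), (10_000_000,), recomb_rate=1.0,
            suppressed_intervals=(("chr1", 2_000_000, 3_000_000, 0.0),),
        )
        # 1 Mb of the 2 Mb span is fully suppressed
        assert gmap.map_distance_cM("chr1", 1_500_000, 3_500_000) == pytest.approx(1.0)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_r(0.0) == 0.0

    def test_limit_half(self):
        assert haldane_r(10_000.0) == pytest.approx(0.5, abs=1e-12)

    def test_50cM(self):
        assert haldane_r(50.0) == pytest.approx(0.5 * (1 - np.exp(-1.0)))


class TestPlaceSites:
    def test_bounds_sorted_unique(self):
        gmap = GeneticMapSpec(("chr1",), (10_000_000,))
        sites = place_sites(gmap, 5, seed=7)
        coords = [(s.chrom, s.pos) for s in sites]
        assert len(coords) == len(set(coords)) == 5
        assert coords == sorted(coords)
        assert all(1 <= s.pos <= 10_000_000 for s in sites)

    def test_causal_included_with_insertion_allele(self):
        gmap = GeneticMapSpec(("chr1",), (10_000_000,))
        sites = place_sites(gmap, 5, seed=7, causal=("chr1", 5_000_000))
        causal = [s for s in sites if s.pos == 5_000_000]
        assert len(causal) == 1
        assert causal[0].alt == causal[0].ref + "AA"

    def test_deterministic(self):
        gmap = GeneticMapSpec(("chr1", "chr2"), (4_000_000, 6_000_000))
        a = place_sites(gmap, 50, seed=3)
        b = place_sites(gmap, 50, seed=3)
        assert a == b

    def test_too_many_sites(self):
        gmap = GeneticMapSpec(("chr1",), (10,))
        with pytest.raises(ValueError, match="exceeds"):
            place_sites(gmap, 11, seed=0)


class TestSimulateF2:
    def test_mendelian_ratio(self):
        gmap = GeneticMapSpec(("chr1",), (1_000_000,))
        sites = [Site("chr1", 500_000)]
        inds = simulate_f2(gmap, sites, ("chr1", 500_000), 20_000, seed=5)
        frac_gt = sum(i.phenotype == "GT" for i in inds) / len(inds)
        se = np.sqrt(0.25 * 0.75 / len(inds))
        assert abs(frac_gt - 0.25) <= 4 * se

    def test_phenotype_iff_dosage_two(self):
        gmap = GeneticMapSpec(("chr1",), (1_000_000,))
        sites = [Site("chr1", 100), Site("chr1", 500_000)]
        inds = simulate_f2(gmap, sites, ("chr1", 500_000), 500, seed=2)
        for ind in inds:
            assert (ind.phenotype == "GT") == (ind.genotypes[1] == 2)

    def test_zero_distance_perfect_linkage(self):
        gmap = GeneticMapSpec(("chr1",), (1_000_000,))
        sites = [Site("chr1", 100), Site("chr1", 100, ref="C", alt="G")]
        inds = simulate_f2(gmap, sites, ("chr1", 100), 2_000, seed=9)
        geno = np.stack([i.genotypes for i in inds])
        assert (geno[:, 0] == geno[:, 1]).all()

    def test_infinite_distance_independent(self):
        # 10 Mb at 1000 cM/Mb = 10 000 cM: r -> 1/2, dosages uncorrelated
        gmap = GeneticMapSpec(("chr1",), (10_000_001,), recomb_rate=1000.0)
        sites = [Site("chr1", 1), Site("chr1", 10_000_001)]
        inds = simulate_f2(gmap, sites, ("chr1", 1), 5_000, seed=13)
        geno = np.stack([i.genotypes for i in inds]).astype(float)
        corr = np.corrcoef(geno[:, 0], geno[:, 1])[0, 1]
        assert abs(corr) < 0.05


class TestFormBulks:
    def test_insufficient_class_named(self):
        gmap = GeneticMapSpec(("chr1",), (1_000,))
        sites = [Site("chr1", 500)]
        inds = simulate_f2(gmap, sites, ("chr1", 500), 60, seed=1)
        n_gt = sum(i.phenotype == "GT" for i in inds)
        assert n_gt < 30  # ~15 expected
        with pytest.raises(ValueError, match="GT"):
            form_bulks(inds, 30, seed=1)

    def test_bulk_sizes_and_recessive_rule(self, small_dataset):
        ds, cfg, _ = small_dataset
        assert len(ds.wt_bulk) == len(ds.gt_bulk) == cfg.bulk_size
        causal_idx = next(
            i for i, s in enumerate(ds.sites) if s.pos == cfg.causal_pos_bp
        )
        assert all(ind.genotypes[causal_idx] == 2 for ind in ds.gt_bulk)
        assert all(ind.genotypes[causal_idx] in (0, 1) for ind in ds.wt_bulk)


class TestSimulatePoolReads:
    def test_fixed_depth_no_error_at_fixation(self, small_dataset):
        ds, cfg, _ = small_dataset
        causal_idx = next(i for i, s in enumerate(ds.sites) if s.pos == cfg.causal_pos_bp)
        counts = ds.gt_counts[causal_idx]
        assert counts.ref_reads == 0
        assert counts.alt_fraction == 1.0

    def test_error_shifts_mean(self):
        # p = 1 with e = 0.001 over many replicates: mean alt fraction ~ 0.999
        gmap = GeneticMapSpec(("chr1",), (1_000,))
        sites = [Site("chr1", 500)]
        inds = simulate_f2(gmap, sites, ("chr1", 500), 4_000, seed=3)
        gt = [i for i in inds if i.phenotype == "GT"][:500]
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(200):
            counts = simulate_pool_reads(gt, mean_depth=50, seq_error=0.001,
                                         depth_law="fixed", seed=rng)
            fracs.append(counts[0].alt_fraction)
        assert np.mean(fracs) == pytest.approx(0.999, abs=0.002)

    def test_wt_bulk_mean_one_third(self):
        gmap = GeneticMapSpec(("chr1",), (1_000,))
        sites = [Site("chr1", 500)]
        rng = np.random.default_rng(17)
        fracs = []
        for seed in range(40):
            inds = simulate_f2(gmap, sites, ("chr1", 500), 300, seed=seed)
            wt_bulk, _ = form_bulks(inds, 30, seed=seed)
            counts = simulate_pool_reads(wt_bulk, mean_depth=60, seq_error=0.0,
                                         depth_law="fixed", seed=rng)
            fracs.append(counts[0].alt_fraction)
        assert np.mean(fracs) == pytest.approx(1 / 3, abs=0.03)

    def test_empty_bulk_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            simulate_pool_reads([], seed=0)


class TestEmitVcf:
    def test_round_trip_counts(self, small_dataset, tmp_path):
        ds, cfg, gmap = small_dataset
        path = emit_vcf(ds.sites, ds.wt_counts, ds.gt_counts, tmp_path / "sim.vcf", gmap=gmap)
        result = read_vcf(path)
        assert len(result.sites) == len(ds.sites)
        for site, wc, gc in zip(result.sites, ds.wt_counts, ds.gt_counts):
            assert (site.wt.ref_reads, site.wt.alt_reads) == (wc.ref_reads, wc.alt_reads)
            assert (site.gt.ref_reads, site.gt.alt_reads) == (gc.ref_reads, gc.alt_reads)

    def test_causal_ad_serialization(self, small_dataset, tmp_path):
        ds, cfg, gmap = small_dataset
        path = emit_vcf(ds.sites, ds.wt_counts, ds.gt_counts, tmp_path / "sim.vcf", gmap=gmap)
        causal_line = next(
            line for line in path.read_text().splitlines()
            if not line.startswith("#") and f"\t{cfg.causal_pos_bp}\t" in line
        )
        gt_field = causal_line.split("\t")[10]
        depth = ds.gt_counts[
            next(i for i, s in enumerate(ds.sites) if s.pos == cfg.causal_pos_bp)
        ].depth
        assert f":0,{depth}:" in gt_field

    def test_header_declares_samples(self, small_dataset, tmp_path):
        ds, _, gmap = small_dataset
        path = emit_vcf(ds.sites, ds.wt_counts, ds.gt_counts, tmp_path / "sim.vcf", gmap=gmap)
        header = next(l for l in path.read_text().splitlines() if l.startswith("#CHROM"))
        assert header.endswith("WT_pool\tGT_pool")

    def test_bit_identical_for_identical_seed(self, tmp_path):
        gmap = GeneticMapSpec(("chr1",), (2_000_000,))
        cfg = SimulationConfig(n_f2=240, bulk_size=30, n_sites=50, causal_chrom="chr1",
                               causal_pos_bp=1_000_000, seed=21)
        for name in ("a", "b"):
            ds = simulate_dataset(cfg, gmap)
            write_dataset(ds, cfg, gmap, tmp_path / name)
        assert (tmp_path / "a" / "bulks.vcf").read_bytes() == (
            tmp_path / "b" / "bulks.vcf"
        ).read_bytes()

    def test_misaligned_counts_rejected(self, small_dataset, tmp_path):
        ds, _, gmap = small_dataset
        with pytest.raises(ValueError, match="aligned"):
            emit_vcf(ds.sites, ds.wt_counts[:-1], ds.gt_counts, tmp_path / "x.vcf")


class TestTruth:
    def test_wt_bulk_true_freq_near_third_at_causal(self, small_dataset):
        ds, cfg, _ = small_dataset
        causal_idx = next(i for i, s in enumerate(ds.sites) if s.pos == cfg.causal_pos_bp)
        # 30 WT individuals: expected 1/3, binomial-ish tolerance
        assert abs(ds.truth.true_wt_freq[causal_idx] - 1 / 3) < 0.25
        assert ds.truth.true_gt_freq[causal_idx] == 1.0

    def test_truth_dimensions_consistent(self, small_dataset, tmp_path):
        ds, cfg, gmap = small_dataset
        assert len(ds.truth.sites) == len(ds.wt_counts)
        assert len(ds.truth.phenotypes) == cfg.n_f2
        ds.truth.write_tsv(tmp_path / "truth.tsv")
        lines = (tmp_path / "truth.tsv").read_text().splitlines()
        assert lines[0].startswith("#causal\tchr1\t5000000")
        assert len(lines) == 2 + len(ds.sites)


class TestConfigValidation:
    def test_bulk_budget(self, toy_map):
        cfg = SimulationConfig(n_f2=50, bulk_size=30, n_sites=10,
                               causal_chrom="chr1", causal_pos_bp=100)
        with pytest.raises(ValueError, match="bulk_size"):
            cfg.validate(toy_map)

    def test_seq_error_range(self, toy_map):
        cfg = SimulationConfig(n_f2=100, bulk_size=30, n_sites=10, causal_chrom="chr1",
                               causal_pos_bp=100, seq_error=0.5)
        with pytest.raises(ValueError, match="seq_error"):
            cfg.validate(toy_map)

    def test_causal_position_in_range(self, toy_map):
        cfg = SimulationConfig(n_f2=100, bulk_size=30, n_sites=10, causal_chrom="chr1",
                               causal_pos_bp=10_000_001)
        with pytest.raises(ValueError, match="causal"):
            cfg.validate(toy_map)
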