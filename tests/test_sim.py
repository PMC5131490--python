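import numpy as np
import pytest

from recmap.io import read_haplotypes, read_ped_map, read_region_vcf, \
    read_sample_table
from recmap.qc import hwe_exact_test
from recmap.sim import (SimulationConfig, SimulationError, simulate_population,
                        simulate_region_variants, write_fixture_set)
from recmap.variants import HET, HOM_ALT, MISSING


SMALL = dict(n_chromosomes=2, snps_per_chromosome=200,
             chromosome_length_bp=50_000_000,
             carrier_haplotype_chromosome="2",
             carrier_region_bp=(10_000_000, 30_000_000),
             n_panel_healthy=20, n_region_variants=50)


class TestConfig:
    def test_rejects_region_outside_chromosome(self):
        with pytest.raises(ValueError, match="chromosome bounds"):
            SimulationConfig(chromosome_length_bp=10_000,
                             carrier_region_bp=(5_000, 20_000))

    def test_rejects_odd_carrier_count(self):
        with pytest.raises(ValueError, match="even"):
            SimulationConfig(n_obligate_carriers=13)

    def test_rejects_more_affecteds_than_carrier_pairs(self):
        with pytest.raises(ValueError, match="carriers per affected"):
            SimulationConfig(n_affected=8, n_obligate_carriers=14)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_chromosomes: 3\ncarrier_haplotype_chromosome: '2'\n"
                     "carrier_region_bp: [1000000, 9000000]\nseed: 7\n")
        cfg = SimulationConfig.from_yaml(p)
        assert cfg.n_chromosomes == 3 and cfg.seed == 7
        assert cfg.carrier_region_bp == (1_000_000, 9_000_000)


class TestSimulatePopulation:
    def test_deterministic_from_seed(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert np.array_equal(a[0].alleles, b[0].alleles)
        assert np.array_equal(a[1].dosages, b[1].dosages)
        assert list(a[2].position_bp) == list(b[2].position_bp)
        assert a[4].copy_counts == b[4].copy_counts

    def test_cohort_composition_matches_design(self, default_sim, default_cfg):
        samples = default_sim["samples"]
        assert len(samples.ids("affected")) == default_cfg.n_affected
        assert len(samples.ids("obligate_carrier")) == default_cfg.n_obligate_carriers
        assert len(samples.ids("control")) == default_cfg.n_controls
        assert len(samples.ids("panel_healthy")) == default_cfg.n_panel_healthy
        # genotyped cohort = 2 + 14 + 27 = 43 animals
        assert default_sim["genotypes"].n_samples == 43

    def test_truth_consistent_with_emitted_haplotypes(self, default_sim):
        """Affecteds carry two copies of the carrier haplotype over the
        region, verified directly against the phased alleles, not the truth's
        own bookkeeping; carriers carry at least one; controls none."""
        haps, truth = default_sim["haps"], default_sim["truth"]
        samples = default_sim["samples"]
        m = haps.markers
        lo, hi = truth.carrier_region_bp
        region = np.flatnonzero((m.chrom == truth.carrier_chrom)
                                & (m.position_bp >= lo) & (m.position_bp <= hi))
        letters = {}
        for sid in haps.sample_ids:
            i = haps.sample_index(sid)
            strs = []
            for h in range(2):
                strs.append("".join(
                    m.alt_allele[j] if haps.alleles[i, h, j] else m.ref_allele[j]
                    for j in region))
            letters[sid] = strs
        for sid in samples.ids("affected"):
            assert letters[sid] == [truth.carrier_haplotype] * 2
            assert truth.copy_counts[sid] == 2
        for sid in samples.ids("obligate_carrier"):
            assert truth.carrier_haplotype in letters[sid]
            assert truth.copy_counts[sid] >= 1
        for sid in samples.ids("control"):
            assert truth.carrier_haplotype not in letters[sid]
            assert truth.copy_counts[sid] == 0

    def test_dosages_are_masked_haplotype_sums(self, default_sim):
        assert default_sim["haps"].consistent_with(default_sim["genotypes"])

    def test_no_recombination_transmits_whole_parental_chromosomes(self):
        cfg = SimulationConfig(seed=3, recombination_rate=0.0, n_chromosomes=1,
                               snps_per_chromosome=150,
                               chromosome_length_bp=50_000_000,
                               carrier_haplotype_chromosome="1",
                               carrier_region_bp=(10_000_000, 30_000_000),
                               n_panel_healthy=5, n_region_variants=10)
        haps, _, markers, samples, _ = simulate_population(cfg)
        for sid in samples.ids("affected"):
            row = samples.table.set_index("sample_id").loc[sid]
            child = haps.alleles[haps.sample_index(sid)]
            for parent_id, hap in ((row["sire_id"], child[0]),
                                   (row["dam_id"], child[1])):
                parent = haps.alleles[haps.sample_index(parent_id)]
                assert (np.array_equal(hap, parent[0])
                        or np.array_equal(hap, parent[1]))

    def test_gametes_obey_parental_homozygosity(self, default_sim):
        """Mendelian mosaic check on the genotyped trios: wherever a parent
        is homozygous, the transmitted allele equals the parental allele."""
        haps, samples = default_sim["haps"], default_sim["samples"]
        tab = samples.table.set_index("sample_id")
        for sid in samples.ids("affected"):
            child = haps.alleles[haps.sample_index(sid)]
            for parent_id, hap in ((tab.loc[sid, "sire_id"], child[0]),
                                   (tab.loc[sid, "dam_id"], child[1])):
                parent = haps.alleles[haps.sample_index(parent_id)]
                hom = parent[0] == parent[1]
                assert np.array_equal(hap[hom], parent[0][hom])

    def test_founder_generation_near_hardy_weinberg(self):
        """Genotypes of animals bred from random founder pairs pass the exact
        HWE test at alpha 0.001 at >= 99% of loci, aggregated over seeds."""
        n_pass = n_tot = 0
        for seed in (101, 202, 303):
            cfg = SimulationConfig(seed=seed, **SMALL)
            haps, _, _, samples, _ = simulate_population(cfg)
            controls = samples.ids("control")
            d = haps.subset_samples(controls).dosages()
            for j in range(d.shape[1]):
                col = d[:, j]
                p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                   int((col == 2).sum()))
                n_pass += p > 0.001
                n_tot += 1
        assert n_pass / n_tot >= 0.99

    def test_impossible_demand_fails_naming_the_budget(self):
        cfg = SimulationConfig(seed=1, retry_budget=5, recombination_rate=40.0,
                               **SMALL)
        with pytest.raises(SimulationError, match="retry budget|redraws"):
            simulate_population(cfg)


class TestRegionVariants:
    def test_single_variant_is_the_causal_one(self):
        cfg = SimulationConfig(seed=9, **{**SMALL, "n_region_variants": 1})
        haps, _, _, samples, truth = simulate_population(cfg)
        recs = simulate_region_variants(cfg, truth, samples)
        assert len(recs) == 1
        v = recs[0]
        assert v.variant_id == truth.causal_variant_id
        assert v.consequence == "stop_gained"
        for sid in samples.ids("affected"):
            assert v.genotypes[sid] == HOM_ALT
        for sid in samples.ids("obligate_carrier"):
            assert v.genotypes[sid] == HET

    def test_causal_never_hom_alt_in_panel(self, default_sim, default_variants):
        panel = default_sim["samples"].ids("panel_healthy")
        causal = next(v for v in default_variants
                      if v.variant_id == default_sim["truth"].causal_variant_id)
        assert all(causal.genotypes[p] != HOM_ALT for p in panel)

    def test_hom_alt_count_in_affected_matches_brute_force_scan(
            self, default_sim, default_variants):
        aff = default_sim["samples"].ids("affected")[0]
        count = sum(1 for v in default_variants if v.genotypes[aff] == HOM_ALT)
        brute = 0
        for v in default_variants:
            brute += int(v.genotypes[aff] == HOM_ALT)
        assert count == brute
        assert 0 < count < len(default_variants)

    def test_variant_positions_inside_region_and_unique(self, default_sim,
                                                        default_variants):
        lo, hi = default_sim["truth"].carrier_region_bp
        pos = [v.position_bp for v in default_variants]
        assert all(lo <= p <= hi for p in pos)
        assert len(set(pos)) == len(pos)

    def test_adding_variants_does_not_perturb_genotypes(self):
        base = SimulationConfig(seed=4, **SMALL)
        more = SimulationConfig(seed=4, **{**SMALL, "n_region_variants": 80})
        a = simulate_population(base)
        b = simulate_population(more)
        assert np.array_equal(a[1].dosages, b[1].dosages)


class TestFixtureSet:
    def test_written_artefacts_reload_consistently(self, tmp_path):
        cfg = SimulationConfig(seed=6, **SMALL)
        paths = write_fixture_set(cfg, tmp_path)
        gm, _ = read_ped_map(paths["ped"], paths["map"])
        haps, genotypes, markers, samples, truth = simulate_population(cfg)
        assert np.array_equal(gm.dosages, genotypes.dosages)
        hm = read_haplotypes(paths["haplotypes"], gm.markers)
        assert np.array_equal(hm.alleles, haps.alleles)
        st = read_sample_table(paths["samples"])
        assert st.ids("affected") == samples.ids("affected")
        lo, hi = cfg.carrier_region_bp
        vcf = read_region_vcf(paths["vcf"],
                              f"{cfg.carrier_haplotype_chromosome}:{lo}-{hi}")
        assert len(vcf) == cfg.n_region_variants
        recs = simulate_region_variants(cfg, truth, samples)
        for orig, back in zip(sorted(recs, key=lambda r: r.position_bp),
                              vcf.records):
            assert back.genotypes == orig.genotypes
            assert back.consequence == orig.consequence
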