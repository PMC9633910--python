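"""Synthetic population, pooling, pileup and Sanger-call generators."""

import numpy as np
import pytest
from scipy import stats

from mtwa.errors import ConfigError, DataError
from mtwa.genemodels import GeneModel
from mtwa.simulate import (EffectTable, SimulationConfig, annotate_individuals,
                           assign_phenotypes, make_pools, simulate_pileup,
                           simulate_population, simulate_sanger)


def flat_locus(n_bases: int = 5000, seed: int = 1):
    """A featureless single-exon interval for rate calibration tests."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n_bases)])
    model = GeneModel("FLAT", "chrF", "+", exons=[(1, n_bases)])
    return [model], {"chrF": seq}


def dummy_population(n: int):
    from mtwa.simulate import SimulatedIndividual

    return [SimulatedIndividual(f"M2-{i:04d}") for i in range(1, n + 1)]


class TestSimulatePopulation:
    def test_zero_rate_gives_no_variants(self):
        models, reference = flat_locus(500)
        cfg = SimulationConfig(population_size=50, per_base_mutation_rate=0.0, seed=3)
        inds = simulate_population(cfg, models, reference)
        assert all(not ind.variants for ind in inds)

    def test_mean_variant_count_matches_brute_force_recount(self):
        """rate 1e-3 over 5000 bases, 1000 plants: mean count within 3 SE of 5,
        where the count is independently recounted from the emitted records."""
        models, reference = flat_locus(5000)
        cfg = SimulationConfig(population_size=1000, per_base_mutation_rate=1e-3, seed=9)
        inds = simulate_population(cfg, models, reference)
        recount = {}
        for ind in inds:
            for v in ind.variants:
                recount[ind.individual_id] = recount.get(ind.individual_id, 0) + 1
        counts = np.array([recount.get(ind.individual_id, 0) for ind in inds])
        se = np.sqrt(5000 * 1e-3 * (1 - 1e-3) / 1000)
        assert abs(counts.mean() - 5.0) < 3 * se
        assert counts.sum() == sum(len(ind.variants) for ind in inds)

    def test_alleles_consistent_with_reference(self):
        models, reference = flat_locus(2000)
        cfg = SimulationConfig(population_size=100, per_base_mutation_rate=1e-3, seed=5)
        for ind in simulate_population(cfg, models, reference):
            for v in ind.variants:
                if v.ref != "-":
                    assert reference[v.chrom][v.pos - 1] == v.ref[0]
                assert models[0].span[0] <= v.pos <= models[0].span[1]
                assert set(v.genotype) <= {v.ref, v.alt}

    def test_empty_model_list_rejected(self):
        with pytest.raises(ConfigError):
            simulate_population(SimulationConfig(), [], {})

    def test_interval_outside_reference_rejected(self):
        model = GeneModel("G", "chrF", "+", exons=[(1, 100)])
        with pytest.raises(ConfigError):
            simulate_population(SimulationConfig(), [model], {"chrF": "ACGT" * 10})

    def test_fixed_seed_reproduces_population(self):
        from mtwa.io import population_frame

        models, reference = flat_locus(3000)
        cfg = SimulationConfig(population_size=200, per_base_mutation_rate=5e-4, seed=21)
        a = population_frame(simulate_population(cfg, models, reference))
        b = population_frame(simulate_population(cfg, models, reference))
        assert a.to_csv(sep="\t") == b.to_csv(sep="\t")


class TestMakePools:
    def test_published_pool_arithmetic(self):
        pool_set = make_pools(dummy_population(3872), 8)
        assert pool_set.n_pools == 484
        assert pool_set.wt.pool_id == "WT" and not pool_set.wt.members

    def test_single_full_pool(self):
        pool_set = make_pools(dummy_population(8), 8)
        assert pool_set.n_pools == 1
        assert len(pool_set.pools[0].member_ids) == 8

    def test_twelve_pools_hold_96_individuals(self):
        pool_set = make_pools(dummy_population(96), 8)
        assert pool_set.n_pools == 12
        assert sum(len(p.members) for p in pool_set.pools) == 96

    def test_pools_partition_population(self):
        inds = dummy_population(100)
        pool_set = make_pools(inds, 8)  # remainder of 4 -> short final pool
        seen = [m for p in pool_set.pools for m in p.member_ids]
        assert seen == [i.individual_id for i in inds]
        assert len(set(seen)) == len(seen)
        assert len(pool_set.pools[-1].members) == 4

    def test_errors(self):
        with pytest.raises(ConfigError):
            make_pools(dummy_population(4), 8)
        with pytest.raises(ConfigError):
            make_pools(dummy_population(10), 1)


class TestSimulatePileup:
    @pytest.mark.parametrize("zygosity,expected_vaf", [("hom", 2 / 16), ("het", 1 / 16)])
    def test_expected_vaf_counts_carrier_haplotypes(self, zygosity, expected_vaf):
        """One carrier in an 8-plex pool: expected VAF is haplotypes/16; the
        heterozygous case sits exactly on the 1/16 retention threshold."""
        from mtwa.simulate import InducedVariant

        inds = dummy_population(8)
        inds[3].variants.append(InducedVariant("chrF", 10, "A", "G", zygosity))
        pool = make_pools(inds, 8).pools[0]
        freqs = pool.allele_frequencies("chrF", 10, "A")
        assert freqs["G"] == pytest.approx(expected_vaf)
        rng = np.random.default_rng(0)
        site = simulate_pileup(pool, "chrF", 10, "A", 50000, 0.0, rng, fixed_depth=True)
        assert site.depth == 50000
        assert site.counts["G"] / site.depth == pytest.approx(expected_vaf, abs=0.005)

    def test_enumerated_pools_match_haplotype_counting(self):
        """Exact combinatorial check across all carrier configurations of a
        4-plex pool: expected frequency equals carriers' haplotypes / 8."""
        from mtwa.simulate import InducedVariant

        for n_hom in range(5):
            for n_het in range(5 - n_hom):
                inds = dummy_population(4)
                for i in range(n_hom):
                    inds[i].variants.append(InducedVariant("c", 1, "A", "T", "hom"))
                for i in range(n_hom, n_hom + n_het):
                    inds[i].variants.append(InducedVariant("c", 1, "A", "T", "het"))
                pool = make_pools(inds, 4).pools[0]
                freqs = pool.allele_frequencies("c", 1, "A")
                assert freqs.get("T", 0.0) == pytest.approx((2 * n_hom + n_het) / 8)

    def test_depth_10000_matches_multinomial_resampling_oracle(self):
        """Empirical VAF of a hom carrier agrees with direct binomial resampling."""
        from mtwa.simulate import InducedVariant

        inds = dummy_population(8)
        inds[0].variants.append(InducedVariant("c", 5, "A", "T", "hom"))
        pool = make_pools(inds, 8).pools[0]
        rng = np.random.default_rng(17)
        depth = 10000
        site = simulate_pileup(pool, "c", 5, "A", depth, 0.0, rng, fixed_depth=True)
        vaf = site.counts["T"] / site.depth
        oracle = np.random.default_rng(99).binomial(depth, 0.125, size=2000) / depth
        se = oracle.std()
        assert abs(vaf - 0.125) < 3 * se
        assert abs(oracle.mean() - 0.125) < 3 * se / np.sqrt(2000)

    def test_counts_sum_to_depth_and_error_spreads(self):
        pool = make_pools(dummy_population(8), 8).pools[0]
        rng = np.random.default_rng(2)
        site = simulate_pileup(pool, "c", 1, "A", 5000, 0.01, rng, fixed_depth=True)
        assert site.depth == 5000
        assert sum(site.counts.values()) == 5000
        err = sum(site.counts[b] for b in "CGT")
        se = np.sqrt(5000 * 0.01 * 0.99)
        assert abs(err - 50) < 4 * se

    def test_bad_depth_rejected(self):
        pool = make_pools(dummy_population(8), 8).pools[0]
        with pytest.raises(ConfigError):
            simulate_pileup(pool, "c", 1, "A", 0, 0.0, np.random.default_rng(0))


class TestSimulateSanger:
    def test_zero_discordance_returns_truth(self):
        models, reference = flat_locus(2000)
        cfg = SimulationConfig(population_size=50, per_base_mutation_rate=2e-3, seed=8)
        inds = simulate_population(cfg, models, reference)
        rng = np.random.default_rng(0)
        for ind in inds:
            positions = [(v.chrom, v.pos) for v in ind.variants]
            calls = simulate_sanger(ind, positions, reference, 0.0, rng)
            for v in ind.variants:
                assert calls[(v.chrom, v.pos)] == v.genotype

    def test_discordance_rate_matches_binomial_oracle(self):
        """10,000 sites at discordance 0.1: confirmed fraction within 3 SE of 0.9."""
        from mtwa.simulate import InducedVariant, SimulatedIndividual

        n = 10000
        reference = {"c": "A" * (n + 1)}
        ind = SimulatedIndividual("x")
        for p in range(1, n + 1):
            ind.variants.append(InducedVariant("c", p, "A", "G", "hom"))
        rng = np.random.default_rng(4)
        calls = simulate_sanger(ind, [("c", p) for p in range(1, n + 1)],
                                reference, 0.1, rng)
        confirmed = sum(calls[("c", p)] == ("G", "G") for p in range(1, n + 1))
        se = np.sqrt(n * 0.9 * 0.1)
        assert abs(confirmed - 0.9 * n) < 3 * se

    def test_forced_discordance_reverts_to_wt(self):
        from mtwa.simulate import InducedVariant, SimulatedIndividual

        reference = {"c": "ACGTACGT"}
        ind = SimulatedIndividual("x", [InducedVariant("c", 3, "G", "T", "hom")])
        calls = simulate_sanger(ind, [("c", 3)], reference, 0.0,
                                np.random.default_rng(0),
                                forced_discordant=frozenset({("c", 3)}))
        assert calls[("c", 3)] == ("G", "G")


class TestPhenotypes:
    def _annotated(self, demo_targets, variants=()):
        from mtwa.simulate import InducedVariant, SimulatedIndividual

        models, reference = demo_targets
        ind = SimulatedIndividual("x", list(variants))
        annotate_individuals([ind], models, reference)
        return ind, models, reference

    def test_no_variant_line_hits_wt_means_at_zero_noise(self, demo_targets):
        ind, _, _ = self._annotated(demo_targets)
        cfg = SimulationConfig(noise_sd_length=0.0, noise_sd_width=0.0)
        assign_phenotypes([ind], EffectTable.default_grain_effects(), cfg,
                          np.random.default_rng(0))
        assert ind.true_length == pytest.approx(9.31)
        assert ind.true_width == pytest.approx(2.03)
        assert np.allclose(ind.length_replicates, 9.31)

    def test_osr_truncation_lengthens_grain_to_10_22(self, demo_targets):
        """A stop in the OSR domain adds +0.91 mm: mutant mean 10.22 at zero noise."""
        from mtwa.annotate import classify_variant
        from mtwa.simulate import InducedVariant

        models, reference = demo_targets
        gs3 = next(m for m in models if m.gene_id == "GS3")
        variant = None
        for residue in range(12, 80):
            for off in range((residue - 1) * 3, residue * 3):
                pos = gs3.cds_positions()[off]
                ref = reference[gs3.chrom][pos - 1]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    if classify_variant(gs3, reference, pos, ref, alt).klass == "stopgain":
                        variant = InducedVariant(gs3.chrom, pos, ref, alt, "hom")
                        break
                if variant:
                    break
            if variant:
                break
        assert variant is not None
        ind, _, _ = self._annotated(demo_targets, [variant])
        cfg = SimulationConfig(noise_sd_length=0.0, noise_sd_width=0.0)
        assign_phenotypes([ind], EffectTable.default_grain_effects(), cfg,
                          np.random.default_rng(0))
        assert ind.true_length == pytest.approx(10.22)

    def test_zero_effect_phenotypes_are_normal_by_ks(self, demo_targets):
        """All-zero effect table: replicate lengths are Normal(9.31, 0.18)."""
        models, reference = demo_targets
        cfg = SimulationConfig(population_size=167, per_base_mutation_rate=0.0,
                               noise_sd_length=0.18, seed=6)
        rng = np.random.default_rng(6)
        inds = simulate_population(cfg, models, reference, rng)
        annotate_individuals(inds, models, reference)
        assign_phenotypes(inds, EffectTable(), cfg, rng)
        values = np.concatenate([ind.length_replicates for ind in inds])
        assert values.size >= 5000
        p = stats.kstest(values, "norm", args=(9.31, 0.18)).pvalue
        assert p > 0.01

    def test_unannotated_variants_rejected(self, demo_targets):
        from mtwa.simulate import InducedVariant, SimulatedIndividual

        ind = SimulatedIndividual("x", [InducedVariant("chr3", 1500, "A", "G", "hom")])
        cfg = SimulationConfig()
        with pytest.raises(DataError):
            assign_phenotypes([ind], EffectTable(), cfg, np.random.default_rng(0))

    def test_probability_validation(self):
        with pytest.raises(Exception):
            SimulationConfig(per_base_mutation_rate=1.5)
        with pytest.raises(Exception):
            SimulationConfig(population_size=4, pool_size=8)
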