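import numpy as np
import pytest

from triabc import (
    HeterogeneitySubmodel,
    LocusSpec,
    SpeciesTrio,
    draw_genomic_factors,
    mutate_fixed,
    mutate_theta,
    sample_parameters,
    simulate_dataset,
    simulate_genealogy,
)
from triabc.model_space import ScenarioCategory

from conftest import isolation_draw, panmictic_draw


class TestGenomicFactors:
    def test_homogeneous_submodel_gives_all_ones(self):
        d = sample_parameters(ScenarioCategory("AM", "SI"),
                              HeterogeneitySubmodel(False, False), rng=0)
        f = draw_genomic_factors(d.submodel, d, 100, rng=1)
        assert np.all(f.ne == 1.0) and np.all(f.mig == 1.0)

    def test_ne_factors_average_to_one(self):
        d = sample_parameters(ScenarioCategory("AM", "SI"),
                              HeterogeneitySubmodel(True, False), rng=0)
        d = type(d)(**{**d.asdict(), "category": d.category,
                       "submodel": d.submodel,
                       "ne_shape_a": 2.0, "ne_shape_b": 2.0})
        f = draw_genomic_factors(d.submodel, d, 10_000, rng=2)
        assert abs(f.ne.mean() - 1.0) < 0.02
        assert np.all(f.mig == 1.0)

    def test_uniform_migration_factors(self):
        d = sample_parameters(ScenarioCategory("AM", "SI"),
                              HeterogeneitySubmodel(False, True), rng=0)
        d = type(d)(**{**d.asdict(), "category": d.category,
                       "submodel": d.submodel,
                       "mig_shape_a": 1.0, "mig_shape_b": 1.0})
        f = draw_genomic_factors(d.submodel, d, 10_000, rng=3)
        assert np.all((f.mig >= 0) & (f.mig <= 1))
        assert abs(f.mig.mean() - 0.5) < 0.02

    def test_nonpositive_n_loci_rejected(self):
        d = sample_parameters(ScenarioCategory("AM", "SI"),
                              HeterogeneitySubmodel(False, False), rng=0)
        with pytest.raises(ValueError):
            draw_genomic_factors(d.submodel, d, 0)


class TestGenealogies:
    def test_one_sequence_per_population_coalesces_twice(self):
        trio = SpeciesTrio(n_seq_p1=1, n_seq_p2=1, n_seq_p3=1)
        d = isolation_draw(10_000, t12=5e4, t123=1e5)
        ts = simulate_genealogy(d, trio, rng=1)
        tree = ts.first()
        internal = [u for u in tree.nodes() if not tree.is_leaf(u)]
        assert ts.num_samples == 3
        assert len(internal) == 2

    def test_mean_tmrca_matches_closed_form(self):
        # panmictic sample of n=6: E[TMRCA] = 4N(1 - 1/n) generations
        n_dip = 10_000
        trio = SpeciesTrio(n_seq_p1=2, n_seq_p2=2, n_seq_p3=2)
        d = panmictic_draw(n_dip)
        rng = np.random.default_rng(12)
        tmrcas = []
        for _ in range(3000):
            ts = simulate_genealogy(d, trio, rng=rng)
            tmrcas.append(ts.first().time(ts.first().root))
        expected = 4 * n_dip * (1 - 1 / 6)
        se = np.std(tmrcas) / np.sqrt(len(tmrcas))
        assert abs(np.mean(tmrcas) - expected) < 3 * se

    def test_no_migration_coalescence_predates_root_split(self):
        trio = SpeciesTrio(n_seq_p1=1, n_seq_p2=1, n_seq_p3=1)
        d = isolation_draw(1000, t12=1e5, t123=5e5)
        rng = np.random.default_rng(5)
        for _ in range(50):
            ts = simulate_genealogy(d, trio, rng=rng)
            tree = ts.first()
            assert tree.tmrca(0, 2) >= 5e5
            assert tree.tmrca(1, 2) >= 5e5

    def test_ne_factor_rescales_coalescence(self):
        trio = SpeciesTrio(n_seq_p1=2, n_seq_p2=2, n_seq_p3=2)
        d = panmictic_draw(50_000)
        rng = np.random.default_rng(9)
        def mean_tmrca(factor):
            vals = []
            for _ in range(300):
                t = simulate_genealogy(d, trio, ne_factor=factor, rng=rng).first()
                vals.append(t.time(t.root))
            return np.mean(vals)

        assert mean_tmrca(0.1) < mean_tmrca(1.0)


class TestMutationModes:
    def test_zero_rate_is_always_monomorphic(self):
        trio = SpeciesTrio(n_seq_p1=2, n_seq_p2=2, n_seq_p3=2)
        d = panmictic_draw(1000)
        ts = simulate_genealogy(d, trio, rng=3)
        assert mutate_theta(ts, LocusSpec(500), 0.0, trio, rng=1) is None

    def test_watterson_expectation(self):
        # E[S] = theta * a_{n-1} with theta = 4 N mu L
        n_dip, mu, L = 250_000, 3e-9, 1000
        trio = SpeciesTrio(n_seq_p1=4, n_seq_p2=4, n_seq_p3=2)
        d = panmictic_draw(n_dip)
        rng = np.random.default_rng(21)
        spec = LocusSpec(L)
        counts = []
        for _ in range(4000):
            ts = simulate_genealogy(d, trio, rng=rng)
            loc = mutate_theta(ts, spec, mu, trio, rng=rng)
            counts.append(0 if loc is None else loc.n_sites)
        a9 = sum(1 / i for i in range(1, 10))
        expected = 4 * n_dip * mu * L * a9
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_theta_mode_determinism(self):
        trio = SpeciesTrio(n_seq_p1=3, n_seq_p2=3, n_seq_p3=2)
        d = panmictic_draw(100_000)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            ts = simulate_genealogy(d, trio, rng=rng)
            out.append(mutate_theta(ts, LocusSpec(600), 3e-8, trio, rng=rng))
        assert np.array_equal(out[0].genotypes, out[1].genotypes)
        assert np.array_equal(out[0].positions, out[1].positions)

    def test_fixed_mode_forces_snp_count(self):
        trio = SpeciesTrio(n_seq_p1=3, n_seq_p2=3, n_seq_p3=2)
        d = panmictic_draw(1000)
        ts = simulate_genealogy(d, trio, rng=4)
        loc = mutate_fixed(ts, 5, trio, 400, rng=5)
        assert loc.n_sites == 5
        assert loc.genotypes.shape == (8, 5)
        # every site segregating in the pooled sample
        colsums = loc.genotypes.sum(axis=0)
        assert np.all((colsums > 0) & (colsums < 8))

    def test_fixed_mode_rejects_zero_snps(self):
        trio = SpeciesTrio(n_seq_p1=2, n_seq_p2=2, n_seq_p3=2)
        ts = simulate_genealogy(panmictic_draw(1000), trio, rng=6)
        with pytest.raises(ValueError):
            mutate_fixed(ts, 0, trio, 400)


class TestSimulateDataset:
    def test_fixed_mode_returns_one_locus_per_spec(self, small_trio):
        d = isolation_draw(20_000, t12=1e5, t123=1e6)
        rng = np.random.default_rng(1)
        specs = [LocusSpec(400 + i, observed_snp_count=1 + i % 91,
                           locus_id=f"L{i}") for i in range(60)]
        loci = simulate_dataset(d, specs, mode="fixed_snp", trio=small_trio,
                                rng=rng)
        assert len(loci) == 60
        assert [l.n_sites for l in loci] == [s.observed_snp_count for s in specs]

    def test_theta_mode_excludes_monomorphic(self, small_trio):
        d = panmictic_draw(200)  # tiny theta: most loci monomorphic
        specs = [LocusSpec(400) for _ in range(200)]
        loci = simulate_dataset(d, specs, mode="theta", trio=small_trio, rng=2)
        assert len(loci) < 200
        for loc in loci:
            colsums = loc.genotypes.sum(axis=0)
            assert np.all((colsums > 0) & (colsums < loc.genotypes.shape[0]))

    def test_dataset_determinism(self, small_trio):
        d = sample_parameters(ScenarioCategory("SC", "P3BOTH"),
                              HeterogeneitySubmodel(True, True), rng=8)
        specs = [LocusSpec(500) for _ in range(20)]
        a = simulate_dataset(d, specs, trio=small_trio, rng=np.random.default_rng(9))
        b = simulate_dataset(d, specs, trio=small_trio, rng=np.random.default_rng(9))
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            assert np.array_equal(la.genotypes, lb.genotypes)

    def test_snp_table_round_trip(self, small_trio, tmp_path):
        from triabc.coalsim import read_snp_table, write_snp_table
        d = isolation_draw(50_000, t12=2e5, t123=2e6)
        specs = [LocusSpec(400 + i, locus_id=f"L{i}") for i in range(15)]
        loci = simulate_dataset(d, specs, trio=small_trio, rng=41)
        p = tmp_path / "snp_table.tsv"
        write_snp_table(loci, p)
        back = read_snp_table(p)
        assert len(back) == len(loci)
        for a, b in zip(loci, back):
            assert a.locus_id == b.locus_id
            assert a.length_bp == b.length_bp
            assert np.array_equal(a.genotypes, b.genotypes)
            assert np.array_equal(a.pops, b.pops)
            assert np.array_equal(a.positions, b.positions)

    def test_empty_specs_rejected(self, small_trio):
        d = panmictic_draw(1000)
        with pytest.raises(ValueError):
            simulate_dataset(d, [], trio=small_trio)

    def test_split_depth_increases_fixed_differences(self, small_trio):
        # deeper outer splits accumulate more fixed differences to P3
        from triabc.sumstats import site_pattern_counts
        rng = np.random.default_rng(31)
        means = []
        for t123 in (2e5, 1e6, 5e6):
            d = isolation_draw(10_000, t12=1e5, t123=t123)
            specs = [LocusSpec(500) for _ in range(200)]
            loci = simulate_dataset(d, specs, trio=small_trio, rng=rng)
            sf = [site_pattern_counts(l.pop_matrix(0), l.pop_matrix(2))[1]
                  for l in loci]
            means.append(np.mean(sf))
        assert means[0] < means[1] < means[2]

    def test_ne_heterogeneity_inflates_pi_variance(self, small_trio):
        from triabc.sumstats import pi
        base = panmictic_draw(100_000)
        het = type(base)(**{**base.asdict(), "category": base.category,
                            "submodel": HeterogeneitySubmodel(True, False),
                            "ne_shape_a": 0.5, "ne_shape_b": 0.5})
        specs = [LocusSpec(500) for _ in range(2000)]
        pis = {}
        for tag, d in (("hom", base), ("het", het)):
            loci = simulate_dataset(d, specs, trio=small_trio,
                                    rng=np.random.default_rng(13))
            pis[tag] = np.array([pi(l.genotypes, l.length_bp) for l in loci])
        assert pis["het"].var() > pis["hom"].var()
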