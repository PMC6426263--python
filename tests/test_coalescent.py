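import numpy as np
import pytest
from scipy import stats

from sweepscan.coalescent import (DEFAULT_MS_COMMAND, default_three_population_model,
                                  empirical_pvalue, migration_from_ancestry,
                                  parse_ms_command, pbs_null, simulate,
                                  to_ms_command)
from sweepscan.errors import (FormatError, ModelError, UnsupportedFeatureError)

S15_STYLE = ("ms 300 10000 –s 1 –t 0.01 –I 3 100 100 100 –eg 0.002 1 50 "
             "–em 0.002 1 3 31.0 −em 0.002 3 1 4.46 -ej 0.025 3 1 "
             "–en 0.06 1 1.0 –en 0.06 2 1.0 –ej 0.06 2 1 –en 0.1 1 0.5")


class TestParser:
    def test_study_style_command_parses_with_unicode_dashes(self):
        m = parse_ms_command(S15_STYLE)
        assert m.nsam == 300 and m.npop == 3
        assert m.fixed_s == 1 and m.theta == pytest.approx(0.01)
        joins = [e for e in m.events if e.kind == "join"]
        assert [(e.time, e.pop, e.pop2) for e in joins] == [(0.025, 2, 0), (0.06, 1, 0)]

    def test_join_semantics_population_three_into_one(self):
        m = parse_ms_command("ms 30 1 -s 1 -I 3 10 10 10 -ej 0.025 3 1")
        e = m.events[0]
        assert e.kind == "join" and e.pop == 2 and e.pop2 == 0  # 0-based

    def test_island_without_rate_has_zero_migration(self):
        m = parse_ms_command("ms 30 1 -t 1 -I 3 10 10 10")
        assert np.all(m.migration == 0)

    def test_island_symmetric_rate_divided_among_demes(self):
        m = parse_ms_command("ms 30 1 -t 1 -I 3 10 10 10 2.0")
        off = m.migration[0, 1]
        assert off == pytest.approx(1.0)
        assert np.all(np.diag(m.migration) == 0)

    def test_round_trip_serialization(self):
        m1 = parse_ms_command(S15_STYLE)
        m2 = parse_ms_command(to_ms_command(m1))
        assert m1.sample_sizes == m2.sample_sizes
        assert m1.theta == m2.theta and m1.fixed_s == m2.fixed_s
        assert [(e.time, e.kind, e.pop, e.pop2, e.value) for e in m1.events] == \
               [(e.time, e.kind, e.pop, e.pop2, e.value) for e in m2.events]
        np.testing.assert_allclose(m1.migration, m2.migration)

    def test_unsupported_flag_rejected(self):
        with pytest.raises(UnsupportedFeatureError):
            parse_ms_command("ms 10 1 -t 1 -r 10 1000")

    def test_malformed_numeric_and_unknown_population(self):
        with pytest.raises(FormatError):
            parse_ms_command("ms 10 1 -t abc")
        with pytest.raises(FormatError):
            parse_ms_command("ms 30 1 -s 1 -I 3 10 10 10 -ej 0.1 5 1")

    def test_sample_sizes_must_sum_to_total(self):
        with pytest.raises(FormatError):
            parse_ms_command("ms 25 1 -s 1 -I 3 10 10 10")


class TestSimulator:
    def test_pairwise_tmrca_mean_is_one(self):
        m = parse_ms_command("ms 2 1 -t 1")
        reps = simulate(m, 3000, seed=1)
        t2 = np.array([r.tmrca for r in reps])
        se = t2.std() / np.sqrt(len(t2))
        assert abs(t2.mean() - 1.0) < 3 * se

    def test_watterson_segregating_sites(self):
        m = parse_ms_command("ms 10 1 -t 1")
        reps = simulate(m, 4000, seed=2)
        s = np.array([r.alleles.shape[1] for r in reps])
        expect = sum(1.0 / i for i in range(1, 10))
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - expect) < 3 * se

    def test_fixed_s_invariant_one_polymorphic_site(self):
        m = parse_ms_command("ms 12 1 -s 1 -I 2 6 6 1.0")
        for r in simulate(m, 300, seed=3):
            assert r.alleles.shape[1] == 1
            assert 1 <= r.alleles[:, 0].sum() <= 11

    def test_disconnected_demes_raise_model_error(self):
        m = parse_ms_command("ms 4 1 -t 1 -I 2 2 2")
        with pytest.raises(ModelError):
            simulate(m, 1, seed=4)

    def test_seeded_runs_bit_reproducible(self):
        m = parse_ms_command("ms 10 1 -t 2 -I 2 5 5 1.0 -ej 0.8 2 1")
        a = simulate(m, 20, seed=9)
        b = simulate(m, 20, seed=9)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.alleles, rb.alleles)
            assert ra.tmrca == rb.tmrca

    def test_growth_shortens_coalescence_times(self):
        const = simulate(parse_ms_command("ms 2 1 -t 1"), 1500, seed=5)
        grown = simulate(parse_ms_command("ms 2 1 -t 1 -g 1 5"), 1500, seed=5)
        assert np.mean([r.tmrca for r in grown]) < 0.8 * np.mean(
            [r.tmrca for r in const])

    @pytest.mark.parametrize("cmd,msp_split", [
        ("ms 20 1 -t 1 -I 2 10 10 1.0", None),        # island, M = 1
        ("ms 20 1 -t 1 -I 2 10 10 -ej 0.5 2 1", 0.5),  # clean split
    ])
    def test_agreement_with_independent_coalescent_oracle(self, cmd, msp_split):
        """E[S] and mean FST match msprime on the same two-deme model."""
        msprime = pytest.importorskip("msprime")
        from sweepscan.allele_stats import FreqTable, fst_per_snp

        reps = 1500
        model = parse_ms_command(cmd)
        ours = simulate(model, reps, seed=11)

        n_ref = 10_000.0  # arbitrary diploid size; one scaled unit = 2*N gens
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=n_ref)
        dem.add_population(name="p2", initial_size=n_ref)
        if msp_split is None:
            m = model.migration[0, 1] / (4 * n_ref)
            dem.set_migration_rate("p1", "p2", m)
            dem.set_migration_rate("p2", "p1", m)
        else:
            dem.add_population(name="anc", initial_size=n_ref)
            dem.add_population_split(time=msp_split * 2 * n_ref,
                                     derived=["p1", "p2"], ancestral="anc")
        mu = model.theta / (4 * n_ref)

        def stats_of(mats):
            s_counts, fsts = [], []
            for g in mats:
                s_counts.append(g.shape[1])
                if g.shape[1] == 0:
                    continue
                pa, pb = g[:10].mean(axis=0), g[10:].mean(axis=0)
                r = fst_per_snp(FreqTable("a", pa, np.full(g.shape[1], 10)),
                                FreqTable("b", pb, np.full(g.shape[1], 10)),
                                "hudson")
                fsts.extend(r.fst[r.ok])
            return np.asarray(s_counts, float), np.asarray(fsts, float)

        msp_mats = []
        seed_rng = np.random.default_rng(33)
        for ts in msprime.sim_ancestry(samples={"p1": 5, "p2": 5}, demography=dem,
                                       sequence_length=1, num_replicates=reps,
                                       random_seed=21):
            mts = msprime.sim_mutations(ts, rate=mu,
                                        random_seed=int(seed_rng.integers(1, 2**31)),
                                        discrete_genome=False)
            msp_mats.append(mts.genotype_matrix().T)
        s_ours, f_ours = stats_of([r.alleles for r in ours])
        s_msp, f_msp = stats_of(msp_mats)
        se = np.sqrt(s_ours.var() / reps + s_msp.var() / reps)
        assert abs(s_ours.mean() - s_msp.mean()) < 3 * se
        assert abs(f_ours.mean() - f_msp.mean()) < 0.03


class TestPbsNull:
    def test_symmetric_model_mean_near_zero_and_role_invariant(self):
        # near-panmixia: focal-branch excess vanishes and the null is
        # invariant to which deme plays the focal role
        m = parse_ms_command("ms 60 1 -s 1 -I 3 20 20 20 20.0")
        null = pbs_null(m, roles=(0, 1, 2), reps=800, seed=6)
        assert abs(null.snp.mean()) < 0.05
        rotated = pbs_null(m, roles=(1, 2, 0), reps=800, seed=66)
        assert stats.ks_2samp(null.snp, rotated.snp).pvalue > 0.01

    def test_window_null_is_group_means_of_snp_null(self):
        m = parse_ms_command("ms 30 1 -s 1 -I 3 10 10 10 5.0")
        null = pbs_null(m, roles=(0, 1, 2), reps=400, window_size=20, seed=7)
        expect = null.snp[:400].reshape(20, 20).mean(axis=1)
        np.testing.assert_allclose(null.window, expect)

    def test_stronger_drift_gives_stochastically_larger_null(self):
        base = "ms 30 1 -s 1 -I 3 10 10 10 -ej 0.3 2 1 -ej 0.6 3 1"
        small_focal = base + " -en 0 1 0.2"
        n1 = pbs_null(parse_ms_command(base), roles=(0, 1, 2), reps=600, seed=8)
        n2 = pbs_null(parse_ms_command(small_focal), roles=(0, 1, 2), reps=600, seed=9)
        res = stats.mannwhitneyu(n2.snp, n1.snp, alternative="greater")
        assert res.pvalue < 0.01

    def test_default_study_model_parses_and_simulates(self):
        model = default_three_population_model((20, 20, 20))
        null = pbs_null(model, roles=(0, 2, 1), reps=150, seed=10)
        assert len(null.snp) == 150
        assert np.isfinite(null.snp).all()
        assert parse_ms_command(DEFAULT_MS_COMMAND).npop == 3


class TestEmpiricalPvalue:
    def test_extremes_with_pseudo_count(self):
        null = np.arange(1.0, 10_001.0)
        assert empirical_pvalue(0.0, null) == 1.0
        assert empirical_pvalue(20_000.0, null) == pytest.approx(1 / 10_001)

    def test_requires_enough_null_values(self):
        with pytest.raises(ModelError):
            empirical_pvalue(1.0, np.arange(50.0))

    def test_randomized_transform_is_uniform_for_continuous_null(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=5000)
        obs = rng.normal(size=800)
        ps = np.array([empirical_pvalue(o, null, rng=rng) for o in obs])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_migration_from_ancestry_inverts_expected_ancestry():
    m = migration_from_ancestry(0.3, 0.023)
    assert 1 - np.exp(-m * 0.023 / 2) == pytest.approx(0.3, abs=1e-12)
    with pytest.raises(ModelError):
        migration_from_ancestry(1.0, 0.1)
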