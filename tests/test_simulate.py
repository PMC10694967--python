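"""Wright-Fisher mechanics: fitness model, meiosis, migration, drift."""

import numpy as np
import pytest

from structne import (Haplotype, Individual, MetapopState, advance_generation,
                      choose_parent_deme, inversion_fitness, make_gamete,
                      run_scenario)
from structne.config import (DemographyEvent, GenomeConfig, SampleSpec,
                             ScenarioConfig, InversionConfig)
from structne.simulate import (_offspring_parent_demes,
                               parent_deme_probabilities)


def drift_scenario(n, generations=10**6, mu=1e-12, map_rate=1e-12, L=1000):
    return ScenarioConfig(name="drift", family="panmictic", deme_sizes=(n,),
                          total_generations=generations,
                          genome=GenomeConfig(L, mu, map_rate, 1),
                          sample=SampleSpec(2), seed=0)


def one_snp_state(n, n_derived, pos=500, demes=None):
    demes = demes or (n,)
    H = np.zeros((2 * n, 1), dtype=np.uint8)
    H[:n_derived, 0] = 1
    return MetapopState(np.array([pos]), H, np.zeros(2 * n, bool), demes, 0)


class TestInversionFitness:
    def test_neutral_at_half(self):
        assert inversion_fitness(0.5) == 1.0

    @pytest.mark.parametrize("q,w", [(0.4, 1.02), (1.0, 0.9), (0.0, 1.1)])
    def test_direct_substitution(self, q, w):
        assert inversion_fitness(q) == pytest.approx(w)

    def test_monotone_decreasing_with_slope(self):
        qs = np.linspace(0, 1, 21)
        ws = np.array([inversion_fitness(q) for q in qs])
        assert np.all(np.diff(ws) < 0)
        slopes = np.diff(ws) / np.diff(qs)
        assert np.allclose(slopes, -0.2)

    @pytest.mark.parametrize("q", [-0.01, 1.01])
    def test_rejects_out_of_range(self, q):
        with pytest.raises(ValueError):
            inversion_fitness(q)


class TestMakeGamete:
    def test_identical_haplotypes_give_identical_gamete(self):
        muts = np.array([10, 500, 900], dtype=np.int64)
        parent = Individual(Haplotype(muts.copy()), Haplotype(muts.copy()))
        genome = GenomeConfig(1000, 1e-12, 0.01, 1)  # heavy recombination, no mutation
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = make_gamete(parent, genome, rng=rng)
            assert np.array_equal(g.mutations, muts)

    def test_no_crossovers_inside_inversion_in_heterozygote(self):
        parent = Individual(Haplotype(np.array([5]), carries_inversion=True),
                            Haplotype(np.array([900]), carries_inversion=False))
        genome = GenomeConfig(1000, 1e-12, 0.005, 1)  # ~5 crossovers per meiosis
        interval = (250, 750)
        rng = np.random.default_rng(1)
        inside = 0
        for _ in range(10_000):
            _, xpos = make_gamete(parent, genome, inversion_interval=interval,
                                  rng=rng, return_crossovers=True)
            inside += int(((xpos >= 250) & (xpos < 750)).sum())
        assert inside == 0

    def test_crossover_count_is_poisson_with_map_length_mean(self):
        parent = Individual(Haplotype(np.array([], dtype=np.int64)),
                            Haplotype(np.array([], dtype=np.int64)))
        genome = GenomeConfig(1_000_000, 1e-12, 1e-6, 1)  # 1 Morgan
        rng = np.random.default_rng(2)
        n = 100_000
        counts = np.empty(n)
        for i in range(n):
            _, xpos = make_gamete(parent, genome, rng=rng, return_crossovers=True)
            counts[i] = xpos.size
        se = np.sqrt(1.0 / n)  # Poisson(1): var = 1
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_inversion_flag_follows_midpoint_haplotype(self):
        # homozygous carrier: gamete always carries the inversion
        parent = Individual(Haplotype(np.array([], dtype=np.int64), True),
                            Haplotype(np.array([], dtype=np.int64), True))
        genome = GenomeConfig(1000, 1e-12, 0.001, 1)
        rng = np.random.default_rng(3)
        assert all(make_gamete(parent, genome, inversion_interval=(250, 750),
                               rng=rng).carries_inversion for _ in range(20))


class TestMigration:
    def test_no_migration_keeps_focal_deme(self):
        sc = ScenarioConfig(family="reciprocal_migration", deme_sizes=(50, 50),
                            migration_rate=0.0, total_generations=10)
        rng = np.random.default_rng(0)
        assert all(choose_parent_deme(1, sc, 5, rng) == 1 for _ in range(100))

    def test_two_demes_half_migration_is_symmetric(self):
        sc = ScenarioConfig(family="reciprocal_migration", deme_sizes=(50, 50),
                            migration_rate=0.5, total_generations=10)
        p = parent_deme_probabilities(0, sc)
        assert np.allclose(p, [0.5, 0.5])

    def test_island_model_foreign_deme_frequencies(self):
        # n = 10, m = 0.04: each specific foreign deme at 0.04/9
        sc = ScenarioConfig(family="reciprocal_migration", deme_sizes=(500,) * 10,
                            migration_rate=0.04, total_generations=10)
        rng = np.random.default_rng(4)
        n_draws = 1_000_000
        state = MetapopState(np.empty(0, np.int64), np.zeros((10_000, 0), np.uint8),
                             np.zeros(10_000, bool), (500,) * 10, 0)
        demes = _offspring_parent_demes(state, sc, [], (n_draws,) + (0,) * 9, 0, rng)
        freqs = np.bincount(demes, minlength=10) / n_draws
        p_foreign = 0.04 / 9
        se = np.sqrt(p_foreign * (1 - p_foreign) / n_draws)
        for d in range(1, 10):
            assert abs(freqs[d] - p_foreign) < 3 * se
        assert abs(freqs[0] - 0.96) < 3 * np.sqrt(0.96 * 0.04 / n_draws)

    def test_source_never_receives_migrants(self):
        sc = ScenarioConfig(family="source_sink", deme_sizes=(100, 50),
                            migration_rate=0.3, total_generations=10)
        assert np.allclose(parent_deme_probabilities(0, sc), [1.0, 0.0])
        assert np.allclose(parent_deme_probabilities(1, sc), [0.3, 0.7])

    def test_pulsed_migration_inactive_off_period(self):
        sc = ScenarioConfig(family="reciprocal_migration", deme_sizes=(50, 50),
                            migration_rate=0.5, migration_period=10,
                            total_generations=100)
        rng = np.random.default_rng(0)
        assert all(choose_parent_deme(0, sc, g, rng) == 0
                   for g in range(100) if g % 10)


class TestAdvanceGeneration:
    def test_no_variation_operators_copy_parents(self):
        sc = drift_scenario(2)
        rng = np.random.default_rng(5)
        st = one_snp_state(2, 1)
        parent_rows = {tuple(r) for r in st.haplotypes}
        nxt = advance_generation(st, sc, rng, prune=False)
        assert all(tuple(r) in parent_rows for r in nxt.haplotypes)

    def test_fixation_probability_matches_initial_frequency(self):
        # neutral WF: P(fix) = p0
        n, runs, p0 = 10, 2000, 0.3
        sc = drift_scenario(n)
        rng = np.random.default_rng(6)
        fixed = 0
        for _ in range(runs):
            st = one_snp_state(n, int(p0 * 2 * n))
            p = p0
            while 0.0 < p < 1.0:
                st = advance_generation(st, sc, rng, prune=False)
                p = st.haplotypes[:, 0].mean()
            fixed += p == 1.0
        se = np.sqrt(p0 * (1 - p0) / runs)
        assert abs(fixed / runs - p0) < 3 * se

    def test_admix_event_draws_parents_uniformly(self):
        sc = ScenarioConfig(
            family="synthetic", deme_sizes=(20,) * 5, total_generations=10,
            events=(DemographyEvent(5, "admix", {"size": 100}),))
        state = MetapopState(np.empty(0, np.int64), np.zeros((200, 0), np.uint8),
                             np.zeros(200, bool), (20,) * 5, 0)
        rng = np.random.default_rng(7)
        event = sc.events[0]
        demes = _offspring_parent_demes(state, sc, [event], (100_000,), 4, rng)
        freqs = np.bincount(demes, minlength=5) / demes.size
        se = np.sqrt(0.2 * 0.8 / demes.size)
        assert np.all(np.abs(freqs - 0.2) < 3 * se)

    def test_event_emptying_deme_rejected(self):
        sc = ScenarioConfig(
            family="panmictic", deme_sizes=(20,), total_generations=10,
            events=(DemographyEvent(10, "resize", {"deme": 0, "size": 1}),))
        st = one_snp_state(20, 5)
        with pytest.raises(Exception, match="fewer than 2"):
            advance_generation(st, sc, np.random.default_rng(0))

    def test_independent_drift_across_isolated_demes(self):
        # m = 0: allele-frequency increments uncorrelated between demes
        n = 50
        sc = ScenarioConfig(family="reciprocal_migration", deme_sizes=(n, n),
                            migration_rate=0.0, total_generations=10**6,
                            genome=GenomeConfig(1000, 1e-12, 1e-12, 1))
        H = np.zeros((4 * n, 1), dtype=np.uint8)
        H[:n, 0] = 1          # deme 0 at 0.5
        H[2 * n:3 * n, 0] = 1  # deme 1 at 0.5
        st = MetapopState(np.array([500]), H, np.zeros(4 * n, bool), (n, n), 0)
        rng = np.random.default_rng(8)
        T = 400
        p = np.empty((T + 1, 2))
        p[0] = 0.5, 0.5
        for t in range(T):
            st = advance_generation(st, sc, rng, prune=False)
            p[t + 1, 0] = st.haplotypes[:2 * n, 0].mean()
            p[t + 1, 1] = st.haplotypes[2 * n:, 0].mean()
        d = np.diff(p, axis=0)
        keep = (d != 0).any(axis=1)
        r = np.corrcoef(d[keep, 0], d[keep, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(keep.sum())


class TestInversionDynamics:
    def test_balancing_selection_restores_towards_half(self):
        # mean one-generation change in q has sign opposite to (q - 0.5)
        n = 100
        genome = GenomeConfig(1000, 1e-12, 1e-12, 1)
        sc = ScenarioConfig(family="inversion", deme_sizes=(n,),
                            total_generations=10**6, genome=genome,
                            inversion=InversionConfig(250, 750, 1.9, "balanced"))
        rng = np.random.default_rng(9)
        for q0, sign in ((0.75, -1), (0.25, +1)):
            base_flags = np.zeros(2 * n, bool)
            base_flags[:int(q0 * 2 * n)] = True
            deltas = np.empty(5000)
            for i in range(deltas.size):
                st = MetapopState(np.empty(0, np.int64),
                                  np.zeros((2 * n, 0), np.uint8),
                                  base_flags.copy(), (n,), 0)
                nxt = advance_generation(st, sc, rng)
                deltas[i] = nxt.inv_flags.mean() - q0
            se = deltas.std() / np.sqrt(deltas.size)
            assert sign * deltas.mean() > 3 * se

    def test_balanced_mode_settles_near_half(self):
        # terminal q within [0.3, 0.7] in >= 90% of replicates
        sc = ScenarioConfig(
            name="inv", family="inversion", deme_sizes=(100,),
            total_generations=400,
            genome=GenomeConfig(100_000, 1e-7, 1e-9, 10),
            inversion=InversionConfig(25_000, 75_000, 1.9, "balanced"),
            sample=SampleSpec(20), seed=11)
        states = run_scenario(sc)
        qs = np.array([st.inversion_frequency() for st in states])
        assert (np.abs(qs - 0.5) <= 0.2).mean() >= 0.9

    def test_recent_low_mode_introduces_late_at_low_frequency(self):
        sc = ScenarioConfig(
            name="inv-low", family="inversion", deme_sizes=(100,),
            total_generations=300,
            genome=GenomeConfig(100_000, 1e-7, 1e-9, 6),
            inversion=InversionConfig(25_000, 75_000, 0.2, "recent_low",
                                      introduce_time=5, initial_copies=20),
            sample=SampleSpec(20), seed=12)
        states = run_scenario(sc)
        qs = np.array([st.inversion_frequency() for st in states])
        assert np.all(qs > 0)
        assert qs.mean() < 0.35  # no time to climb to the balanced point


class TestRunScenario:
    def test_same_seed_bit_identical(self, toy_scenario):
        a = run_scenario(toy_scenario)
        b = run_scenario(toy_scenario)
        for x, y in zip(a, b):
            assert np.array_equal(x.positions, y.positions)
            assert np.array_equal(x.haplotypes, y.haplotypes)

    def test_replicates_are_distinct(self, toy_states):
        assert not np.array_equal(toy_states[0].positions, toy_states[1].positions)

    def test_neutral_equilibrium_diversity(self):
        # pi/site ~= theta/(1 + theta) after 10N generations (theta = 4*N*mu)
        n, mu, L = 100, 1e-5, 10_000
        sc = ScenarioConfig(name="eq", family="panmictic", deme_sizes=(n,),
                            total_generations=10 * n,
                            genome=GenomeConfig(L, mu, 1e-8, 20),
                            sample=SampleSpec(50), seed=2)
        states = run_scenario(sc)
        pis = []
        for st in states:
            p = st.haplotypes.mean(axis=0)
            nh = st.haplotypes.shape[0]
            pis.append((2 * p * (1 - p) * nh / (nh - 1)).sum() / L)
        theta = 4 * n * mu
        expected = theta / (1 + theta)
        assert abs(np.mean(pis) - expected) / expected < 0.15
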