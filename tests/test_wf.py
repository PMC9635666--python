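"""Wright-Fisher engine: determinism, drift, mutation, migration, sampling."""

import numpy as np
import pytest

from rhoflow import (
    MigrationSpec,
    advance_generation,
    build_schedule,
    draw_paired_sample,
    draw_sample,
    initialize_population,
    rescale,
    run_schedule,
)
from rhoflow.stats import diversity, hudson_fst, island_fst
from rhoflow._kernels import _copy_gametes_elem, _copy_gametes_py, copy_gametes

from conftest import equilibrate, make_params, zero_rate_params


def _noop_schedule(params):
    mig = MigrationSpec.from_nem(0.0, params.N_model)
    sched = build_schedule("continuous", mig, 1.0, params)
    return mig, sched


class TestDeterminismAndInvariants:
    def test_initialize_deterministic(self):
        p = make_params(20, 1000)
        a, b = initialize_population(p, 7), initialize_population(p, 7)
        for _ in range(20):
            mig, sched = _noop_schedule(p)
            advance_generation(a, mig, sched)
            advance_generation(b, mig, sched)
        assert np.array_equal(a.H, b.H)
        assert np.array_equal(a.positions, b.positions)

    def test_monomorphic_start_has_zero_diversity(self):
        p = make_params(20, 1000)
        s = initialize_population(p, 1)
        assert s.H.shape == (40, 0)

    def test_zero_rates_are_noop(self):
        p = zero_rate_params(20)
        mig, sched = _noop_schedule(p)
        state = initialize_population(p, 3)
        state.H = np.zeros((40, 2), dtype=np.uint8)  # monomorphic columns would be purged
        state.H[:, 0] = 1
        state.positions = np.array([10, 20])
        g0 = state.generation
        advance_generation(state, mig, sched)
        # fixed column purged, lost column dropped; no new variation arises
        assert state.H.shape[1] == 0
        assert state.generation == g0 + 1
        assert len(state.substitutions) == 1

    def test_purge_interval_does_not_affect_samples(self):
        p = make_params(30, 3000)
        mig, sched = _noop_schedule(p)
        samples = []
        for interval in (1, 7):
            state = initialize_population(p, 11)
            state.purge_interval = interval
            for _ in range(60):
                advance_generation(state, mig, sched)
            samples.append(draw_sample(state, 0, 15, seed=5))
        assert np.array_equal(samples[0].positions, samples[1].positions)
        assert np.array_equal(samples[0].H, samples[1].H)

    def test_kernel_variants_agree(self):
        rng = np.random.default_rng(0)
        parents = rng.integers(0, 2, (30, 200)).astype(np.uint8)
        row_a = rng.integers(0, 30, 40)
        row_b = rng.integers(0, 30, 40)
        k = rng.poisson(3, 40)
        off = np.zeros(41, dtype=np.int64)
        np.cumsum(k, out=off[1:])
        bp = np.concatenate([np.sort(rng.integers(0, 200, kk)) for kk in k]).astype(np.int64)
        outs = []
        for fn in (_copy_gametes_py, _copy_gametes_elem, copy_gametes):
            out = np.empty((40, 200), dtype=np.uint8)
            fn(parents, row_a.astype(np.int64), row_b.astype(np.int64), bp, off, out)
            outs.append(out)
        assert np.array_equal(outs[0], outs[1])
        assert np.array_equal(outs[0], outs[2])


class TestNeutralDynamics:
    def test_drift_decay_of_heterozygosity(self):
        """E[H_t] = H_0 (1 - 1/2N)^t for a single neutral locus."""
        N, t, reps = 50, 15, 300
        p = zero_rate_params(N)
        mig, sched = _noop_schedule(p)
        hets = []
        for rep in range(reps):
            state = initialize_population(p, 10_000 + rep)
            col = np.zeros((2 * N, 1), dtype=np.uint8)
            col[: N, 0] = 1  # frequency 1/2
            state.H = col
            state.positions = np.array([50])
            for _ in range(t):
                advance_generation(state, mig, sched)
            if state.H.shape[1]:
                q = state.H[:, 0].mean()
            else:
                q = 0.0 if not state.substitutions else 1.0
            hets.append(2 * q * (1 - q))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        got = np.mean(hets)
        se = np.std(hets) / np.sqrt(reps)
        assert abs(got - expected) < 4 * se + 0.01

    def test_mutation_influx_matches_poisson_mean(self):
        p = rescale(1.72e6, 5.49e-9, 2.23e-8, 100, 20_000)
        # 2 N mu L = 2 * 100 * 9.4428e-5 * 2e4 -- per-generation mutation count
        lam = 2 * 100 * p.mu_site_model * 20_000
        assert lam == pytest.approx(377.7, abs=0.2)
        mig, sched = _noop_schedule(p)
        state = initialize_population(p, 2)
        prev_pos = set()
        new_counts = []
        for _ in range(30):
            advance_generation(state, mig, sched)
            cur = set(state.positions.tolist())
            new_counts.append(len(cur - prev_pos))
            prev_pos = cur
        got = np.mean(new_counts)
        se = np.sqrt(lam / 30)
        assert abs(got - lam) < 4 * se

    def test_fixation_probability_of_unique_mutant(self):
        """A single neutral copy fixes with probability ~ 1/(2N)."""
        N, reps = 20, 800
        p = zero_rate_params(N)
        mig, sched = _noop_schedule(p)
        fixed = 0
        for rep in range(reps):
            state = initialize_population(p, 50_000 + rep)
            col = np.zeros((2 * N, 1), dtype=np.uint8)
            col[0, 0] = 1
            state.H = col
            state.positions = np.array([7])
            for _ in range(20 * N):
                advance_generation(state, mig, sched)
                if state.H.shape[1] == 0:
                    break
            if state.substitutions:
                fixed += 1
        p_hat = fixed / reps
        p_exp = 1 / (2 * N)
        se = np.sqrt(p_exp * (1 - p_exp) / reps)
        assert abs(p_hat - p_exp) < 4 * se

    def test_equilibrium_diversity_matches_theta(self):
        """After a 20N burn-in, mean pi/site over 20 replicates is within
        10% of the neutral expectation theta = 4 N mu."""
        params = make_params(30, 5000)
        pis = []
        for k in range(20):
            st = equilibrate(params, 2000 + k)
            pis.append(diversity(draw_sample(st, 0, 15, seed=1)).pi_per_site)
        assert np.mean(pis) == pytest.approx(0.0377712, rel=0.10)

    def test_segregating_sites_near_watterson(self, eq_states_small):
        params, states = eq_states_small
        n = 30
        theta_L = params.theta_site * params.L
        expected = theta_L * sum(1.0 / i for i in range(1, n))
        S = [diversity(draw_sample(st, 0, n // 2, seed=2)).segregating_sites for st in states]
        assert np.mean(S) == pytest.approx(expected, rel=0.3)


class TestScheduleAndSampling:
    def test_sample_shape_and_segregation(self, eq_states_small):
        _, states = eq_states_small
        s = draw_sample(states[0], 0, 25, seed=9)
        assert s.n_hap == 50
        freqs = s.H.mean(axis=0)
        assert np.all((freqs > 0) & (freqs < 1))
        assert np.all(np.diff(s.positions) > 0)

    def test_sample_determinism(self, eq_states_small):
        _, states = eq_states_small
        a = draw_sample(states[0], 0, 10, seed=4)
        b = draw_sample(states[0], 0, 10, seed=4)
        assert np.array_equal(a.H, b.H)

    def test_oversampling_rejected(self, eq_states_small):
        _, states = eq_states_small
        with pytest.raises(ValueError):
            draw_sample(states[0], 0, 51)

    def test_run_schedule_counts_and_pairing(self):
        p = make_params(30, 3000)
        mig = MigrationSpec.from_nem(0.0, 30)
        sched = build_schedule(
            "continuous", mig, 1.0, p,
            burn_in_actual=50 * p.Q, post_div_actual=6 * p.Q,
            sampling_interval_actual=2 * p.Q, n_sample=5,
        )
        samples = list(run_schedule(p, sched, mig, 77))
        n_times = len(sched.sampling_times)
        assert len(samples) == 2 * n_times
        pops = {s.population for s in samples}
        assert pops == {"p1", "p2"}
        # paired draws share the column set so FST is computable directly
        s1, s2 = samples[0], samples[1]
        assert np.array_equal(s1.positions, s2.positions)

    def test_split_halves_population(self):
        p = make_params(30, 2000)
        mig, _ = _noop_schedule(p)
        sched = build_schedule(
            "continuous", mig, 1.0, p,
            burn_in_actual=10 * p.Q, post_div_actual=5 * p.Q,
        )
        state = initialize_population(p, 5)
        for _ in range(sched.split_gen + 1):
            advance_generation(state, mig, sched)
        assert state.pop_sizes == [15, 15]

    def test_recomb_factor_applies_to_p2_only(self):
        p = make_params(30, 2000)
        mig = MigrationSpec.from_nem(0.0, 30)
        sched = build_schedule(
            "continuous", mig, 2.0, p,
            burn_in_actual=10 * p.Q, post_div_actual=5 * p.Q,
        )
        state = initialize_population(p, 5)
        for _ in range(sched.split_gen + 1):
            advance_generation(state, mig, sched)
        assert state.r_factors == [1.0, 2.0]


class TestIslandModel:
    def test_fst_matches_structured_coalescent_oracle(self):
        """Two demes exchanging Nem = 2 migrants: forward-simulated Hudson
        FST agrees with an independent msprime island-model simulation."""
        import msprime

        n_model, nem = 40, 2.0
        p = make_params(n_model, 4000)
        mig = MigrationSpec.from_nem(nem, n_model)
        sched = build_schedule(
            "continuous", mig, 1.0, p,
            burn_in_actual=5 * p.Q, post_div_actual=30 * n_model * p.Q,
            sampling_interval_actual=30 * n_model * p.Q, n_sample=10,
        )
        fst_wf = []
        for rep in range(8):
            samples = list(run_schedule(p, sched, mig, 900 + rep))
            s1, s2 = samples[-2], samples[-1]
            fst_wf.append(hudson_fst(s1, s2).fst_raw)

        n_sub = n_model // 2
        m = mig.m_model
        fst_ms = []
        for rep in range(30):
            dem = msprime.Demography()
            dem.add_population(name="a", initial_size=n_sub)
            dem.add_population(name="b", initial_size=n_sub)
            dem.set_symmetric_migration_rate(["a", "b"], m)
            ts = msprime.sim_ancestry(
                samples={"a": 10, "b": 10}, demography=dem,
                sequence_length=4000, recombination_rate=p.r_site_model,
                random_seed=1234 + rep,
            )
            mts = msprime.sim_mutations(ts, rate=p.mu_site_model, random_seed=77 + rep)
            div = mts.diversity(
                [list(range(0, 20)), list(range(20, 40))], mode="site"
            )
            dxy = mts.divergence(
                [list(range(0, 20)), list(range(20, 40))], mode="site"
            )
            fst_ms.append(1 - div.mean() / dxy)
        wf, ms = np.mean(fst_wf), np.mean(fst_ms)
        assert wf == pytest.approx(ms, abs=0.03 + 0.5 * ms)

    def test_island_fst_closed_form(self):
        assert island_fst(10.0) == pytest.approx(1 / 41)
        assert island_fst(10.0, n_demes=2) == pytest.approx(1 / (1 + 160))
        assert island_fst(0.0) == 1.0
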