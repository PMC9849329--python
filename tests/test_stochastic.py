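"""Tests of the exact stochastic simulation engine."""

import numpy as np
import pytest
from scipy import stats as sps

from cosplice.commitment import (
    FEW_STEPS,
    CommitmentParams,
    DelaySet,
    analytic_psi,
    compute_delays,
)
from cosplice.stochastic import (
    Reaction,
    StochasticModelSpec,
    binomial_reference,
    delay_model_spec,
    ensemble_psi,
    exon_definition_spec,
    gillespie_run,
    noise_mean_curve,
    sample_runs,
)


@pytest.fixture(scope="module")
def delay_spec():
    params = CommitmentParams(ki=0.1, ks=0.1, kesc=0.0)
    return delay_model_spec(params, compute_delays(FEW_STEPS, 50.0)), params


class TestGillespieRun:
    def test_identical_seed_gives_identical_trajectory(self, delay_spec):
        spec, _ = delay_spec
        a = gillespie_run(spec, {"mRNA": 200}, seed=42)
        b = gillespie_run(spec, {"mRNA": 200}, seed=42)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.reactions, b.reactions)
        assert np.array_equal(a.final_counts, b.final_counts)

    def test_different_seed_differs(self, delay_spec):
        spec, _ = delay_spec
        a = gillespie_run(spec, {"mRNA": 200}, seed=1)
        b = gillespie_run(spec, {"mRNA": 200}, seed=2)
        assert not np.array_equal(a.times, b.times)

    def test_closed_skipping_window_yields_pure_inclusion(self):
        params = CommitmentParams(ki=0.2, ks=0.5, kesc=0.0)
        # skipping window never opens
        spec = delay_model_spec(params, DelaySet(0.0, 0.0, np.inf))
        traj = gillespie_run(spec, {"mRNA": 300}, seed=3, t_end=500.0)
        incl = traj.final_counts[spec.species.index("Incl")]
        skip = traj.final_counts[spec.species.index("Skip")]
        assert incl == 300 and skip == 0

    def test_counts_never_negative_and_conserved(self, delay_spec):
        spec, _ = delay_spec
        counts = sample_runs(spec, {"mRNA": 50}, 20, np.linspace(0, 1000, 9), seed=9)
        assert counts.min() >= 0
        assert np.all(counts.sum(axis=2) == 50)

    def test_pure_death_first_event_times_are_exponential(self):
        """Exactness on a two-state toy: survival matches exp(-k t)."""
        k = 0.7
        spec = StochasticModelSpec(
            ("A", "B"), (Reaction("decay", k, "A", {"B": 1}),)
        )
        rng_seeds = np.random.SeedSequence(77).generate_state(10_000) % (2**31 - 1)
        times = np.empty(10_000)
        reactant_idx, rates, stoich, t_on, t_off, sw = spec.compile()
        from cosplice._ssa_core import ssa_events

        for j, s in enumerate(rng_seeds):
            t, _, n, _ = ssa_events(
                np.array([1, 0], dtype=np.int64), reactant_idx, rates, stoich,
                t_on, t_off, sw, 1e3, int(s), 4,
            )
            assert n == 1
            times[j] = t[0]
        ks_stat = sps.kstest(times, "expon", args=(0, 1 / k))
        assert ks_stat.pvalue > 0.01

    def test_boundary_redraw_equals_thinning_distribution(self):
        """First-event times with one propensity switch: engine (redraw at
        the boundary) vs an independent thinning sampler."""
        r1, r2, tau = 0.3, 1.2, 1.5
        spec = StochasticModelSpec(
            ("A", "X", "Y"),
            (
                Reaction("slow", r1, "A", {"X": 1}),
                Reaction("late", r2, "A", {"Y": 1}, t_on=tau),
            ),
        )
        n = 8000
        reactant_idx, rates, stoich, t_on, t_off, sw = spec.compile()
        from cosplice._ssa_core import ssa_events

        seeds = np.random.SeedSequence(123).generate_state(n) % (2**31 - 1)
        engine_times = np.empty(n)
        for j, s in enumerate(seeds):
            t, _, m, _ = ssa_events(
                np.array([1, 0, 0], dtype=np.int64), reactant_idx, rates,
                stoich, t_on, t_off, sw, 1e4, int(s), 4,
            )
            engine_times[j] = t[0]
        # thinning oracle: propose at the max propensity, accept at a(t)/amax
        rng = np.random.default_rng(456)
        amax = r1 + r2
        thinning_times = np.empty(n)
        for j in range(n):
            t = 0.0
            while True:
                t += rng.exponential(1 / amax)
                a_t = r1 + (r2 if t >= tau else 0.0)
                if rng.random() < a_t / amax:
                    break
            thinning_times[j] = t
        ks = sps.ks_2samp(engine_times, thinning_times)
        assert ks.pvalue > 0.01


class TestEnsemble:
    def test_ensemble_mean_matches_ode_solution(self, delay_spec):
        """Species means over 5000 runs track the deterministic solution
        within 3 standard errors at ten checkpoints."""
        spec, params = delay_spec
        delays = compute_delays(FEW_STEPS, 50.0)
        n_runs, n0 = 5000, 100
        grid = np.linspace(1.0, 40.0, 10)
        counts = sample_runs(spec, {"mRNA": n0}, n_runs, grid, seed=5)
        mean = counts.mean(axis=0) / n0
        se = counts.std(axis=0, ddof=1) / n0 / np.sqrt(n_runs)

        from scipy.integrate import solve_ivp
        from cosplice.commitment import _rhs

        bounds = [0, delays.tau_inh1, delays.tau_inh2, delays.tau, grid[-1] + 1]
        active = [(params.ki, 0, 0), (params.ki, 0, params.kesc),
                  (params.ki, 0, 0), (params.ki, params.ks, 0)]
        y = np.array([1.0, 0, 0, 0])
        ode_vals = np.empty((grid.size, 4))
        for i in range(4):
            rhs = _rhs(active[i][0], active[i][1], active[i][2])
            sol = solve_ivp(rhs, (bounds[i], bounds[i + 1]), y,
                            rtol=1e-10, atol=1e-12, dense_output=True)
            inside = (grid >= bounds[i]) & (grid < bounds[i + 1])
            if inside.any():
                ode_vals[inside] = sol.sol(grid[inside]).T
            y = sol.y[:, -1]
        resid = np.abs(mean - ode_vals)
        assert np.all(resid <= 3 * se + 1e-12)

    def test_degenerate_runs_are_excluded_and_counted(self):
        # no spliced molecules can ever appear
        params = CommitmentParams(ki=0.0, ks=0.0, kesc=0.1)
        spec = delay_model_spec(params, DelaySet(0.0, 50.0, 50.0))
        with pytest.raises(RuntimeError, match="undefined"):
            ensemble_psi(spec, 10, 50, seed=4, t_end=100.0)

    def test_mean_psi_one_regime_has_zero_noise(self):
        params = CommitmentParams(ki=0.5, ks=0.0)
        spec = delay_model_spec(params, compute_delays(FEW_STEPS, 50.0))
        stats = ensemble_psi(spec, 100, 200, seed=6)
        assert stats.mean_psi == 1.0
        assert stats.std_psi == 0.0

    def test_noise_decreases_with_molecule_count(self):
        params = CommitmentParams(ki=0.1, ks=0.1)
        spec = delay_model_spec(params, compute_delays(FEW_STEPS, 30.0))
        stds = [
            ensemble_psi(spec, n, 2000, seed=7).std_psi for n in (10, 100, 1000)
        ]
        assert stds[0] > stds[1] > stds[2]

    def test_requires_at_least_two_runs(self, delay_spec):
        spec, _ = delay_spec
        with pytest.raises(ValueError):
            ensemble_psi(spec, 10, 1, seed=1)


class TestBinomialReference:
    @pytest.mark.parametrize(
        "n,p,expected", [(100, 0.5, 0.05), (400, 0.5, 0.025), (10, 0.0, 0.0),
                         (7, 1.0, 0.0)]
    )
    def test_closed_form(self, n, p, expected):
        assert binomial_reference(n, p) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_reference(0, 0.5)
        with pytest.raises(ValueError):
            binomial_reference(10, 1.5)


def _std_mc_se(psi_values):
    """Monte-Carlo standard error of the sample std (delta method with the
    empirical fourth moment)."""
    s2 = psi_values.var(ddof=0)
    m4 = ((psi_values - psi_values.mean()) ** 4).mean()
    var_s2 = (m4 - s2**2) / psi_values.size
    return np.sqrt(max(var_s2, 0.0)) / (2 * np.sqrt(s2)) if s2 > 0 else 0.0


class TestNoiseMeanCurve:
    def test_commitment_noise_is_binomial_at_matched_count(self):
        """Splicing noise of the delay model is congruent with binomial
        sampling at every molecule count (runtime-scaled sweep)."""
        params = CommitmentParams(ki=0.1, ks=0.1, kesc=1.0)

        def factory(vpol):
            return delay_model_spec(params, compute_delays(FEW_STEPS, vpol))

        table = noise_mean_curve(
            factory, sweep_values=(5.0, 50.0, 500.0),
            molecule_counts=(10, 100), n_runs=3000, seed=13,
        )
        for _, row in table.iterrows():
            assert abs(row.std_psi - row.binomial_std) < max(
                3 * row.std_psi / np.sqrt(2 * 3000), 2e-3
            )

    def test_mechanistic_noise_binomial_after_retention_conditioning(self):
        """Exon-definition ensembles: PSI noise matches the binomial model
        once the count basis is the per-run spliced total (Incl+Skip)."""
        import dataclasses as dc
        from cosplice.exondef import RON_MINIGENE, ExonDefinitionParams, InhibitionProfile

        params = ExonDefinitionParams()
        profile = InhibitionProfile()

        def factory(pos):
            arch = dc.replace(RON_MINIGENE, rbp_pos=float(pos))
            return exon_definition_spec(params, arch, profile)

        table = noise_mean_curve(
            factory, sweep_values=(220.0, 280.0), molecule_counts=(40,),
            n_runs=3000, seed=17,
        )
        for _, row in table.iterrows():
            se = max(3 * row.std_psi / np.sqrt(2 * 3000), 3e-3)
            assert abs(row.std_psi - row.binomial_std) < se
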