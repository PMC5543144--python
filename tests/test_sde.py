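"""Stochastic simulation: integrator contracts, classification, sorting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mescgrn import (
    classify_states,
    make_variant,
    simulate_cell,
    simulate_population,
    sorting_experiment,
    steady_state_fractions,
)
from mescgrn.network import CompiledDrift
from mescgrn.sde import SimulationEnsemble


def noiseless(model):
    m = model.with_inputs(model.inputs)
    for k in m.noise:
        m.noise[k] = 0.0
    return m


class TestIntegrator:
    def test_identical_seeds_bit_identical(self, serum):
        t1, x1 = simulate_cell(serum, t_end=5.0, seed=42)
        t2, x2 = simulate_cell(serum, t_end=5.0, seed=42)
        assert np.array_equal(x1, x2)
        _, x3 = simulate_cell(serum, t_end=5.0, seed=43)
        assert not np.array_equal(x1, x3)

    def test_noise_free_equilibrium_is_fixed_point(self, serum, serum_attractor_states):
        m = noiseless(serum)
        for x_star in serum_attractor_states:
            _, traj = simulate_cell(m, t_end=15.0, x0=x_star, record_every=15.0)
            assert np.allclose(traj[-1], x_star, atol=1e-6)

    def test_noise_free_path_matches_ode_solver(self, serum):
        m = noiseless(serum)
        x0 = m.initial_state() * 0.5
        _, traj = simulate_cell(m, t_end=10.0, dt=0.01, x0=x0, record_every=10.0)
        f = CompiledDrift(m)
        sol = solve_ivp(lambda t, y: f(y), (0, 10.0), x0, rtol=1e-10, atol=1e-12)
        assert np.allclose(traj[-1], sol.y[:, -1], atol=5e-3)  # O(dt) agreement

    def test_concentrations_stay_non_negative(self, serum):
        _, traj = simulate_cell(serum, t_end=30.0, seed=7, record_every=0.5)
        assert np.all(traj >= 0.0)

    def test_dt_validation(self, serum):
        with pytest.raises(ValueError):
            simulate_cell(serum, t_end=0.001, dt=0.01)

    def test_nanog_fluctuates_while_os_stays_flat(self, serum, threshold):
        """Over 15 h a serum cell crosses the NH/NL threshold while the
        Oct4-Sox2 level stays comparatively constant."""
        crossings = 0
        os_cv, nanog_cv = [], []
        for seed in range(6):
            _, traj = simulate_cell(serum, t_end=15.0, seed=seed, record_every=0.1)
            nanog = traj[:, 1]
            os_ = traj[:, 0]
            crossings += int(np.any(nanog >= threshold) and np.any(nanog < threshold))
            nanog_cv.append(nanog.std() / nanog.mean())
            os_cv.append(os_.std() / os_.mean())
        assert crossings >= 2
        assert np.mean(os_cv) < 0.3 * np.mean(nanog_cv)


class TestPopulation:
    def test_single_cell_population_reduces_to_simulate_cell(self, serum):
        ens = simulate_population(serum, n_cells=1, t_end=2.0, seed=9, record_every=1.0)
        assert ens.trajectories.shape[0] == 1
        assert ens.n_cells == 1

    def test_n_cells_validated(self, serum):
        with pytest.raises(ValueError):
            simulate_population(serum, n_cells=0, t_end=1.0)

    def test_classification_tie_breaks_high(self, serum):
        fin = np.full((5, serum.n_species), 0.7)
        ens = SimulationEnsemble(
            times=np.array([0.0]), trajectories=fin[:, None, :], final_states=fin,
            seed=0, model_tag="t", species=serum.names,
        )
        cls = classify_states(ens, threshold=0.7)
        assert cls.fraction_high == 1.0
        assert set(cls.labels) == {"NH"}

    def test_empty_ensemble_rejected(self, serum):
        ens = SimulationEnsemble(
            times=np.array([0.0]), trajectories=np.empty((0, 1, 8)),
            final_states=np.empty((0, 8)), seed=0, model_tag="t", species=serum.names,
        )
        with pytest.raises(ValueError):
            classify_states(ens, 0.5)

    def test_weak_convergence_under_dt_halving(self, serum, threshold):
        """Halving dt moves the serum NH fraction by less than the
        Monte-Carlo spread of the estimator."""
        f1 = steady_state_fractions(serum, n_cells=400, repeats=3, burn_in=60.0,
                                    dt=0.02, seed=5, threshold=threshold)
        f2 = steady_state_fractions(serum, n_cells=400, repeats=3, burn_in=60.0,
                                    dt=0.01, seed=5, threshold=threshold)
        mc_se = np.sqrt(0.25 / 400) + f1.std(ddof=1) / np.sqrt(3)
        assert abs(f1.mean() - f2.mean()) < 3 * mc_se

    def test_noise_off_population_settles_on_attractors(self, serum, threshold,
                                                        serum_attractor_states):
        m = noiseless(serum)
        fr = steady_state_fractions(m, n_cells=20, repeats=1, burn_in=50.0,
                                    dt=0.01, seed=3, threshold=threshold)
        # cells split evenly on the two attractors stay there: fraction is the
        # initialisation share, not an intermediate value
        assert fr[0] == pytest.approx(0.5, abs=1e-12)


class TestSorting:
    def test_zero_day_fractions_are_pure(self, serum, threshold):
        t, fr = sorting_experiment(serum, "NH", n_cells=50, days=0.01,
                                   record_every=0.24, repeats=2, seed=1,
                                   threshold=threshold, jitter=0.0)
        assert fr[:, 0] == pytest.approx(1.0)
        t, fr = sorting_experiment(serum, "NL", n_cells=50, days=0.01,
                                   record_every=0.24, repeats=2, seed=1,
                                   threshold=threshold, jitter=0.0)
        assert fr[:, 0] == pytest.approx(0.0)

    def test_monostable_model_lacking_attractor_errors(self, serum):
        m = make_variant(serum, "delete:TCF3")
        with pytest.raises(ValueError, match="NL"):
            sorting_experiment(m, "NL", n_cells=10, days=0.1, threshold=0.5)

    def test_sorting_brackets_unsorted_fraction(self, serum, threshold):
        """NH- and NL-initialised populations approach the mixed fraction
        from above and below respectively."""
        t, hi = sorting_experiment(serum, "NH", n_cells=250, days=2.0,
                                   repeats=2, seed=11, threshold=threshold)
        t, lo = sorting_experiment(serum, "NL", n_cells=250, days=2.0,
                                   repeats=2, seed=12, threshold=threshold)
        hi_end = hi[:, -1].mean()
        lo_end = lo[:, -1].mean()
        assert lo_end < hi_end
        assert 0.3 < lo_end < 0.65
        assert 0.35 < hi_end < 0.7
        # monotone-ish approach: NH curve decreases, NL curve increases
        assert hi.mean(axis=0)[0] > hi_end
        assert lo.mean(axis=0)[0] < lo_end
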