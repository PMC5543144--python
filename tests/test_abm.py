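"""Agent-based colony model: division bookkeeping, growth curves, RMSE."""

import numpy as np
import pytest

from mescgrn.abm import (
    ColonyTrajectory,
    CyclePolicy,
    MIN_CYCLE_H,
    ProliferationDataset,
    growth_curve,
    mycn_threshold,
    rmse,
    simulate_colony,
    sorting_with_division,
)


def noiseless(model):
    m = model.with_inputs(model.inputs)
    for k in m.noise:
        m.noise[k] = 0.0
    return m


def make_dataset(folds, days=None):
    folds = np.asarray(folds, dtype=float)
    days = np.arange(folds.size, dtype=float) if days is None else np.asarray(days)
    return ProliferationDataset(times_days=days, fold_change=folds,
                                se=np.zeros(folds.size), replicates=1)


class TestRmse:
    def test_identical_curves_give_zero(self):
        a = make_dataset([1, 2, 4, 8])
        assert rmse(a, a) == 0.0

    def test_hand_computed_values(self):
        assert rmse(make_dataset([1, 2, 4, 8]), make_dataset([1, 2, 4, 10])) == pytest.approx(1.0)
        assert rmse(make_dataset([1, 1, 1, 1]), make_dataset([1, 3, 1, 1])) == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            rmse(make_dataset([1, 2]), make_dataset([1, 2, 4]))


class TestPolicy:
    def test_high_state_must_cycle_faster(self):
        with pytest.raises(ValueError):
            CyclePolicy("NANOG", mean_high=14.0, mean_low=10.0)

    def test_presets_encode_printed_cycle_times(self):
        assert (CyclePolicy.nanog_serum().mean_high, CyclePolicy.nanog_serum().mean_low) == (8.5, 13.5)
        assert (CyclePolicy.nanog_2i().mean_high, CyclePolicy.nanog_2i().mean_low) == (13.175, 20.925)
        assert (CyclePolicy.mycn_serum().mean_high, CyclePolicy.mycn_serum().mean_low) == (8.5, 15.0)
        assert (CyclePolicy.mycn_2i().mean_high, CyclePolicy.mycn_2i().mean_low) == (9.5, 16.0)


class TestColony:
    def test_synchronous_doubling_with_degenerate_policy(self, serum):
        """All-High, sd = 0 policy: every cell divides exactly once per T
        hours, so count(t + T) = 2 count(t)."""
        T = 8.0
        policy = CyclePolicy("NANOG", mean_high=T, mean_low=2 * T,
                             sd_high=0.0, sd_low=0.0, threshold=0.0)
        m = noiseless(serum)
        tr = simulate_colony(m, policy, n0=16, t_end=3 * T, dt=0.05, seed=2,
                             sample_every=T)
        counts = tr.counts
        assert counts[0] == 16
        for k in range(len(counts) - 1):
            assert counts[k + 1] == pytest.approx(2 * counts[k])

    def test_growth_bounds(self, serum):
        """Count lies between n0*2^floor(t/max_cycle) and n0*2^ceil(t/min_cycle)."""
        policy = CyclePolicy("NANOG", 8.5, 13.5, 1.0, 1.0)
        tr = simulate_colony(serum, policy, n0=20, t_end=48.0, dt=0.05, seed=4)
        t_end = tr.times[-1]
        lo = 20 * 2 ** np.floor(t_end / 30.0)  # generous max cycle
        hi = 20 * 2 ** np.ceil(t_end / MIN_CYCLE_H)
        assert lo <= tr.counts[-1] <= hi

    def test_lineage_is_binary_forest(self, serum):
        policy = CyclePolicy("NANOG", 6.0, 9.0, 0.5, 0.5)
        tr = simulate_colony(serum, policy, n0=5, t_end=20.0, dt=0.05, seed=6)
        parents = tr.parent_ids
        assert np.all(parents[:5] == -1)
        counts = np.bincount(parents[5:][parents[5:] >= 0])
        assert np.all(counts <= 2)  # at most two daughters per cell
        # every division adds exactly one cell to the living population:
        # final count = n0 + number of divisions = n0 + (new ids) / 2
        n_new = parents.size - 5
        assert tr.final_states.shape[0] == 5 + n_new // 2

    def test_no_division_limit_matches_sde(self, serum, threshold):
        """With cycle means far beyond the horizon the colony is just a
        non-dividing SDE population."""
        policy = CyclePolicy("NANOG", 500.0, 800.0, 1.0, 1.0)
        tr = simulate_colony(serum, policy, n0=200, t_end=30.0, dt=0.02, seed=8)
        # founders carry uniform random initial ages, so only the few cells
        # born near the end of a 500 h cycle divide within 30 h
        assert tr.final_states.shape[0] < 220
        from mescgrn import steady_state_fractions
        fr = steady_state_fractions(serum, n_cells=200, repeats=2, burn_in=30.0,
                                    dt=0.02, seed=8, threshold=threshold)
        assert abs(tr.fraction_nh[-1] - fr.mean()) < 0.12

    def test_colony_nanog_split_matches_sde_in_serum(self, serum):
        """A serum colony with the Nanog policy keeps roughly half of its
        cells Nanog-High, consistent with the population SDE model."""
        tr = simulate_colony(serum, CyclePolicy.nanog_serum(), n0=60,
                             t_end=60.0, dt=0.02, seed=12)
        assert 0.35 < tr.fraction_nh[-1] < 0.68

    def test_mycn_threshold_between_modes(self, serum):
        thr = mycn_threshold(serum)
        att_m = [a[serum.index("MYCN")] for a in
                 __import__("mescgrn").sde.serum_attractors(serum)]
        assert min(att_m) < thr < max(att_m)


class TestGrowthCurve:
    def test_exact_doubling_series(self):
        times = np.arange(0.0, 72.1, 1.0)
        counts = 10 * 2 ** (times / 24.0)
        tr = ColonyTrajectory(times=times, counts=counts,
                              fraction_high_coupled=np.zeros_like(times),
                              fraction_nh=np.zeros_like(times),
                              final_states=np.empty((0, 8)),
                              parent_ids=np.empty(0, int), seed=0,
                              policy=CyclePolicy("NANOG", 24.0, 30.0))
        ds = growth_curve(tr)
        assert np.allclose(ds.fold_change, [1, 2, 4, 8])

    def test_constant_count_colony(self):
        times = np.arange(0.0, 72.1, 1.0)
        tr = ColonyTrajectory(times=times, counts=np.full_like(times, 7.0),
                              fraction_high_coupled=np.zeros_like(times),
                              fraction_nh=np.zeros_like(times),
                              final_states=np.empty((0, 8)),
                              parent_ids=np.empty(0, int), seed=0,
                              policy=CyclePolicy("NANOG", 24.0, 30.0))
        ds = growth_curve(tr)
        assert np.allclose(ds.fold_change, 1.0)
        ds.validate()

    def test_se_shrinks_with_repeats(self, serum):
        """Standard error scales roughly as 1/sqrt(repeats)."""
        policy = CyclePolicy("NANOG", 9.0, 14.0, 1.0, 1.0)
        runs = [simulate_colony(serum, policy, n0=12, t_end=48.0, dt=0.05, seed=s)
                for s in range(16)]
        few = growth_curve(runs[:4], horizon=48.0)
        many = growth_curve(runs, horizon=48.0)
        ratio = few.se[-1] / many.se[-1]
        assert 1.0 < ratio < 4.5  # ~2 expected for 4x repeats

    def test_short_trajectory_rejected(self, serum):
        policy = CyclePolicy("NANOG", 9.0, 14.0)
        tr = simulate_colony(serum, policy, n0=5, t_end=24.0, dt=0.05, seed=1)
        with pytest.raises(ValueError):
            growth_curve(tr, horizon=72.0)


class TestSortingWithDivision:
    def test_zero_horizon_keeps_initial_fractions(self, serum):
        t, fr = sorting_with_division(serum, CyclePolicy.mycn_serum(), "NH",
                                      days=0.02, n0=40, repeats=2, seed=3,
                                      record_every=0.48)
        assert fr[:, 0].mean() > 0.9
        t, fr = sorting_with_division(serum, CyclePolicy.mycn_serum(), "NL",
                                      days=0.02, n0=40, repeats=2, seed=3,
                                      record_every=0.48)
        assert fr[:, 0].mean() < 0.1

    def test_invalid_start_state(self, serum):
        with pytest.raises(ValueError):
            sorting_with_division(serum, CyclePolicy.mycn_serum(), "XX", days=0.1)
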