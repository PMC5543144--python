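"""Agent-based colony model coupling gene expression to the cell cycle.

Each cell carries the full intracellular network state, integrated with the
same Euler-Maruyama scheme as the population SDE module.  A cell keeps a
fixed cycle length from birth; on reaching it the cell divides into two
daughters that inherit the mother's protein concentrations.  Each
daughter's cycle length is drawn from a normal distribution whose mean and
spread depend on whether the mother is High or Low in the coupled species
(Nanog or Mycn) at the moment of division; draws are truncated below at a
positive floor so no cell divides instantaneously.

The Mycn coupling inverts the biology relative to Nanog: Mycn is repressed
by Nanog, so Mycn-High cells largely coincide with Nanog-Low cells, and
Mycn levels fall in 2i/LIF.  Coupling the cycle to Mycn therefore predicts
slower colony growth in ground-state medium even though the Nanog-High
fraction rises — the model-discrimination argument this module supports.

Colony growth is summarised as fold change in cell count relative to day 0,
sampled every 24 h, averaged over independent simulations; cycle-time
parameters are fitted to such growth curves by grid-refinement search on
the root-mean-squared error (RMSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .network import CompiledDrift, NetworkModel
from .sde import nh_threshold, serum_attractors

__all__ = [
    "CyclePolicy",
    "ColonyTrajectory",
    "ProliferationDataset",
    "mycn_threshold",
    "simulate_colony",
    "growth_curve",
    "rmse",
    "fit_cycle_params",
    "FitResult",
    "sorting_with_division",
]

MIN_CYCLE_H = 2.0  # truncation floor for sampled cycle lengths
DEFAULT_ABM_DT = 0.02  # hours


@dataclass(frozen=True)
class CyclePolicy:
    """Cell-cycle allocation rule.

    ``coupling`` names the species whose High/Low state of the mother at
    division sets each daughter's cycle draw: Normal(mean_high, sd_high)
    for High mothers, Normal(mean_low, sd_low) for Low ones, truncated at
    :data:`MIN_CYCLE_H`.  High-state cells cycle faster (mean_high <
    mean_low).
    """

    coupling: str = "NANOG"  # "NANOG" | "MYCN"
    mean_high: float = 8.5
    mean_low: float = 13.5
    sd_high: float = 1.0
    sd_low: float = 1.0
    threshold: float | None = None  # classifier threshold (AU)

    def __post_init__(self) -> None:
        if self.coupling not in ("NANOG", "MYCN"):
            raise ValueError("coupling must be 'NANOG' or 'MYCN'")
        if self.mean_high <= 0 or self.mean_low <= 0:
            raise ValueError("cycle means must be positive")
        if self.mean_high >= self.mean_low:
            raise ValueError("High-state cells must cycle faster (mean_high < mean_low)")

    @classmethod
    def nanog_serum(cls, threshold: float | None = None) -> "CyclePolicy":
        """Nanog coupling fitted to serum/LIF growth (8.5 h NH / 13.5 h NL)."""
        return cls("NANOG", 8.5, 13.5, 1.0, 1.0, threshold)

    @classmethod
    def nanog_2i(cls, threshold: float | None = None) -> "CyclePolicy":
        """Nanog coupling fitted to 2i/LIF growth: 55% longer cycles."""
        return cls("NANOG", 13.175, 20.925, 1.0, 1.0, threshold)

    @classmethod
    def mycn_serum(cls, threshold: float | None = None) -> "CyclePolicy":
        """Mycn coupling fitted to serum/LIF growth (8.5 h MH / 15 h ML)."""
        return cls("MYCN", 8.5, 15.0, 1.0, 1.0, threshold)

    @classmethod
    def mycn_2i(cls, threshold: float | None = None) -> "CyclePolicy":
        """Mycn coupling fitted to 2i/LIF growth (9.5 h MH / 16 h ML)."""
        return cls("MYCN", 9.5, 16.0, 1.0, 1.0, threshold)


@dataclass
class ColonyTrajectory:
    """Cell counts (and optional state summaries) on a fixed time grid."""

    times: np.ndarray  # hours
    counts: np.ndarray  # effective cell count (float: see cap rescaling)
    fraction_high_coupled: np.ndarray  # per time point, of the coupled species
    fraction_nh: np.ndarray  # NH fraction per time point
    final_states: np.ndarray  # (n_cells, n_species) at t_end
    parent_ids: np.ndarray  # lineage: parent id per cell ever created (-1 roots)
    seed: int
    policy: CyclePolicy


@dataclass
class ProliferationDataset:
    """Fold-change-vs-day-0 growth table with replicate spread.

    ``fold_change[0]`` is exactly 1; values are non-decreasing for growing
    colonies.  ``se`` is the standard error over replicates.
    """

    times_days: np.ndarray
    fold_change: np.ndarray
    se: np.ndarray
    replicates: int

    def validate(self) -> None:
        if abs(self.fold_change[0] - 1.0) > 1e-12:
            raise ValueError("fold change at day 0 must be exactly 1")
        if np.any(np.diff(self.fold_change) < 0):
            raise ValueError("fold change must be non-decreasing")


def mycn_threshold(model: NetworkModel) -> float:
    """MH/ML threshold: midpoint of Mycn levels at the two serum attractors,
    mirroring the Nanog rule."""
    att = serum_attractors(model)
    i = model.index("MYCN")
    levels = sorted(a[i] for a in att)
    if len(levels) < 2:
        raise ValueError("serum system must be bistable to define a Mycn threshold")
    return 0.5 * (levels[0] + levels[-1])


def _policy_threshold(model: NetworkModel, policy: CyclePolicy) -> float:
    if policy.threshold is not None:
        return policy.threshold
    return nh_threshold(model) if policy.coupling == "NANOG" else mycn_threshold(model)


def _draw_cycles(
    rng: np.random.Generator, high: np.ndarray, policy: CyclePolicy
) -> np.ndarray:
    mu = np.where(high, policy.mean_high, policy.mean_low)
    sd = np.where(high, policy.sd_high, policy.sd_low)
    return np.maximum(mu + sd * rng.standard_normal(high.shape), MIN_CYCLE_H)


def simulate_colony(
    model: NetworkModel,
    policy: CyclePolicy,
    n0: int = 50,
    t_end: float = 72.0,
    dt: float = DEFAULT_ABM_DT,
    seed: int = 0,
    sample_every: float = 1.0,
    cap: int = 20000,
    x0: np.ndarray | None = None,
) -> ColonyTrajectory:
    """Grow a well-mixed colony of dividing cells for ``t_end`` hours.

    Founders are drawn from the steady-state split across the serum
    attractors (or ``x0`` rows) with uniformly random initial age in
    ``[0, cycle_length)`` to desynchronise divisions.  If the population
    exceeds ``cap`` it is randomly thinned to half the cap and a count
    multiplier is carried so reported counts stay unbiased (a warning is
    emitted once).
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    drift = CompiledDrift(model)
    sigma = model.sigma()
    thr_c = _policy_threshold(model, policy)
    i_c = model.index(policy.coupling)
    i_n = model.index("NANOG")
    thr_n = thr_c if policy.coupling == "NANOG" else nh_threshold(model)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if x0 is None:
        att = serum_attractors(model)
        x = np.empty((n0, model.n_species))
        for i in range(n0):
            x[i] = att[i % len(att)]
        x += 0.02 * rng.standard_normal(x.shape)
        np.clip(x, 0.0, None, out=x)
    else:
        x = np.array(x0, dtype=float)
        if x.shape[0] != n0:
            raise ValueError("x0 must have n0 rows")

    cyc = _draw_cycles(rng, x[:, i_c] >= thr_c, policy)
    age = rng.uniform(0.0, cyc)
    ids = np.arange(n0)
    parents = [-1] * n0
    next_id = n0
    weight = 1.0
    warned = False

    n_steps = int(round(t_end / dt))
    stride = max(int(round(sample_every / dt)), 1)
    rec_t, rec_count, rec_fc, rec_fn = [], [], [], []
    sq = np.sqrt(dt * drift.time_scale)
    noisy = np.any(sigma > 0)

    def record(t):
        rec_t.append(t)
        rec_count.append(weight * x.shape[0])
        rec_fc.append(float(np.mean(x[:, i_c] >= thr_c)))
        rec_fn.append(float(np.mean(x[:, i_n] >= thr_n)))

    record(0.0)
    for k in range(1, n_steps + 1):
        dx = drift(x) * dt
        if noisy:
            dx += (sigma * sq) * rng.standard_normal(x.shape)
        x = np.clip(x + dx, 0.0, None)
        age = age + dt
        div = age >= cyc
        if np.any(div):
            mothers = np.nonzero(div)[0]
            high = x[mothers, i_c] >= thr_c
            # the mother's row is reused for one daughter, a new row holds
            # the other; both daughters get fresh ids so the lineage is a
            # binary forest rooted at the founders
            mother_ids = ids[mothers].tolist()
            cyc[mothers] = _draw_cycles(rng, high, policy)
            age[mothers] = 0.0
            new_cyc = _draw_cycles(rng, high, policy)
            x = np.vstack([x, x[mothers]])
            cyc = np.concatenate([cyc, new_cyc])
            age = np.concatenate([age, np.zeros(mothers.size)])
            ids[mothers] = np.arange(next_id, next_id + mothers.size)
            ids = np.concatenate(
                [ids, np.arange(next_id + mothers.size, next_id + 2 * mothers.size)]
            )
            parents.extend(mother_ids)  # first-daughter block
            parents.extend(mother_ids)  # second-daughter block
            next_id += 2 * mothers.size
        if x.shape[0] > cap:
            if not warned:
                warnings.warn(
                    f"colony exceeded cap={cap}; thinning with count rescaling",
                    RuntimeWarning,
                    stacklevel=2,
                )
                warned = True
            keep = rng.choice(x.shape[0], size=cap // 2, replace=False)
            weight *= x.shape[0] / keep.size
            x, cyc, age, ids = x[keep], cyc[keep], age[keep], ids[keep]
        if k % stride == 0:
            record(k * dt)

    return ColonyTrajectory(
        times=np.array(rec_t),
        counts=np.array(rec_count),
        fraction_high_coupled=np.array(rec_fc),
        fraction_nh=np.array(rec_fn),
        final_states=x,
        parent_ids=np.array(parents),
        seed=seed,
        policy=policy,
    )


def growth_curve(
    trajectories: "ColonyTrajectory | list[ColonyTrajectory]",
    sample_every: float = 24.0,
    horizon: float = 72.0,
) -> ProliferationDataset:
    """Fold change vs day 0, mean ± SE over independent colony repeats."""
    if isinstance(trajectories, ColonyTrajectory):
        trajectories = [trajectories]
    days = np.arange(0.0, horizon + 1e-9, sample_every)
    folds = np.empty((len(trajectories), days.size))
    for r, tr in enumerate(trajectories):
        if tr.times[-1] + 1e-9 < horizon:
            raise ValueError("trajectory shorter than the sampling horizon")
        idx = [int(np.argmin(np.abs(tr.times - t))) for t in days]
        folds[r] = tr.counts[idx] / tr.counts[idx[0]]
    mean = folds.mean(axis=0)
    se = (
        folds.std(axis=0, ddof=1) / np.sqrt(len(trajectories))
        if len(trajectories) > 1
        else np.zeros(days.size)
    )
    mean[0] = 1.0
    return ProliferationDataset(
        times_days=days / 24.0, fold_change=mean, se=se, replicates=len(trajectories)
    )


def rmse(model_curve: ProliferationDataset, data_curve: ProliferationDataset) -> float:
    """Root-mean-squared error between fold-change means (day 0 included)."""
    if model_curve.times_days.size != data_curve.times_days.size or np.any(
        np.abs(model_curve.times_days - data_curve.times_days) > 1e-9
    ):
        raise ValueError("time grids of the two curves do not match")
    d = model_curve.fold_change - data_curve.fold_change
    return float(np.sqrt(np.mean(d**2)))


def _mean_curve(
    model: NetworkModel,
    policy: CyclePolicy,
    repeats: int,
    seed: int,
    n0: int,
    dt: float,
    horizon: float,
    cap: int = 20000,
) -> ProliferationDataset:
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    runs = [
        simulate_colony(model, policy, n0=n0, t_end=horizon, dt=dt, seed=int(s), cap=cap)
        for s in seeds
    ]
    return growth_curve(runs, horizon=horizon)


@dataclass
class FitResult:
    policy: CyclePolicy
    rmse: float
    validation_rmse: float | None = None
    converged: bool = True
    evaluations: int = 0
    curve: ProliferationDataset | None = field(default=None, repr=False)


def fit_cycle_params(
    model: NetworkModel,
    policy_template: CyclePolicy,
    data: ProliferationDataset,
    bounds_high: tuple[float, float] = (6.0, 24.0),
    bounds_low: tuple[float, float] = (8.0, 30.0),
    repeats: int = 15,
    n0: int = 40,
    dt: float = DEFAULT_ABM_DT,
    grid: int = 3,
    seed: int = 0,
    max_evals: int = 60,
    cap: int = 20000,
    validation: ProliferationDataset | None = None,
) -> FitResult:
    """Fit (mean_high, mean_low) to a growth curve by RMSE minimisation.

    A coarse ``grid`` x ``grid`` scan seeds a bounded Powell local search.
    Every candidate is evaluated with the same ``repeats`` colony seeds
    (common random numbers), so the objective is deterministic and the
    direction-set search is well behaved despite the Monte-Carlo noise.

    Returns the best policy, its RMSE, and the held-out RMSE on
    ``validation`` if given.  If the evaluation budget runs out the
    best-so-far is returned with ``converged=False``.
    """
    from scipy.optimize import minimize

    data.validate()
    horizon = float(data.times_days[-1] * 24.0)
    cache: dict[tuple[float, float], float] = {}
    state = {"evals": 0, "converged": True}
    best: dict = {}

    def objective(v) -> float:
        mh, ml = float(v[0]), float(v[1])
        key = (round(mh, 3), round(ml, 3))
        if key in cache:
            return cache[key]
        if (
            not bounds_high[0] <= mh <= bounds_high[1]
            or not bounds_low[0] <= ml <= bounds_low[1]
            or ml <= mh + 0.5
        ):
            return 1e6  # infeasible: High cells must cycle faster, inside box
        if state["evals"] >= max_evals:
            state["converged"] = False
            return 1e6
        cand = replace(policy_template, mean_high=mh, mean_low=ml)
        curve = _mean_curve(model, cand, repeats, seed, n0, dt, horizon, cap=cap)
        err = rmse(curve, data)
        cache[key] = err
        state["evals"] += 1
        if not best or err < best["err"]:
            best.update(err=err, policy=cand, curve=curve)
        return err

    for mh in np.linspace(*bounds_high, grid):
        for ml in np.linspace(*bounds_low, grid):
            if ml > mh + 0.5:
                objective((mh, ml))
    if not best:
        raise RuntimeError("no admissible candidate in the search box")
    x0 = np.array([best["policy"].mean_high, best["policy"].mean_low])
    minimize(
        objective,
        x0,
        method="Powell",
        bounds=[bounds_high, bounds_low],
        options={
            "maxfev": max(max_evals - state["evals"], 4),
            "xtol": 0.05,
            "ftol": 1e-4,
        },
    )
    val = None
    if validation is not None:
        vcurve = _mean_curve(
            model,
            best["policy"],
            repeats,
            seed + 1,
            n0,
            dt,
            float(validation.times_days[-1] * 24.0),
            cap=cap,
        )
        val = rmse(vcurve, validation)
    return FitResult(
        policy=best["policy"],
        rmse=best["err"],
        validation_rmse=val,
        converged=state["converged"],
        evaluations=state["evals"],
        curve=best["curve"],
    )


def sorting_with_division(
    model: NetworkModel,
    policy: CyclePolicy,
    start_state: str,
    days: float = 4.0,
    n0: int = 200,
    record_every: float = 12.0,
    repeats: int = 5,
    dt: float = DEFAULT_ABM_DT,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sorting experiment with dividing agents: a pure NH or NL founder
    population relaxing back to the mixed distribution while the colony
    grows.  Returns ``(times, fraction_NH)`` shaped ``(repeats, n_times)``.
    """
    if start_state not in ("NH", "NL"):
        raise ValueError("start_state must be 'NH' or 'NL'")
    att = serum_attractors(model)
    i_n = model.index("NANOG")
    thr = nh_threshold(model)
    wanted = [a for a in att if (a[i_n] >= thr) == (start_state == "NH")]
    if not wanted:
        raise ValueError(f"model lacks a {start_state} attractor to sort from")
    x_star = wanted[0]
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    t_end = days * 24.0
    out = []
    times = None
    for s in seeds:
        rng = np.random.default_rng(int(s))
        x0 = np.tile(x_star, (n0, 1)) + 0.02 * rng.standard_normal((n0, x_star.size))
        tr = simulate_colony(
            model,
            policy,
            n0=n0,
            t_end=t_end,
            dt=dt,
            seed=int(s),
            sample_every=record_every,
            x0=np.clip(x0, 0.0, None),
        )
        times = tr.times
        out.append(tr.fraction_nh)
    return times, np.array(out)
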