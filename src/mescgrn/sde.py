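"""Stochastic single-cell and population simulation.

Each cell is an independent realisation of the network SDE

    dX = f(X) dt + sigma dW,

integrated by Euler-Maruyama with reflection at zero truncated to a clip
(concentrations cannot go negative).  Population runs vectorise all cells
in one state array; independent cells draw independent Gaussian increments
from a generator spawned off the master seed, so results are reproducible
from the recorded seed alone.

NH/NL classification uses a fixed Nanog threshold.  By default the
threshold is the midpoint of the two stable Nanog equilibria of the
deterministic serum/LIF system, and the same threshold is reused in 2i for
comparability; ties classify as NH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .continuation import find_equilibria
from .network import CompiledDrift, MediumInputs, NetworkModel

__all__ = [
    "IntegrationError",
    "SimulationEnsemble",
    "StateClassification",
    "simulate_cell",
    "simulate_population",
    "classify_states",
    "nh_threshold",
    "serum_attractors",
    "steady_state_fractions",
    "sorting_experiment",
]

DEFAULT_DT = 0.01  # hours
DEFAULT_BURN_IN = 100.0  # hours


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationEnsemble:
    """Per-cell time courses on a thinned hours grid plus final states."""

    times: np.ndarray
    trajectories: np.ndarray  # (n_cells, n_times, n_species)
    final_states: np.ndarray  # (n_cells, n_species)
    seed: int
    model_tag: str
    species: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return self.final_states.shape[0]

    def final_nanog(self) -> np.ndarray:
        return self.final_states[:, self.species.index("NANOG")]


@dataclass
class StateClassification:
    threshold: float
    labels: np.ndarray  # "NH" / "NL" per cell
    fraction_high: float


# ---------------------------------------------------------------------------
# Core integrator
# ---------------------------------------------------------------------------


def _em_integrate(
    drift: CompiledDrift,
    x0: np.ndarray,
    sigma: np.ndarray,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
    record_idx: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Euler-Maruyama with clip-at-zero.  Returns (recorded, final)."""
    x = np.array(x0, dtype=float)
    sq = np.sqrt(dt * drift.time_scale)
    noisy = np.any(sigma > 0)
    rec = None
    rec_set = None
    if record_idx is not None:
        rec = np.empty((record_idx.size,) + x.shape)
        rec_set = {int(k): i for i, k in enumerate(record_idx)}
        if 0 in rec_set:
            rec[rec_set[0]] = x
    for k in range(1, n_steps + 1):
        dx = drift(x) * dt
        if noisy:
            dx += (sigma * sq) * rng.standard_normal(x.shape)
        x = x + dx
        np.clip(x, 0.0, None, out=x)
        if not np.all(np.isfinite(x)):
            raise IntegrationError(
                f"non-finite state at step {k} (t = {k * dt:.3f} h); "
                "reduce dt for stability"
            )
        if rec_set is not None and k in rec_set:
            rec[rec_set[k]] = x
    return rec, x


def _record_indices(n_steps: int, dt: float, record_every: float | None) -> np.ndarray:
    if record_every is None:
        return np.array([0, n_steps])
    stride = max(int(round(record_every / dt)), 1)
    idx = np.arange(0, n_steps + 1, stride)
    if idx[-1] != n_steps:
        idx = np.append(idx, n_steps)
    return idx


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------


def simulate_cell(
    model: NetworkModel,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    x0: np.ndarray | None = None,
    record_every: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-cell Euler-Maruyama path of all species.

    Returns ``(times, trajectory)`` with trajectory shaped
    ``(n_times, n_species)``.  With all noise sigmas zero the path matches
    a deterministic ODE solve to O(dt).
    """
    if dt <= 0 or t_end < dt:
        raise ValueError("require dt > 0 and t_end >= dt")
    drift = CompiledDrift(model)
    n_steps = int(round(t_end / dt))
    idx = _record_indices(n_steps, dt, record_every if record_every is not None else dt)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x0 = model.initial_state() if x0 is None else np.asarray(x0, dtype=float)
    rec, _ = _em_integrate(drift, x0, model.sigma(), dt, n_steps, rng, idx)
    return idx * dt, rec


_ATTRACTOR_CACHE: dict[str, list[np.ndarray]] = {}


def serum_attractors(model: NetworkModel) -> list[np.ndarray]:
    """Stable equilibria of the model's serum/LIF (PD = Chiron = 0)
    deterministic counterpart, sorted by Nanog level.

    Results are memoised on the serialised serum configuration, since the
    same root-finding problem recurs for every population, colony and
    threshold computation built from one parameter set.
    """
    import json

    from .network import model_to_dict

    serum = model.with_inputs(MediumInputs.serum())
    key = json.dumps(model_to_dict(serum), sort_keys=True)
    if key not in _ATTRACTOR_CACHE:
        eqs = find_equilibria(serum)
        _ATTRACTOR_CACHE[key] = [e.state.copy() for e in eqs if e.stable]
    return _ATTRACTOR_CACHE[key]


def nh_threshold(model: NetworkModel) -> float:
    """NH/NL Nanog threshold: midpoint of the two stable serum equilibria.

    Computed on the model's serum counterpart so the same threshold applies
    across media.  Raises if the serum system is not bistable.
    """
    att = serum_attractors(model)
    if len(att) < 2:
        raise ValueError(
            "serum deterministic system is not bistable; supply an explicit threshold"
        )
    i = model.index("NANOG")
    levels = sorted(a[i] for a in att)
    return 0.5 * (levels[0] + levels[-1])


def _initial_population(
    model: NetworkModel,
    n_cells: int,
    rng: np.random.Generator,
    jitter: float = 0.02,
    attractors: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Cells split evenly across the serum attractors with small Gaussian
    jitter (clipped at zero); a monostable variant starts all cells at its
    single attractor."""
    att = serum_attractors(model) if attractors is None else attractors
    n_att = len(att)
    x0 = np.empty((n_cells, model.n_species))
    for i in range(n_cells):
        x0[i] = att[i % n_att]
    x0 += jitter * rng.standard_normal(x0.shape)
    return np.clip(x0, 0.0, None)


def simulate_population(
    model: NetworkModel,
    n_cells: int,
    t_end: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    x0: np.ndarray | None = None,
    record_every: float | None = None,
) -> SimulationEnsemble:
    """Simulate ``n_cells`` independent cells, recording a thinned grid.

    Initial conditions default to an even split across the serum
    attractors with small jitter; pass ``x0`` of shape
    ``(n_cells, n_species)`` to override.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    drift = CompiledDrift(model)
    n_steps = int(round(t_end / dt))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if x0 is None:
        x0 = _initial_population(model, n_cells, rng)
    else:
        x0 = np.asarray(x0, dtype=float)
    idx = _record_indices(n_steps, dt, record_every)
    rec, fin = _em_integrate(drift, x0, model.sigma(), dt, n_steps, rng, idx)
    return SimulationEnsemble(
        times=idx * dt,
        trajectories=np.swapaxes(rec, 0, 1),
        final_states=fin,
        seed=seed,
        model_tag=model.variant_tag,
        species=model.names,
    )


def classify_states(
    ensemble: SimulationEnsemble, threshold: float
) -> StateClassification:
    """Label each cell NH or NL by its final Nanog level (ties -> NH)."""
    if ensemble.n_cells == 0:
        raise ValueError("empty ensemble")
    nan = ensemble.final_nanog()
    high = nan >= threshold
    labels = np.where(high, "NH", "NL")
    return StateClassification(
        threshold=float(threshold),
        labels=labels,
        fraction_high=float(np.mean(high)),
    )


def steady_state_fractions(
    model: NetworkModel,
    n_cells: int = 1000,
    repeats: int = 50,
    burn_in: float = DEFAULT_BURN_IN,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    threshold: float | None = None,
) -> np.ndarray:
    """Per-repeat NH fractions of the steady-state distribution.

    Mirrors the estimation protocol of repeated 1000-cell populations:
    every repeat draws its own seed from the master seed, cells start
    evenly split across the serum attractors, burn in to stationarity and
    are classified by the midpoint threshold at the final time.  All
    repeats are integrated in one stacked state array for speed.
    """
    if threshold is None:
        threshold = nh_threshold(model)
    att = serum_attractors(model)
    drift = CompiledDrift(model)
    n_steps = int(round(burn_in / dt))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x0 = _initial_population(model, repeats * n_cells, rng, attractors=att)
    _, fin = _em_integrate(drift, x0, model.sigma(), dt, n_steps, rng, None)
    nanog = fin[:, model.index("NANOG")].reshape(repeats, n_cells)
    return np.mean(nanog >= threshold, axis=1)


def sorting_experiment(
    model: NetworkModel,
    start_state: str,
    n_cells: int = 1000,
    days: float = 4.0,
    record_every: float = 12.0,
    repeats: int = 10,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    threshold: float | None = None,
    jitter: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """FACS-sorting simulation: a pure NH or NL population relaxing back.

    Every cell starts at the deterministic serum equilibrium of the
    requested state (plus small jitter) and the NH fraction is recorded
    every ``record_every`` hours over ``days`` days.  Returns
    ``(times, fractions)`` with fractions shaped ``(repeats, n_times)``.
    """
    if start_state not in ("NH", "NL"):
        raise ValueError("start_state must be 'NH' or 'NL'")
    att = serum_attractors(model)
    i_n = model.index("NANOG")
    if threshold is None:
        threshold = nh_threshold(model)
    wanted = [a for a in att if (a[i_n] >= threshold) == (start_state == "NH")]
    if not wanted:
        raise ValueError(
            f"model {model.variant_tag!r} has no {start_state} attractor to sort from"
        )
    x_star = wanted[0]
    drift = CompiledDrift(model)
    t_end = days * 24.0
    n_steps = int(round(t_end / dt))
    idx = _record_indices(n_steps, dt, record_every)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x0 = np.tile(x_star, (repeats * n_cells, 1))
    x0 += jitter * rng.standard_normal(x0.shape)
    np.clip(x0, 0.0, None, out=x0)
    rec, _ = _em_integrate(drift, x0, model.sigma(), dt, n_steps, rng, idx)
    nanog = rec[:, :, i_n].reshape(idx.size, repeats, n_cells)
    fractions = np.mean(nanog >= threshold, axis=2).T
    return idx * dt, fractions
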