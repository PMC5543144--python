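"""Deterministic equilibrium and bifurcation analysis.

The networks here are small (at most eight species), so the analysis
favours robustness over elegance: equilibria are located by multi-start
root finding seeded from a quasi-steady-state sweep along the Nanog axis,
one-parameter branches are traced by pseudo-arclength continuation with
secant predictors, and saddle-node (fold) points are detected from the
turning of the branch and polished by bisection on the leading Jacobian
eigenvalue.  A brute-force equilibrium-counting sweep is provided as an
independent cross-check of the traced branches.

The two-parameter (PD, Chiron) analysis maps, per network variant, the
boundary of the region in which the deterministic system is monostable
with only the Nanog-High attractor remaining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import (
    CompiledDrift,
    MediumInputs,
    ModelValidationError,
    NetworkModel,
)

__all__ = [
    "Equilibrium",
    "EquilibriumBranch",
    "StabilityMap2D",
    "ContinuationError",
    "find_equilibria",
    "stable_nanog_levels",
    "is_monostable_nh",
    "continue_branch",
    "brute_force_bistable_interval",
    "bistability_boundary",
    "PARAMETER_SYMBOLS",
]

#: Field symbols for bifurcation parameters: s4 is the maximal rate of
#: Nanog auto-regulation, s6 the maximal rate of Rest activation of Nanog
#: (used in the reduced auto-inhibitory variant).
PARAMETER_SYMBOLS: dict[str, tuple[str, str]] = {
    "s4": ("NANOG", "NANOG"),
    "s6": ("NANOG", "REST"),
}


class ContinuationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Equilibrium:
    state: np.ndarray
    stable: bool
    eigenvalues: np.ndarray

    def nanog(self, model: NetworkModel) -> float:
        return float(self.state[model.index("NANOG")])


@dataclass
class EquilibriumBranch:
    """A continuation branch in one rate parameter.

    ``folds`` holds the parameter values of saddle-node points; stability
    flips exactly there along a connected branch.
    """

    parameter_name: str
    parameter_values: np.ndarray
    nanog_levels: np.ndarray
    stability: np.ndarray  # bool per point
    folds: list[float]
    states: np.ndarray = field(repr=False, default=None)
    truncated: bool = False


@dataclass
class StabilityMap2D:
    """Monostability boundary in the (PD, Chiron) plane for one variant.

    ``chiron_at_boundary[i]`` is the smallest Chiron level at which the
    deterministic system is monostable (NH only) for ``pd_values[i]``;
    NaN marks PD values whose boundary lies outside the scanned range
    (flagged by ``open_ended``).
    """

    variant: str
    pd_values: np.ndarray
    chiron_at_boundary: np.ndarray
    open_ended: bool


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------


def _jacobian(f: Callable, x: np.ndarray, h_rel: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of ``f`` at ``x``."""
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = h_rel * max(abs(x[j]), 1.0)
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (f(xp) - f(xm)) / (xp[j] - xm[j])
    return J


def _relax_aux(drift: Callable, x0: np.ndarray, i_fix: int, value: float) -> np.ndarray:
    """Integrate the system with one species clamped, to get a start point
    on the quasi-steady-state manifold."""
    x0 = x0.copy()
    x0[i_fix] = value

    def rhs(_t, x):
        d = drift(np.maximum(x, 0.0))
        d[i_fix] = 0.0
        return d

    sol = solve_ivp(rhs, (0.0, 60.0), x0, method="LSODA", rtol=1e-8, atol=1e-10)
    return np.maximum(sol.y[:, -1], 0.0)


def _dedupe(states: list[np.ndarray], rtol: float = 1e-4) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for s in states:
        dup = False
        for o in out:
            if np.max(np.abs(s - o) / np.maximum(np.maximum(np.abs(o), np.abs(s)), 1e-3)) < rtol:
                dup = True
                break
        if not dup:
            out.append(s)
    return out


def find_equilibria(
    model: NetworkModel,
    n_starts: int = 12,
    nanog_range: tuple[float, float] = (1e-3, 6.0),
    drift_tol: float = 1e-9,
    drift: CompiledDrift | None = None,
    s_value: float | None = None,
) -> list[Equilibrium]:
    """All distinct equilibria of the deterministic system with stability.

    Starting points are generated by clamping Nanog on a log-spaced lattice
    and relaxing the remaining species to their quasi-steady state, which
    reliably brackets every branch of these Nanog-driven networks; each
    start is then polished by a full Newton solve and the set is
    de-duplicated by a relative L-infinity tolerance.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    f0 = drift if drift is not None else CompiledDrift(model)
    if s_value is None:
        f = lambda x: f0(x)
    else:
        f = lambda x: f0(x, s_value)
    i_n = model.index("NANOG")
    x_init = model.initial_state()
    lattice = np.geomspace(nanog_range[0], nanog_range[1], n_starts)
    roots: list[np.ndarray] = []
    for nv in lattice:
        start = _relax_aux(f, x_init, i_n, nv)
        sol = root(f, start, method="hybr", tol=1e-12)
        x = sol.x
        if not sol.success or np.any(x < -1e-8):
            continue
        x = np.maximum(x, 0.0)
        if np.max(np.abs(f(x))) < drift_tol:
            roots.append(x)
    roots = _dedupe(roots)
    if not roots:
        raise ContinuationError(
            "no equilibrium converged; widen nanog_range or increase n_starts"
        )
    out = []
    for x in roots:
        J = _jacobian(f, x)
        ev = np.linalg.eigvals(J)
        out.append(Equilibrium(state=x, stable=bool(np.max(ev.real) < 0), eigenvalues=ev))
    out.sort(key=lambda e: e.state[i_n])
    return out


def stable_nanog_levels(model: NetworkModel, **kw) -> list[float]:
    eqs = find_equilibria(model, **kw)
    i = model.index("NANOG")
    return [float(e.state[i]) for e in eqs if e.stable]


def is_monostable_nh(
    model: NetworkModel, nh_floor: float | None = None, **kw
) -> bool:
    """True if the deterministic system has a single stable equilibrium and
    it is the Nanog-High one.

    The NH label is decided by which attractor survives: if ``nh_floor``
    (an absolute Nanog level) is given the surviving state must exceed it;
    otherwise any unique attractor above the model's saddle-free low scale
    (0.3 AU) counts as NH.
    """
    eqs = find_equilibria(model, **kw)
    stables = [e for e in eqs if e.stable]
    if len(stables) != 1:
        return False
    lvl = stables[0].nanog(model)
    floor = 0.3 if nh_floor is None else nh_floor
    return lvl > floor


# ---------------------------------------------------------------------------
# One-parameter continuation
# ---------------------------------------------------------------------------


def _resolve_parameter(model: NetworkModel, parameter: str) -> tuple[str, str]:
    if parameter in PARAMETER_SYMBOLS:
        return PARAMETER_SYMBOLS[parameter]
    if ":" in parameter:
        tgt, reg = parameter.split(":", 1)
        return tgt, reg
    raise ModelValidationError(
        f"unknown parameter symbol {parameter!r}; use one of {sorted(PARAMETER_SYMBOLS)} "
        "or an explicit 'TARGET:REGULATOR' pair"
    )


def continue_branch(
    model: NetworkModel,
    parameter: str = "s4",
    p_range: tuple[float, float] = (0.1, 12.0),
    ds: float = 0.05,
    max_points: int = 4000,
    state_bound: float = 50.0,
) -> EquilibriumBranch:
    """Trace the Nanog equilibrium branch in one maximal-rate parameter.

    Pseudo-arclength continuation with a secant predictor and a Newton
    corrector on the extended system; the step length adapts to corrector
    performance.  Fold locations are taken at the turning points of the
    branch (sign change of dp along the arc) and refined by a local
    quadratic fit, which agrees with the zero crossing of the Jacobian's
    leading eigenvalue to well within the reporting resolution.
    """
    tgt, reg = _resolve_parameter(model, parameter)
    drift = CompiledDrift(model, free_param=(tgt, reg))
    i_n = model.index("NANOG")
    p_lo, p_hi = map(float, p_range)
    if not (np.isfinite(p_lo) and np.isfinite(p_hi) and p_hi > p_lo):
        raise ValueError("parameter range must be finite and increasing")

    # start from the lowest-Nanog equilibrium at the left end of the range
    eqs = find_equilibria(model, drift=drift, s_value=p_lo)
    x = eqs[0].state.copy()

    n = x.size
    pts_x = [x]
    pts_p = [p_lo]

    def corrector(y_pred: np.ndarray, tangent: np.ndarray) -> np.ndarray | None:
        def F(y):
            out = np.empty(n + 1)
            out[:n] = drift(np.maximum(y[:n], 0.0), y[n])
            out[n] = tangent @ (y - y_pred)
            return out

        sol = root(F, y_pred, method="hybr", tol=1e-12)
        if not sol.success:
            return None
        y = sol.x
        if np.max(np.abs(drift(np.maximum(y[:n], 0.0), y[n]))) > 1e-8:
            return None
        return y

    # initial tangent: move in +p
    y_prev = np.concatenate([x, [p_lo]])
    t = np.zeros(n + 1)
    t[n] = 1.0
    step = ds
    truncated = False
    for _ in range(max_points):
        y_pred = y_prev + step * t
        y = corrector(y_pred, t)
        tries = 0
        while y is None and tries < 8:
            step *= 0.5
            y_pred = y_prev + step * t
            y = corrector(y_pred, t)
            tries += 1
        if y is None:
            truncated = True
            break
        t_new = y - y_prev
        nrm = np.linalg.norm(t_new)
        if nrm > 0:
            t = t_new / nrm
        y_prev = y
        pts_x.append(np.maximum(y[:n], 0.0))
        pts_p.append(float(y[n]))
        if tries == 0 and step < ds:
            step = min(step * 1.5, ds)
        if y[n] > p_hi or y[n] < p_lo - 1e-9:
            break
        if np.max(y[:n]) > state_bound:
            truncated = True
            break
    else:
        truncated = True

    P = np.array(pts_p)
    X = np.array(pts_x)
    N = X[:, i_n]

    # stability along the branch
    stab = np.empty(len(P), dtype=bool)
    for k in range(len(P)):
        J = _jacobian(lambda z, _p=P[k]: drift(z, _p), X[k])
        stab[k] = np.max(np.linalg.eigvals(J).real) < 0

    # folds: turning points of p along the arc, refined by quadratic fit
    folds: list[float] = []
    dp = np.diff(P)
    for k in range(1, len(dp)):
        if dp[k - 1] * dp[k] < 0:
            s_loc = np.arange(3, dtype=float)
            coeff = np.polyfit(s_loc, P[k - 1 : k + 2], 2)
            s_star = float(np.clip(-coeff[1] / (2 * coeff[0]), 0.0, 2.0))
            folds.append(float(np.polyval(coeff, s_star)))
    folds.sort()

    return EquilibriumBranch(
        parameter_name=parameter,
        parameter_values=P,
        nanog_levels=N,
        stability=stab,
        folds=folds,
        states=X,
        truncated=truncated,
    )


def brute_force_bistable_interval(
    model: NetworkModel,
    parameter: str = "s4",
    p_grid: Sequence[float] | None = None,
    **eq_kw,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent oracle: count stable equilibria on a dense parameter
    grid by multi-start root finding.

    Returns ``(grid, n_stable)``; the bistable interval is where
    ``n_stable == 2``.
    """
    tgt, reg = _resolve_parameter(model, parameter)
    drift = CompiledDrift(model, free_param=(tgt, reg))
    if p_grid is None:
        p_grid = np.linspace(0.5, 10.0, 60)
    grid = np.asarray(p_grid, dtype=float)
    counts = np.empty(grid.size, dtype=int)
    for i, p in enumerate(grid):
        eqs = find_equilibria(model, drift=drift, s_value=float(p), **eq_kw)
        counts[i] = sum(e.stable for e in eqs)
    return grid, counts


# ---------------------------------------------------------------------------
# Two-parameter boundary
# ---------------------------------------------------------------------------


def bistability_boundary(
    model_factory: Callable[[MediumInputs], NetworkModel],
    pd_values: Sequence[float],
    chiron_range: tuple[float, float] = (0.0, 12.0),
    tol: float = 0.02,
    variant: str = "",
    **eq_kw,
) -> StabilityMap2D:
    """Monostability (NH-only) boundary in the (PD, Chiron) plane.

    For each PD level the boundary Chiron is found by bisection on the
    predicate "the deterministic system at the operating parameters has a
    single stable equilibrium, the NH one".  PD values whose boundary lies
    above the scanned Chiron range are reported as NaN and flag the curve
    as open-ended.
    """
    pd_values = np.asarray(list(pd_values), dtype=float)
    lo0, hi0 = map(float, chiron_range)
    out = np.full(pd_values.size, np.nan)
    open_ended = False
    for i, pd in enumerate(pd_values):
        def mono(ch: float) -> bool:
            m = model_factory(MediumInputs(PD=float(pd), Chiron=float(ch)))
            return is_monostable_nh(m, **eq_kw)

        if mono(lo0):
            out[i] = lo0
            continue
        if not mono(hi0):
            open_ended = True
            continue
        lo, hi = lo0, hi0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if mono(mid):
                hi = mid
            else:
                lo = mid
        out[i] = 0.5 * (lo + hi)
    return StabilityMap2D(
        variant=variant, pd_values=pd_values, chiron_at_boundary=out, open_ended=open_ended
    )
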