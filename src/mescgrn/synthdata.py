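"""Synthetic stand-ins for the wet-lab data the analysis consumes.

The pipeline is fitted and validated against two kinds of experimental
measurement: FACS fluorescence distributions of a Nanog reporter
(bimodal in serum/LIF, NH-dominated in 2i/LIF) and 3-day proliferation
assays (cell counts every 24 h, reported as fold change vs day 0 over four
replicates).  Neither is redistributable here, so this module generates
synthetic datasets with the same shape and known ground truth: a lognormal
two-component mixture for FACS (fluorescence is positive and right-skewed)
and ABM-generated growth curves with multiplicative replicate noise.

Every generated dataset records its seed and the true parameters, and
regeneration from the same spec is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abm import CyclePolicy, ProliferationDataset, growth_curve, simulate_colony
from .network import NetworkModel

__all__ = [
    "SyntheticFACSSpec",
    "SyntheticGrowthSpec",
    "make_facs_sample",
    "make_growth_data",
]


@dataclass(frozen=True)
class SyntheticFACSSpec:
    """Two-state reporter-fluorescence sample specification.

    ``mode_low``/``mode_high`` are the median fluorescence levels (AU) of
    the two states; ``spread_low``/``spread_high`` are lognormal shape
    parameters (sd of log fluorescence).
    """

    n_cells: int = 10000
    fraction_high: float = 0.5
    mode_low: float = 0.2
    mode_high: float = 1.0
    spread_low: float = 0.35
    spread_high: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_high <= 1.0:
            raise ValueError("fraction_high must lie in [0, 1]")
        if self.mode_low <= 0 or self.mode_high <= 0:
            raise ValueError("modes must be positive")
        if self.mode_low >= self.mode_high:
            raise ValueError("mode_low must be below mode_high")


def make_facs_sample(spec: SyntheticFACSSpec) -> np.ndarray:
    """Draw a synthetic FACS fluorescence sample (AU).

    A lognormal mixture: each cell is High with probability
    ``fraction_high`` and its fluorescence is lognormal around the state
    mode.  The empirical fraction above the midpoint threshold converges to
    ``fraction_high`` as ``n_cells`` grows (for well-separated modes).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    high = rng.random(spec.n_cells) < spec.fraction_high
    mode = np.where(high, spec.mode_high, spec.mode_low)
    spread = np.where(high, spec.spread_high, spec.spread_low)
    return mode * np.exp(spread * rng.standard_normal(spec.n_cells))


@dataclass(frozen=True)
class SyntheticGrowthSpec:
    """Proliferation-assay specification with a known generating policy."""

    true_policy: CyclePolicy
    medium_tag: str = "serum"
    n_replicates: int = 4
    days: int = 3
    sample_every_h: float = 24.0
    count_noise_cv: float = 0.05
    n0: int = 40
    dt: float = 0.02
    cap: int = 20000
    seed: int = 0


def make_growth_data(
    spec: SyntheticGrowthSpec, model: NetworkModel
) -> tuple[ProliferationDataset, CyclePolicy]:
    """Generate a synthetic proliferation dataset by running the ABM with
    the true policy and applying multiplicative per-replicate count noise.

    Returns ``(dataset, true_policy)``; the truth is carried alongside for
    parameter-recovery tests.
    """
    horizon = spec.days * spec.sample_every_h
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_replicates) % (2**31)
    noise_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 77)))
    folds = []
    days_axis = None
    for s in seeds:
        tr = simulate_colony(
            model, spec.true_policy, n0=spec.n0, t_end=horizon, dt=spec.dt,
            seed=int(s), cap=spec.cap
        )
        ds = growth_curve(tr, sample_every=spec.sample_every_h, horizon=horizon)
        days_axis = ds.times_days
        f = ds.fold_change.copy()
        if spec.count_noise_cv > 0:
            f *= 1.0 + spec.count_noise_cv * noise_rng.standard_normal(f.size)
        f[0] = 1.0
        f = np.maximum.accumulate(f)  # counting noise cannot make colonies shrink
        folds.append(f)
    folds = np.array(folds)
    mean = folds.mean(axis=0)
    mean[0] = 1.0
    se = folds.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates)
    ds = ProliferationDataset(
        times_days=days_axis, fold_change=mean, se=se, replicates=spec.n_replicates
    )
    ds.validate()
    return ds, spec.true_policy
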