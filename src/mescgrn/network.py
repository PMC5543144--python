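"""Regulatory network model of mESC pluripotency in serum/LIF and 2i/LIF.

The model couples the core pluripotency factors (the Oct4-Sox2 heterodimer
and Nanog) to genes differentially expressed between the two culture media
(Mycn, Rest, Prdm14) and to the signalling components that carry the medium
inputs (Fgf4/Erk, beta-catenin, Tcf3).  The two small-molecule inhibitors of
the 2i medium enter as external inputs: PD (MEK inhibitor) weakens the
repression that Fgf/Erk signalling exerts on Nanog auto-regulation, and
Chiron (Gsk3 inhibitor) stabilises beta-catenin by lowering its effective
degradation rate.

Transcriptional regulations are saturating Hill terms; when a gene has
several transcriptional regulators their Hill terms are summed.  mRNA is
assumed at quasi-steady state, so each species is described by a single
protein-level equation

    dx_i/dt = basal_i + sum_j Hill_ij(x) - k_i(x) * x_i

with additive zero-mean Gaussian noise per species in the stochastic
version.  Non-transcriptional regulations are either multiplicative gates
on a transcriptional term (Tcf3 weakening Oct4-Sox2 binding at the Nanog
locus; Erk repressing Nanog auto-regulation, itself attenuated by PD and
Prdm14) or Hill modulators of a degradation rate (Chiron on beta-catenin,
beta-catenin on Tcf3).

All concentrations are in arbitrary units (AU) and time is in hours.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SPECIES_ORDER",
    "INPUT_NAMES",
    "ConfigError",
    "ModelValidationError",
    "DomainError",
    "Species",
    "Attenuator",
    "Modifier",
    "HillTerm",
    "DegModulator",
    "DegradationTerm",
    "SpeciesEquation",
    "MediumInputs",
    "NetworkModel",
    "CompiledDrift",
    "default_params",
    "build_full_network",
    "make_variant",
    "evaluate_drift",
    "serum_model",
    "two_i_model",
    "two_i_unreduced_noise_model",
    "model_to_dict",
    "model_from_dict",
    "load_model",
    "save_model",
]

#: Canonical species order of the full network.  OS is the Oct4-Sox2
#: heterodimer, treated as a single species.
SPECIES_ORDER = ("OS", "NANOG", "MYCN", "REST", "PRDM14", "FGF_ERK", "BCAT", "TCF3")

#: External inputs set by the culture medium (AU).  Both are zero in
#: serum/LIF and equal to 2 AU in the 2i/LIF preset.
INPUT_NAMES = ("PD", "Chiron")


class ConfigError(ValueError):
    """A parameter configuration is missing or malformed."""


class ModelValidationError(ValueError):
    """A constructed model violates a structural invariant."""


class DomainError(ValueError):
    """A state vector lies outside the model's domain (negative orthant)."""


@dataclass(frozen=True)
class Species:
    """A molecular species with a non-negative initial concentration (AU)."""

    name: str
    initial_value: float = 0.1

    def __post_init__(self) -> None:
        if not math.isfinite(self.initial_value) or self.initial_value < 0:
            raise ModelValidationError(
                f"initial value of {self.name!r} must be finite and non-negative"
            )


@dataclass(frozen=True)
class Attenuator:
    """Scales the effective concentration of a modifier's source.

    The factor is ``K / (K + y)`` where ``y`` is the attenuator source level,
    so a high attenuator level suppresses the modifier.  Used for PD and
    Prdm14 weakening Erk's repression of Nanog auto-regulation.
    """

    source: str
    K: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ModelValidationError(f"attenuator K for {self.source!r} must be > 0")


@dataclass(frozen=True)
class Modifier:
    """A repressive multiplicative gate on a transcriptional Hill term.

    The gate factor is ``K^n / (K^n + x_eff^n)`` with
    ``x_eff = x * prod(attenuator factors)``, giving 1 when the modifier
    source is absent and tending to 0 when it saturates.
    """

    source: str
    K: float
    n: float = 1.0
    attenuators: tuple[Attenuator, ...] = ()

    def __post_init__(self) -> None:
        if self.K <= 0 or self.n < 1:
            raise ModelValidationError(
                f"modifier by {self.source!r} requires K > 0 and n >= 1"
            )


@dataclass(frozen=True)
class HillTerm:
    """One saturating production term: activation or repression.

    An activation term evaluates in ``[0, s]`` as ``s x^n / (K^n + x^n)``;
    a repression term as ``s K^n / (K^n + x^n)``.  Optional modifiers
    multiply the term by repressive gate factors in ``(0, 1]``.
    """

    regulator: str
    mode: str  # "activation" | "repression"
    s: float
    K: float
    n: float = 1.0
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "repression"):
            raise ModelValidationError(
                f"term regulated by {self.regulator!r}: unknown mode {self.mode!r}"
            )
        if self.s < 0 or self.K <= 0 or self.n < 1:
            raise ModelValidationError(
                f"term regulated by {self.regulator!r} requires s >= 0, K > 0, n >= 1"
            )


@dataclass(frozen=True)
class DegModulator:
    """Hill modulation of a first-order degradation rate.

    ``direction="down"`` multiplies the rate by ``1 - strength * h(x)`` with
    ``h(x) = x^n / (K^n + x^n)`` and ``0 <= strength < 1`` (Chiron
    stabilising beta-catenin); ``direction="up"`` multiplies by
    ``1 + strength * h(x)`` (beta-catenin destabilising Tcf3).  Either way
    the effective rate stays strictly positive.
    """

    source: str
    direction: str  # "up" | "down"
    K: float
    strength: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ModelValidationError(
                f"degradation modulator by {self.source!r}: bad direction"
            )
        if self.K <= 0 or self.n < 1 or self.strength < 0:
            raise ModelValidationError(
                f"degradation modulator by {self.source!r}: K > 0, n >= 1, strength >= 0"
            )
        if self.direction == "down" and self.strength >= 1:
            raise ModelValidationError(
                f"degradation modulator by {self.source!r}: 'down' strength must be < 1 "
                "to keep the effective rate positive"
            )


@dataclass(frozen=True)
class DegradationTerm:
    base_rate: float
    modulators: tuple[DegModulator, ...] = ()

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ModelValidationError("degradation base rate must be > 0")


@dataclass(frozen=True)
class SpeciesEquation:
    """Right-hand side of one species: basal + summed Hill terms - degradation."""

    basal: float
    terms: tuple[HillTerm, ...]
    degradation: DegradationTerm

    def __post_init__(self) -> None:
        if self.basal < 0:
            raise ModelValidationError("basal production must be >= 0")


@dataclass(frozen=True)
class MediumInputs:
    """External inhibitor levels (AU): PD (MEK inhibitor), Chiron (Gsk3 inhibitor)."""

    PD: float = 0.0
    Chiron: float = 0.0

    def __post_init__(self) -> None:
        if self.PD < 0 or self.Chiron < 0:
            raise ModelValidationError("input levels must be non-negative")

    @classmethod
    def serum(cls) -> "MediumInputs":
        return cls(0.0, 0.0)

    @classmethod
    def two_i(cls, level: float = 2.0) -> "MediumInputs":
        return cls(level, level)


@dataclass
class NetworkModel:
    """A complete parameterised network: the single source of truth for
    drift and noise terms.

    Attributes
    ----------
    species:
        Ordered species list; defines the state-vector layout.
    equations:
        Per-species right-hand sides keyed by species name.
    noise:
        Per-species additive-noise standard deviation (AU h^-1/2).
    inputs:
        Medium inputs (PD, Chiron).
    time_scale:
        Dimensionless normalisation factor multiplying the drift (and
        entering the diffusion as its square root) so that model time
        matches the hours scale of single-cell time-lapse data.
    variant_tag:
        Human-readable label of the topology/medium variant.
    """

    species: tuple[Species, ...]
    equations: dict[str, SpeciesEquation]
    noise: dict[str, float]
    inputs: MediumInputs
    time_scale: float = 1.0
    variant_tag: str = "full"
    extra_params: dict = field(default_factory=dict)

    # -- layout helpers -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ModelValidationError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([sp.initial_value for sp in self.species], dtype=float)

    def sigma(self) -> np.ndarray:
        return np.array([self.noise.get(n, 0.0) for n in self.names], dtype=float)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ModelValidationError("species names must be unique")
        known = set(names) | set(INPUT_NAMES)

        def check_source(src: str, where: str) -> None:
            if src not in known:
                raise ModelValidationError(
                    f"{where}: {src!r} is neither a declared species nor an input"
                )

        for name in names:
            if name not in self.equations:
                raise ModelValidationError(f"species {name!r} has no equation")
        for name, eq in self.equations.items():
            if name not in names:
                raise ModelValidationError(f"equation for undeclared species {name!r}")
            for t in eq.terms:
                check_source(t.regulator, f"term {t.regulator}->{name}")
                for m in t.modifiers:
                    check_source(m.source, f"modifier {m.source} on {t.regulator}->{name}")
                    for a in m.attenuators:
                        check_source(
                            a.source,
                            f"attenuator {a.source} of modifier {m.source} "
                            f"on {t.regulator}->{name}",
                        )
            for dm in eq.degradation.modulators:
                check_source(dm.source, f"degradation modulator {dm.source} on {name}")
        for n in self.noise:
            if n not in names:
                raise ModelValidationError(f"noise sigma for undeclared species {n!r}")
        for n, s in self.noise.items():
            if s < 0:
                raise ModelValidationError(f"noise sigma for {n!r} must be >= 0")
        if self.time_scale <= 0:
            raise ModelValidationError("time_scale must be > 0")

    # -- convenience ----------------------------------------------------
    def with_inputs(self, inputs: MediumInputs, tag: str | None = None) -> "NetworkModel":
        m = copy.deepcopy(self)
        m.inputs = inputs
        if tag is not None:
            m.variant_tag = tag
        return m

    def with_noise_scale(self, name: str, factor: float) -> "NetworkModel":
        m = copy.deepcopy(self)
        m.noise[name] = m.noise.get(name, 0.0) * factor
        return m

    def find_term(self, target: str, regulator: str) -> HillTerm:
        for t in self.equations[target].terms:
            if t.regulator == regulator:
                return t
        raise ModelValidationError(f"no term {regulator}->{target} in this model")

    def set_rate(self, target: str, regulator: str, s: float) -> None:
        """Replace the maximal rate of the ``regulator -> target`` term."""
        eq = self.equations[target]
        new_terms = []
        hit = False
        for t in eq.terms:
            if t.regulator == regulator and not hit:
                new_terms.append(replace(t, s=s))
                hit = True
            else:
                new_terms.append(t)
        if not hit:
            raise ModelValidationError(f"no term {regulator}->{target} in this model")
        self.equations[target] = replace(eq, terms=tuple(new_terms))

    def get_rate(self, target: str, regulator: str) -> float:
        return self.find_term(target, regulator).s

    def edge_summary(self) -> dict[str, int]:
        """Count regulations by class.

        Transcriptional regulations are the Hill production terms;
        non-transcriptional regulations are term modifiers (Tcf3 on the
        Oct4-Sox2 activation of Nanog, Erk on Nanog auto-regulation) and
        degradation modulators (Chiron on beta-catenin, beta-catenin on
        Tcf3).  Attenuators of a modifier (PD and Prdm14 acting on the Erk
        gate) act on a regulation rather than on a gene and are counted
        separately.
        """
        transcriptional = 0
        non_transcriptional = 0
        attenuators = 0
        for eq in self.equations.values():
            transcriptional += len(eq.terms)
            for t in eq.terms:
                non_transcriptional += len(t.modifiers)
                for m in t.modifiers:
                    attenuators += len(m.attenuators)
            non_transcriptional += len(eq.degradation.modulators)
        return {
            "transcriptional": transcriptional,
            "non_transcriptional": non_transcriptional,
            "attenuators": attenuators,
        }


# ---------------------------------------------------------------------------
# Drift compilation
# ---------------------------------------------------------------------------


class CompiledDrift:
    """Vectorised deterministic right-hand side of a :class:`NetworkModel`.

    Calling the object on a state array of shape ``(..., n_species)``
    returns the drift with the same shape.  If ``free_param`` is given as a
    ``(target, regulator)`` pair, the call signature becomes
    ``f(state, s_value)`` with the named term's maximal rate replaced by
    ``s_value`` — used by the continuation module to vary a bifurcation
    parameter without re-building the model.
    """

    def __init__(
        self,
        model: NetworkModel,
        free_param: tuple[str, str] | None = None,
    ) -> None:
        model.validate()
        self._names = model.names
        idx = {n: i for i, n in enumerate(self._names)}
        inputs = {"PD": model.inputs.PD, "Chiron": model.inputs.Chiron}
        self.time_scale = model.time_scale
        self._n = len(self._names)
        self._free_cell = np.array([0.0])
        if free_param is not None:
            # seed the cell with the current value so f(x) still works
            self._free_cell[0] = model.get_rate(*free_param)

        def value_getter(src: str):
            if src in idx:
                j = idx[src]
                return lambda x: x[..., j]
            lvl = float(inputs[src])
            return lambda x, _v=lvl: _v

        self._production: list[Callable] = []
        self._deg: list[Callable] = []

        for i, name in enumerate(self._names):
            eq = model.equations[name]
            basal = float(eq.basal)

            term_fns = []
            for t in eq.terms:
                reg = value_getter(t.regulator)
                Kn = t.K ** t.n
                n = t.n
                act = t.mode == "activation"
                if free_param is not None and (name, t.regulator) == free_param:
                    s_cell = self._free_cell

                    def s_of(_c=s_cell):
                        return _c[0]

                else:
                    s_val = float(t.s)

                    def s_of(_v=s_val):
                        return _v

                mod_fns = []
                for m in t.modifiers:
                    msrc = value_getter(m.source)
                    att = [
                        (value_getter(a.source), float(a.K)) for a in m.attenuators
                    ]
                    mKn = m.K ** m.n
                    mn = m.n

                    def mod(x, _msrc=msrc, _att=att, _mKn=mKn, _mn=mn):
                        e = _msrc(x)
                        for g, Ka in _att:
                            e = e * (Ka / (Ka + g(x)))
                        return _mKn / (_mKn + e ** _mn)

                    mod_fns.append(mod)

                def term(
                    x,
                    _reg=reg,
                    _Kn=Kn,
                    _n=n,
                    _act=act,
                    _s_of=s_of,
                    _mods=tuple(mod_fns),
                ):
                    xv = _reg(x)
                    xn = xv ** _n
                    h = (xn / (_Kn + xn)) if _act else (_Kn / (_Kn + xn))
                    h = _s_of() * h
                    for m in _mods:
                        h = h * m(x)
                    return h

                term_fns.append(term)

            self._production.append((i, basal, tuple(term_fns)))

            base = float(eq.degradation.base_rate)
            dmods = []
            for dm in eq.degradation.modulators:
                src = value_getter(dm.source)
                Kn = dm.K ** dm.n
                up = dm.direction == "up"
                st = float(dm.strength)

                def dmod(x, _src=src, _Kn=Kn, _n=dm.n, _up=up, _st=st):
                    v = _src(x)
                    h = v ** _n
                    h = h / (_Kn + h)
                    return 1.0 + _st * h if _up else 1.0 - _st * h

                dmods.append(dmod)
            self._deg.append((i, base, tuple(dmods)))

    def __call__(self, state: np.ndarray, s_value: float | None = None) -> np.ndarray:
        x = np.asarray(state, dtype=float)
        if x.shape[-1] != self._n:
            raise DomainError(
                f"state has {x.shape[-1]} components, model has {self._n} species"
            )
        if s_value is not None:
            self._free_cell[0] = s_value
        out = np.zeros_like(x)
        for i, basal, terms in self._production:
            tot = basal
            for t in terms:
                tot = tot + t(x)
            out[..., i] += tot
        for i, base, dmods in self._deg:
            rate = base
            for dm in dmods:
                rate = rate * dm(x)
            out[..., i] -= rate * x[..., i]
        if self.time_scale != 1.0:
            out *= self.time_scale
        return out


def evaluate_drift(model: NetworkModel, state: Sequence[float]) -> np.ndarray:
    """Deterministic d(state)/dt for a single non-negative state vector."""
    x = np.asarray(state, dtype=float)
    if x.ndim != 1 or x.size != model.n_species:
        raise DomainError(
            f"state must be a vector of length {model.n_species}, got shape {x.shape}"
        )
    if np.any(x < 0):
        bad = model.names[int(np.argmin(x))]
        raise DomainError(f"negative concentration for {bad!r}")
    return CompiledDrift(model)(x)


# ---------------------------------------------------------------------------
# Configuration <-> model
# ---------------------------------------------------------------------------

#: Transcriptional edges of the full network, as (regulator, target, mode).
FULL_EDGES: tuple[tuple[str, str, str], ...] = (
    ("OS", "OS", "activation"),
    ("REST", "OS", "activation"),
    ("OS", "NANOG", "activation"),
    ("NANOG", "NANOG", "activation"),
    ("REST", "NANOG", "activation"),
    ("NANOG", "MYCN", "repression"),
    ("MYCN", "MYCN", "repression"),
    ("BCAT", "MYCN", "repression"),
    ("NANOG", "REST", "activation"),
    ("BCAT", "REST", "repression"),
    ("OS", "PRDM14", "repression"),
    ("NANOG", "PRDM14", "activation"),
    ("MYCN", "PRDM14", "activation"),
    ("OS", "FGF_ERK", "activation"),
)


def _term_from_cfg(target: str, cfg: Mapping) -> HillTerm:
    for key in ("regulator", "mode", "s", "K"):
        if key not in cfg:
            raise ConfigError(
                f"term {cfg.get('regulator', '?')}->{target}: missing {key!r}"
            )
    mods = []
    for mc in cfg.get("modifiers", ()) or ():
        atts = tuple(
            Attenuator(a["source"], float(a["K"])) for a in mc.get("attenuators", ()) or ()
        )
        mods.append(
            Modifier(
                source=mc["source"],
                K=float(mc["K"]),
                n=float(mc.get("n", 1.0)),
                attenuators=atts,
            )
        )
    return HillTerm(
        regulator=cfg["regulator"],
        mode=cfg["mode"],
        s=float(cfg["s"]),
        K=float(cfg["K"]),
        n=float(cfg.get("n", 1.0)),
        modifiers=tuple(mods),
    )


def _term_to_cfg(t: HillTerm) -> dict:
    d: dict = {"regulator": t.regulator, "mode": t.mode, "s": t.s, "K": t.K, "n": t.n}
    if t.modifiers:
        d["modifiers"] = [
            {
                "source": m.source,
                "K": m.K,
                "n": m.n,
                **(
                    {"attenuators": [{"source": a.source, "K": a.K} for a in m.attenuators]}
                    if m.attenuators
                    else {}
                ),
            }
            for m in t.modifiers
        ]
    return d


def model_from_dict(cfg: Mapping, inputs: MediumInputs | None = None) -> NetworkModel:
    """Build a model from a configuration mapping (the YAML layout)."""
    if "species" not in cfg:
        raise ConfigError("configuration lacks a 'species' section")
    species = []
    equations: dict[str, SpeciesEquation] = {}
    noise: dict[str, float] = {}
    for name, sc in cfg["species"].items():
        species.append(Species(name=name, initial_value=float(sc.get("initial", 0.1))))
        terms = tuple(_term_from_cfg(name, tc) for tc in sc.get("terms", ()) or ())
        dc = sc.get("degradation", None)
        if dc is None:
            raise ConfigError(f"species {name!r}: missing degradation")
        dmods = tuple(
            DegModulator(
                source=m["source"],
                direction=m["direction"],
                K=float(m["K"]),
                strength=float(m["strength"]),
                n=float(m.get("n", 1.0)),
            )
            for m in dc.get("modulators", ()) or ()
        )
        equations[name] = SpeciesEquation(
            basal=float(sc.get("basal", 0.0)),
            terms=terms,
            degradation=DegradationTerm(base_rate=float(dc["rate"]), modulators=dmods),
        )
        noise[name] = float(sc.get("noise", 0.0))
    if inputs is None:
        ic = cfg.get("inputs", {}) or {}
        inputs = MediumInputs(float(ic.get("PD", 0.0)), float(ic.get("Chiron", 0.0)))
    model = NetworkModel(
        species=tuple(species),
        equations=equations,
        noise=noise,
        inputs=inputs,
        time_scale=float(cfg.get("time_scale", 1.0)),
        variant_tag=str(cfg.get("variant_tag", "full")),
        extra_params=dict(cfg.get("variant_params", {}) or {}),
    )
    model.validate()
    return model


def model_to_dict(model: NetworkModel) -> dict:
    """Serialise a model to the configuration mapping (YAML layout)."""
    sp_cfg: dict = {}
    for sp in model.species:
        eq = model.equations[sp.name]
        sc: dict = {
            "initial": sp.initial_value,
            "noise": model.noise.get(sp.name, 0.0),
        }
        if eq.basal:
            sc["basal"] = eq.basal
        if eq.terms:
            sc["terms"] = [_term_to_cfg(t) for t in eq.terms]
        deg: dict = {"rate": eq.degradation.base_rate}
        if eq.degradation.modulators:
            deg["modulators"] = [
                {
                    "source": m.source,
                    "direction": m.direction,
                    "K": m.K,
                    "strength": m.strength,
                    "n": m.n,
                }
                for m in eq.degradation.modulators
            ]
        sc["degradation"] = deg
        sp_cfg[sp.name] = sc
    out: dict = {
        "time_scale": model.time_scale,
        "variant_tag": model.variant_tag,
        "inputs": {"PD": model.inputs.PD, "Chiron": model.inputs.Chiron},
        "species": sp_cfg,
    }
    if model.extra_params:
        out["variant_params"] = model.extra_params
    return out


def load_model(path, inputs: MediumInputs | None = None) -> NetworkModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh), inputs=inputs)


def save_model(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def default_params() -> dict:
    """The shipped calibrated default parameter configuration."""
    from importlib import resources

    with resources.files("mescgrn.params").joinpath("default.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_full_network(
    params: Mapping | None = None, inputs: MediumInputs | None = None
) -> NetworkModel:
    """Build the full eight-species network from a parameter configuration.

    Raises :class:`ConfigError` if any declared interaction lacks parameters
    and :class:`ModelValidationError` if a regulator name is unknown.
    """
    cfg = default_params() if params is None else params
    model = model_from_dict(cfg, inputs=inputs)
    # The full topology must carry exactly the canonical edge list.
    have = {
        (t.regulator, target, t.mode)
        for target, eq in model.equations.items()
        for t in eq.terms
    }
    missing = [e for e in FULL_EDGES if e not in have]
    if missing:
        reg, tgt, mode = missing[0]
        raise ConfigError(f"missing parameters for edge {reg}->{tgt} ({mode})")
    if model.inputs.PD == 0 and model.inputs.Chiron == 0:
        model.variant_tag = "full/serum"
    else:
        model.variant_tag = "full"
    return model


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def serum_model(params: Mapping | None = None) -> NetworkModel:
    """Full network under serum/LIF: PD = Chiron = 0."""
    return build_full_network(params, inputs=MediumInputs.serum())


def two_i_model(params: Mapping | None = None, level: float = 2.0) -> NetworkModel:
    """Full network under 2i/LIF: PD = Chiron = 2 AU and Nanog
    transcriptional noise reduced by 20% relative to serum, matching
    single-molecule FISH measurements in ground-state cultures."""
    m = build_full_network(params, inputs=MediumInputs.two_i(level))
    m.noise["NANOG"] = m.noise.get("NANOG", 0.0) * 0.8
    m.variant_tag = "full/2i"
    return m


def two_i_unreduced_noise_model(
    params: Mapping | None = None, level: float | None = None
) -> NetworkModel:
    """Alternative 2i scenario: Nanog noise kept at its serum value and the
    inputs raised to the smallest calibrated level at which the
    deterministic system is monostable (NH only).  The default elevated
    level ships in the parameter file under ``variant_params``."""
    cfg = default_params() if params is None else params
    if level is None:
        level = float(
            (cfg.get("variant_params", {}) or {}).get("two_i_unreduced_input", 3.0)
        )
    m = build_full_network(cfg, inputs=MediumInputs.two_i(level))
    m.variant_tag = "full/2i-unreduced-noise"
    return m


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_DELETABLE = set(SPECIES_ORDER)


def _strip_species(model: NetworkModel, names: Iterable[str]) -> None:
    """Remove species entirely: their equations and every term, modifier,
    attenuator or degradation modulator that references them."""
    dead = set(names)
    keep = tuple(sp for sp in model.species if sp.name not in dead)
    eqs: dict[str, SpeciesEquation] = {}
    for sp in keep:
        eq = model.equations[sp.name]
        terms = []
        for t in eq.terms:
            if t.regulator in dead:
                continue
            mods = []
            for m in t.modifiers:
                if m.source in dead:
                    continue
                atts = tuple(a for a in m.attenuators if a.source not in dead)
                mods.append(replace(m, attenuators=atts))
            terms.append(replace(t, modifiers=tuple(mods)))
        dmods = tuple(m for m in eq.degradation.modulators if m.source not in dead)
        eqs[sp.name] = replace(
            eq, terms=tuple(terms), degradation=replace(eq.degradation, modulators=dmods)
        )
    model.species = keep
    model.equations = eqs
    model.noise = {k: v for k, v in model.noise.items() if k not in dead}


def make_variant(base: NetworkModel, variant: str) -> NetworkModel:
    """Derive a structural variant of ``base``.

    Descriptors
    -----------
    ``delete:<SPECIES>``
        Gene knock-out: the species' production is removed and its level is
        clamped to 0 everywhere it appears (so a deleted repressor
        de-represses its targets and a deleted gate modifier stops gating).
    ``nanog_activates_bcat``
        Adds a direct transcriptional activation of beta-catenin by Nanog
        (a shortcut for Nanog repression of the beta-catenin inhibitor Dkk1).
    ``reduced_core``
        Keeps only {OS, NANOG, FGF_ERK, BCAT, TCF3}; interactions retained
        from the full network keep their parameter values, while the Erk
        gate on Nanog auto-regulation (which loses its Prdm14 attenuation)
        is re-parameterised from ``variant_params``.
    ``nanog_autoinhibition:via_bcat_tcf3``
        Reduced core with Nanog auto-repression; the positive feedback is
        restored indirectly by Nanog activation of beta-catenin acting
        through Tcf3 (higher Hill coefficients, from ``variant_params``).
    ``nanog_autoinhibition:via_rest``
        Reduced core plus Rest, with Nanog auto-repression and a sharpened
        reciprocal Nanog-Rest positive loop (rate symbol s6 is the Rest
        activation of Nanog).
    ``mycn_bcat:none | mycn_bcat:activation | mycn_bcat:inhibition``
        Alternative beta-catenin/Mycn couplings.
    """
    m = copy.deepcopy(base)
    vp = dict(m.extra_params)

    if variant.startswith("delete:"):
        name = variant.split(":", 1)[1]
        if name in INPUT_NAMES:
            raise ModelValidationError(
                f"{name} is a medium input; set it via MediumInputs, not deletion"
            )
        if name not in m.names:
            raise ModelValidationError(f"cannot delete unknown species {name!r}")
        eq = m.equations[name]
        m.equations[name] = replace(eq, basal=0.0, terms=())
        m.species = tuple(
            replace(sp, initial_value=0.0) if sp.name == name else sp for sp in m.species
        )
        m.noise[name] = 0.0
        m.variant_tag = f"{base.variant_tag}+d{name}"
        m.validate()
        return m

    if variant == "nanog_activates_bcat":
        p = vp.get("nanog_bcat", {"s": 0.3, "K": 0.5, "n": 1.0})
        eq = m.equations["BCAT"]
        term = HillTerm("NANOG", "activation", float(p["s"]), float(p["K"]), float(p.get("n", 1.0)))
        m.equations["BCAT"] = replace(eq, terms=eq.terms + (term,))
        m.variant_tag = f"{base.variant_tag}+NANOG->BCAT"
        m.validate()
        return m

    if variant == "reduced_core":
        _strip_species(m, ("MYCN", "REST", "PRDM14"))
        rc = vp.get("reduced_core", {})
        # Erk gate loses Prdm14 attenuation; re-gauge its K so the serum
        # operating point stays inside the bistable window.
        eq = m.equations["NANOG"]
        terms = []
        for t in eq.terms:
            if t.regulator == "NANOG" and t.modifiers:
                mods = []
                for mod in t.modifiers:
                    if mod.source == "FGF_ERK" and "erk_K" in rc:
                        mods.append(replace(mod, K=float(rc["erk_K"])))
                    else:
                        mods.append(mod)
                terms.append(replace(t, modifiers=tuple(mods)))
            else:
                terms.append(t)
        m.equations["NANOG"] = replace(eq, terms=tuple(terms))
        m.variant_tag = "reduced_core"
        m.validate()
        return m

    if variant.startswith("nanog_autoinhibition"):
        mode = variant.split(":", 1)[1] if ":" in variant else "via_bcat_tcf3"
        if mode == "via_bcat_tcf3":
            m = make_variant(base, "reduced_core")
            p = dict(m.extra_params.get("autoinhibition_bcat", {}))
        elif mode == "via_rest":
            mm = copy.deepcopy(base)
            _strip_species(mm, ("MYCN", "PRDM14"))
            m = mm
            rc = vp.get("reduced_core", {})
            if "erk_K" in rc:
                eq = m.equations["NANOG"]
                terms = []
                for t in eq.terms:
                    mods = tuple(
                        replace(mod, K=float(rc["erk_K"])) if mod.source == "FGF_ERK" else mod
                        for mod in t.modifiers
                    )
                    terms.append(replace(t, modifiers=mods))
                m.equations["NANOG"] = replace(eq, terms=tuple(terms))
            p = dict(vp.get("autoinhibition_rest", {}))
        else:
            raise ModelValidationError(f"unknown auto-inhibition mode {mode!r}")

        # Flip Nanog auto-regulation to repression (keeping the Erk gate on
        # the auto term, which PD still attenuates).
        eq = m.equations["NANOG"]
        terms = []
        for t in eq.terms:
            if t.regulator == "NANOG":
                terms.append(
                    replace(
                        t,
                        mode="repression",
                        s=float(p.get("s4", t.s)),
                        K=float(p.get("K4", t.K)),
                        n=float(p.get("n4", t.n)),
                    )
                )
            else:
                terms.append(t)
        m.equations["NANOG"] = replace(eq, terms=tuple(terms))

        if mode == "via_bcat_tcf3":
            beq = m.equations["BCAT"]
            term = HillTerm(
                "NANOG",
                "activation",
                float(p.get("nb_s", 0.5)),
                float(p.get("nb_K", 0.5)),
                float(p.get("nb_n", 2.0)),
            )
            m.equations["BCAT"] = replace(beq, terms=beq.terms + (term,))
            if "bt_K" in p or "bt_strength" in p or "bt_n" in p:
                teq = m.equations["TCF3"]
                dmods = tuple(
                    replace(
                        dm,
                        K=float(p.get("bt_K", dm.K)),
                        strength=float(p.get("bt_strength", dm.strength)),
                        n=float(p.get("bt_n", dm.n)),
                    )
                    if dm.source == "BCAT"
                    else dm
                    for dm in teq.degradation.modulators
                )
                m.equations["TCF3"] = replace(
                    teq, degradation=replace(teq.degradation, modulators=dmods)
                )
            if "tn_K" in p or "tn_n" in p:
                neq = m.equations["NANOG"]
                terms = []
                for t in neq.terms:
                    mods = tuple(
                        replace(mod, K=float(p.get("tn_K", mod.K)), n=float(p.get("tn_n", mod.n)))
                        if mod.source == "TCF3"
                        else mod
                        for mod in t.modifiers
                    )
                    terms.append(replace(t, modifiers=mods))
                m.equations["NANOG"] = replace(neq, terms=tuple(terms))
            m.variant_tag = "autoinhibition/via_bcat_tcf3"
        else:
            # Sharpen the reciprocal Nanog-Rest loop (rate symbol s6 is the
            # maximal rate of Rest activation on Nanog).
            neq = m.equations["NANOG"]
            terms = []
            for t in neq.terms:
                if t.regulator == "REST":
                    terms.append(
                        replace(
                            t,
                            s=float(p.get("s6", t.s)),
                            K=float(p.get("K6", t.K)),
                            n=float(p.get("n6", t.n)),
                        )
                    )
                else:
                    terms.append(t)
            m.equations["NANOG"] = replace(neq, terms=tuple(terms))
            req = m.equations["REST"]
            terms = []
            for t in req.terms:
                if t.regulator == "NANOG":
                    terms.append(
                        replace(
                            t,
                            s=float(p.get("nr_s", t.s)),
                            K=float(p.get("nr_K", t.K)),
                            n=float(p.get("nr_n", t.n)),
                        )
                    )
                else:
                    terms.append(t)
            m.equations["REST"] = replace(req, terms=tuple(terms))
            m.variant_tag = "autoinhibition/via_rest"
        m.validate()
        return m

    if variant.startswith("mycn_bcat"):
        mode = variant.split(":", 1)[1] if ":" in variant else "inhibition"
        eq = m.equations["MYCN"]
        if mode == "inhibition":
            return m  # the full network's default coupling
        terms = [t for t in eq.terms if t.regulator != "BCAT"]
        if mode == "activation":
            old = next(t for t in eq.terms if t.regulator == "BCAT")
            terms.append(replace(old, mode="activation"))
        elif mode != "none":
            raise ModelValidationError(f"unknown mycn_bcat mode {mode!r}")
        m.equations["MYCN"] = replace(eq, terms=tuple(terms))
        m.variant_tag = f"{base.variant_tag}+mycn_bcat:{mode}"
        m.validate()
        return m

    raise ModelValidationError(f"unknown variant descriptor {variant!r}")
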