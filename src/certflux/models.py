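"""Reaction-network models of CERT-mediated ceramide transfer at the trans-Golgi network.

Two competing seven-species ODE models are encoded, *short distance shuttle*
(SDS) and *neck swinging* (NS).  Both describe the interplay of three
compartment-like modules — PKD (x1 inactive, x2 active), PI4KIIIB (x3
inactive, x4 active) and CERT (x5, x6, x7, whose biological meaning differs
between the variants) — coupled exclusively through *flow-inducing* signals:
mass flows stay inside a module, but their rates are tuned by concentrations
in other modules.

The module provides

* a declarative :class:`ModelStructure` (species, flows, tuning
  dependencies, input channels) built by :func:`build_model`;
* rate-function families satisfying the monotone-kinetics assumption
  (non-negative, differentiable, strictly increasing in each argument on the
  positive orthant, with the activation rates strictly positive at zero);
* a numeric :class:`ModelInstance` whose :meth:`~ModelInstance.rhs`
  evaluates the full right-hand side;
* the published Michaelis–Menten/mass-action parameterization of both
  variants (:func:`weber_parameters`, :func:`weber_instance`), with rate
  constants per minute and concentrations in molecules/cell;
* the invariant simplex bounds of the three module sums
  (:func:`boundedness_box`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "SDS",
    "NS",
    "EXTERNAL",
    "SINK",
    "MODULE_SPECIES",
    "SpeciesState",
    "RateFunction",
    "AffineRate",
    "SaturatingRate",
    "ComposedRate",
    "ConstantRate",
    "RATE_FAMILIES",
    "FlowSpec",
    "ModelStructure",
    "ParameterSet",
    "ModelInstance",
    "build_model",
    "weber_parameters",
    "weber_instance",
    "boundedness_box",
]

SDS = "SDS"
NS = "NS"
EXTERNAL = "EXTERNAL"
SINK = "SINK"

#: canonical module partition of the seven species (1-based indices)
MODULE_SPECIES: Mapping[str, tuple[int, ...]] = {
    "PKD": (1, 2),
    "PI4KIIIB": (3, 4),
    "CERT": (5, 6, 7),
}

_SPECIES_LABELS = {
    SDS: {1: "PKD", 2: "PKDpDAG", 3: "PI4KIIIB", 4: "PI4KIIIBp",
          5: "CERTaER", 6: "CERTp", 7: "CERTaTGN"},
    NS: {1: "PKD", 2: "PKDpDAG", 3: "PI4KIIIB", 4: "PI4KIIIBp",
         5: "CERTa", 6: "CERTp", 7: "CERTaERTGN"},
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesState:
    """One molecular state: a species index 1..7 with its biological label."""

    index: int
    symbol: str
    label: str
    module_id: str


class RateFunction:
    """Base class of the monotone kinetics families.

    Every family evaluates to a non-negative value on non-negative
    arguments and is strictly increasing in each argument on the positive
    orthant.  Subclasses must set ``family`` and expose positive
    ``parameters``.
    """

    family: str = "abstract"

    @property
    def parameters(self) -> dict[str, float]:
        raise NotImplementedError

    def __call__(self, *args: float):
        raise NotImplementedError

    def _check_args(self, *args) -> None:
        for a in args:
            if np.any(np.asarray(a) < 0):
                raise ValueError(f"{self.family} evaluated on negative argument")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class AffineRate(RateFunction):
    """f(z) = a (1 + b z): activation kinetics, strictly positive at z = 0."""

    a: float
    b: float
    family = "affine_f"

    def __post_init__(self) -> None:
        _require_positive(a=self.a, b=self.b)

    @property
    def parameters(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b}

    def __call__(self, z):
        self._check_args(z)
        return self.a * (1.0 + self.b * np.asarray(z, dtype=float))

    def derivative(self, z):
        return self.a * self.b * np.ones_like(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class SaturatingRate(RateFunction):
    """g(z) = a z / (z + b): Michaelis–Menten style saturating kinetics."""

    a: float
    b: float
    family = "saturating_g"

    def __post_init__(self) -> None:
        _require_positive(a=self.a, b=self.b)

    @property
    def parameters(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b}

    def __call__(self, z):
        self._check_args(z)
        z = np.asarray(z, dtype=float)
        return self.a * z / (z + self.b)

    def derivative(self, z):
        z = np.asarray(z, dtype=float)
        return self.a * self.b / (z + self.b) ** 2


@dataclass(frozen=True)
class ComposedRate(RateFunction):
    """h(z, y) = g_j[y g_i(z)]: two saturating stages in series.

    Models activation of PKD by the ceramide-transfer flux, which requires
    both the recruiting kinase activity (argument z) and the carrier
    concentration (argument y).
    """

    a_i: float
    b_i: float
    a_j: float
    b_j: float
    family = "composed_h"

    def __post_init__(self) -> None:
        _require_positive(a_i=self.a_i, b_i=self.b_i, a_j=self.a_j, b_j=self.b_j)

    @property
    def parameters(self) -> dict[str, float]:
        return {"a_i": self.a_i, "b_i": self.b_i, "a_j": self.a_j, "b_j": self.b_j}

    def __call__(self, z, y):
        self._check_args(z, y)
        z = np.asarray(z, dtype=float)
        y = np.asarray(y, dtype=float)
        inner = y * self.a_i * z / (z + self.b_i)
        return self.a_j * inner / (inner + self.b_j)


@dataclass(frozen=True)
class ConstantRate(RateFunction):
    """A positive rate constant (spontaneous conversions, degradations, inflows)."""

    value: float
    family = "constant"

    def __post_init__(self) -> None:
        _require_positive(value=self.value)

    @property
    def parameters(self) -> dict[str, float]:
        return {"value": self.value}

    def __call__(self, *args):
        return self.value


#: registry of rate-function families, keyed by family tag (extensible: any
#: family passing the monotone-kinetics audit in :mod:`certflux.fixtures`
#: may be registered and swapped in)
RATE_FAMILIES: dict[str, type] = {
    "affine_f": AffineRate,
    "saturating_g": SaturatingRate,
    "composed_h": ComposedRate,
    "constant": ConstantRate,
}


@dataclass(frozen=True)
class FlowSpec:
    """A single flow of the network.

    ``kind`` is one of ``inflow`` (EXTERNAL -> species, constant rate
    symbol), ``degradation`` (species -> SINK), ``spontaneous_conversion``
    (flux = rate * x_source) or ``tuned_conversion`` (flux =
    x_source * rate(tuners), where the tuners live in a different module, or
    are an input channel acting on the PKD module).
    """

    source: Union[int, str]
    target: Union[int, str]
    kind: str
    rate_symbol: str
    tuners: tuple = ()

    def __post_init__(self) -> None:
        kinds = {"inflow", "degradation", "spontaneous_conversion", "tuned_conversion"}
        if self.kind not in kinds:
            raise ValueError(f"unknown flow kind {self.kind!r}")
        if self.kind == "tuned_conversion" and not self.tuners:
            raise ValueError("tuned_conversion requires at least one tuner")
        if self.kind != "tuned_conversion" and self.tuners:
            raise ValueError(f"{self.kind} must not declare tuners")


@dataclass(frozen=True)
class ModelStructure:
    """Declarative description of one network variant.

    ``input_channels`` maps channel name to the flow it tunes; u1 tunes the
    x1 -> x2 activation (through f1), u2 the x2 -> x1 deactivation (f2).
    """

    variant: str
    species: tuple[SpeciesState, ...]
    flows: tuple[FlowSpec, ...]
    input_channels: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def module_of(self, index: int) -> str:
        return next(s.module_id for s in self.species if s.index == index)

    def conversions(self) -> list[FlowSpec]:
        return [f for f in self.flows
                if f.kind in ("spontaneous_conversion", "tuned_conversion")]

    def validate(self) -> None:
        """Check the flow-inducing invariants common to both CERT variants."""
        if self.n_species != 7:
            raise ValueError("CERT models have exactly 7 species")
        modules: dict[str, set[int]] = {}
        for s in self.species:
            modules.setdefault(s.module_id, set()).add(s.index)
        if {m: tuple(sorted(v)) for m, v in modules.items()} != \
                {m: v for m, v in MODULE_SPECIES.items()}:
            raise ValueError("modules must partition species as {x1,x2},{x3,x4},{x5,x6,x7}")
        degraded, inflowed = set(), set()
        for f in self.flows:
            if f.kind == "degradation":
                if f.source in degraded:
                    raise ValueError(f"species {f.source} degraded twice")
                degraded.add(f.source)
            elif f.kind == "inflow":
                inflowed.add(f.target)
            else:
                src_mod = self.module_of(f.source)
                if self.module_of(f.target) != src_mod:
                    raise ValueError(
                        f"conversion {f.source}->{f.target} crosses modules "
                        "(violates the flow-inducing property)")
                if f.kind == "tuned_conversion":
                    for t in f.tuners:
                        if isinstance(t, int) and self.module_of(t) == src_mod:
                            raise ValueError(
                                f"tuner x{t} of {f.source}->{f.target} lies in the "
                                "source module; tuning must come from another module")
                        if isinstance(t, str) and src_mod != "PKD":
                            raise ValueError("input channels act on the PKD module only")
        if degraded != {1, 2, 3, 4, 5, 6, 7}:
            raise ValueError("every species needs exactly one degradation flow")
        if inflowed != {1, 3, 5}:
            raise ValueError("inflows must feed exactly x1, x3, x5")

    # -- serialization ------------------------------------------------------

    def to_json(self, indent: int | None = 2) -> str:
        doc = {
            "variant": self.variant,
            "species": [vars(s) for s in self.species],
            "flows": [{"source": f.source, "target": f.target, "kind": f.kind,
                       "rate_symbol": f.rate_symbol, "tuners": list(f.tuners)}
                      for f in self.flows],
            "input_channels": dict(self.input_channels),
        }
        return json.dumps(doc, indent=indent)

    @staticmethod
    def from_json(text: str) -> "ModelStructure":
        doc = json.loads(text)
        species = tuple(SpeciesState(**s) for s in doc["species"])
        flows = tuple(FlowSpec(source=f["source"], target=f["target"], kind=f["kind"],
                               rate_symbol=f["rate_symbol"], tuners=tuple(f["tuners"]))
                      for f in doc["flows"])
        return ModelStructure(variant=doc["variant"], species=species, flows=flows,
                              input_channels=doc.get("input_channels", {}))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_model(variant: str) -> ModelStructure:
    """Build the complete flow list of one variant ("SDS" or "NS").

    Both share: external inflows into x1, x3, x5; self-degradation of every
    species; u1-tuned activation x1->x2 (f1) and u2-tuned deactivation
    x2->x1 (f2); x2-tuned activation x3->x4 (g1) with spontaneous return
    x4->x3 (kappa); and the x2-tuned detachment x7->x6 (g2).

    SDS only: x5->x7 tuned by x4 (g4), spontaneous x6->x5 (lambda), and an
    x1->x2 activation tuned jointly by (x4, x5) through the composed rate h.

    NS only: x6->x7 tuned by x4 (g4), spontaneous x5->x6 (nu) and x6->x5
    (lambda), and the x1->x2 activation tuned by x7 (g7).
    """
    if variant not in (SDS, NS):
        raise ValueError(f"unknown variant {variant!r}: expected 'SDS' or 'NS'")
    labels = _SPECIES_LABELS[variant]
    species = tuple(
        SpeciesState(index=i, symbol=f"x{i}", label=labels[i],
                     module_id=next(m for m, idxs in MODULE_SPECIES.items() if i in idxs))
        for i in range(1, 8))
    deg_symbols = {1: "alpha", 2: "beta", 3: "gamma", 4: "delta",
                   5: "epsilon", 6: "zeta", 7: "eta"}
    flows: list[FlowSpec] = []
    for i, s in ((1, "s1"), (3, "s3"), (5, "s5")):
        flows.append(FlowSpec(EXTERNAL, i, "inflow", s))
    for i in range(1, 8):
        flows.append(FlowSpec(i, SINK, "degradation", deg_symbols[i]))
    # PKD module: channel-tuned interconversion
    flows.append(FlowSpec(1, 2, "tuned_conversion", "f1", ("u1",)))
    flows.append(FlowSpec(2, 1, "tuned_conversion", "f2", ("u2",)))
    # PI4KIIIB module
    flows.append(FlowSpec(3, 4, "tuned_conversion", "g1", (2,)))
    flows.append(FlowSpec(4, 3, "spontaneous_conversion", "kappa"))
    # CERT module and the transfer-activated PKD feedback
    flows.append(FlowSpec(7, 6, "tuned_conversion", "g2", (2,)))
    flows.append(FlowSpec(6, 5, "spontaneous_conversion", "lambda"))
    if variant == SDS:
        flows.append(FlowSpec(5, 7, "tuned_conversion", "g4", (4,)))
        flows.append(FlowSpec(1, 2, "tuned_conversion", "h", (4, 5)))
    else:
        flows.append(FlowSpec(6, 7, "tuned_conversion", "g4", (4,)))
        flows.append(FlowSpec(5, 6, "spontaneous_conversion", "nu"))
        flows.append(FlowSpec(1, 2, "tuned_conversion", "g7", (7,)))
    model = ModelStructure(variant=variant, species=species, flows=tuple(flows),
                           input_channels={"u1": "f1", "u2": "f2"})
    model.validate()
    return model


# ---------------------------------------------------------------------------
# published parameterization
# ---------------------------------------------------------------------------

# Printed values kept as exact decimal strings; rate constants are per
# minute, inflows molecules/cell/min, Michaelis constants molecules/cell.
_WEBER_STRINGS: dict[str, dict[str, str]] = {
    SDS: {
        "p11": "0.6467", "p12": "0.0507", "p13": "0.2064",
        "m11": "2.3412e7", "s1": "4.8511e5",
        "a11": "0.9933", "a12": "9.2877",
        "p21": "8.1888", "p22": "1.8621", "m22": "7191.9",
        "s3": "2.0894e6", "a21": "1.3142", "a22": "0.0030",
        "p31": "636.5506", "p32": "4.7598", "p33": "12861",
        "m31": "4.5024e9", "m33": "7.6925e6", "s5": "139.0702",
        "a31": "2.2868e-4", "a32": "7.8218e-4", "a33": "3.2251e-4",
    },
    NS: {
        "p11": "1.3493", "p12": "7.1440e-4", "p13": "3.1170",
        "m11": "5.9974e5", "s1": "6.2447e5",
        "a11": "0.9933", "a12": "9.2877",
        "p21": "0.5782", "p22": "1.1462", "m22": "2.1550e4",
        "s3": "6.9681e5", "a21": "0.0903", "a22": "8.7353",
        "p31": "3.1330e-4", "p32": "0.0012", "p33": "207.5791",
        "p34": "516.5629", "m31": "6.5757e6", "m33": "7.8586e6",
        "s5": "2122.7", "a31": "0.0046", "a32": "0.0043", "a33": "7.1526e-4",
    },
}


@dataclass(frozen=True)
class ParameterSet:
    """Named positive reals of one published parameterization.

    ``p34`` exists only in the NS variant (the x7 -> x6 detachment scale,
    whose role is played by p33 in the SDS set).
    """

    variant: str
    p11: float
    p12: float
    p13: float
    m11: float
    s1: float
    a11: float
    a12: float
    p21: float
    p22: float
    m22: float
    s3: float
    a21: float
    a22: float
    p31: float
    p32: float
    p33: float
    m31: float
    m33: float
    s5: float
    a31: float
    a32: float
    a33: float
    p34: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.variant == NS and self.p34 is None:
            raise ValueError("NS parameter set requires p34")
        if self.variant == SDS and self.p34 is not None:
            raise ValueError("SDS parameter set has no p34")

    def as_dict(self) -> dict[str, float]:
        d = {k: v for k, v in vars(self).items() if k != "variant" and v is not None}
        return d

    def to_json(self, indent: int | None = 2) -> str:
        strings = _WEBER_STRINGS.get(self.variant, {})
        doc = {"variant": self.variant}
        for k, v in self.as_dict().items():
            # keep the exact printed decimal string when the value is the
            # published one, otherwise emit repr of the float
            if k in strings and float(strings[k]) == v:
                doc[k] = strings[k]
            else:
                doc[k] = repr(v)
        return json.dumps(doc, indent=indent)

    @staticmethod
    def from_json(text: str) -> "ParameterSet":
        doc = json.loads(text)
        variant = doc.pop("variant")
        return ParameterSet(variant=variant, **{k: float(v) for k, v in doc.items()})


def weber_parameters(variant: str) -> ParameterSet:
    """The published parameter values of one variant, bit-exact."""
    if variant not in _WEBER_STRINGS:
        raise ValueError(f"unknown variant {variant!r}")
    values = {k: float(v) for k, v in _WEBER_STRINGS[variant].items()}
    return ParameterSet(variant=variant, **values)


# ---------------------------------------------------------------------------
# numeric instantiation and right-hand side
# ---------------------------------------------------------------------------

@dataclass
class ModelInstance:
    """A structure together with numeric rates: the evaluatable ODE system.

    ``rates`` maps every rate symbol of the structure to either a
    :class:`RateFunction` (tuned conversions) or a positive float
    (constants: inflows, degradations, spontaneous conversions).
    """

    structure: ModelStructure
    rates: Mapping[str, Union[RateFunction, float]]

    def __post_init__(self) -> None:
        missing = {f.rate_symbol for f in self.structure.flows} - set(self.rates)
        if missing:
            raise ValueError(f"missing rates for symbols {sorted(missing)}")
        inflow_syms = {f.rate_symbol for f in self.structure.flows
                       if f.kind == "inflow"}
        for sym, r in self.rates.items():
            if isinstance(r, (int, float)):
                lo_ok = r >= 0 if sym in inflow_syms else r > 0
                if not lo_ok or not math.isfinite(float(r)):
                    raise ValueError(f"rate constant {sym} must be "
                                     f"{'non-negative' if sym in inflow_syms else 'strictly positive'}")

    def constant(self, symbol: str) -> float:
        r = self.rates[symbol]
        if isinstance(r, ConstantRate):
            return r.value
        if isinstance(r, (int, float)):
            return float(r)
        raise TypeError(f"rate {symbol} is not a constant")

    def _flow_rate(self, f: FlowSpec, x: np.ndarray, u1: float, u2: float) -> float:
        """Per-source-molecule conversion rate of one flow (1/min)."""
        r = self.rates[f.rate_symbol]
        if f.kind == "spontaneous_conversion":
            return r.value if isinstance(r, ConstantRate) else float(r)
        args = []
        for t in f.tuners:
            if t == "u1":
                args.append(u1)
            elif t == "u2":
                args.append(u2)
            else:
                args.append(x[t - 1])
        return float(r(*args))

    def flux(self, f: FlowSpec, x: np.ndarray, u1: float = 0.0, u2: float = 0.0) -> float:
        """Mass flux (molecules/cell/min) carried by one flow at state x."""
        if f.kind == "inflow":
            return self.constant(f.rate_symbol)
        rate = (self.constant(f.rate_symbol) if f.kind == "degradation"
                else self._flow_rate(f, x, u1, u2))
        return rate * float(x[f.source - 1])

    def rhs(self, x: Sequence[float], u1: float = 0.0, u2: float = 0.0,
            add: Sequence[float] | None = None) -> np.ndarray:
        """Time derivatives of the seven concentrations.

        ``add`` is an optional persistent additive input vector
        (molecules/cell/min), used by the perturbation experiments.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.structure.n_species,):
            raise ValueError(f"state must have length {self.structure.n_species}")
        if np.any(x < 0):
            raise ValueError("state must be non-negative")
        if u1 < 0 or u2 < 0:
            raise ValueError("inputs must be non-negative")
        dx = np.zeros_like(x)
        for f in self.structure.flows:
            if f.kind == "inflow":
                dx[f.target - 1] += self.constant(f.rate_symbol)
            elif f.kind == "degradation":
                dx[f.source - 1] -= self.constant(f.rate_symbol) * x[f.source - 1]
            else:
                phi = self._flow_rate(f, x, u1, u2) * x[f.source - 1]
                dx[f.source - 1] -= phi
                dx[f.target - 1] += phi
        if add is not None:
            dx = dx + np.asarray(add, dtype=float)
        return dx

    def degradation_rates(self) -> dict[int, float]:
        return {f.source: self.constant(f.rate_symbol)
                for f in self.structure.flows if f.kind == "degradation"}

    def inflows(self) -> dict[int, float]:
        return {f.target: self.constant(f.rate_symbol)
                for f in self.structure.flows if f.kind == "inflow"}


def weber_instance(variant: str, params: ParameterSet | None = None) -> ModelInstance:
    """Instantiate one variant with the published kinetics.

    Mapping to the generic symbols — SDS: f1 = p12(1+u1), f2 = p13(1+u2),
    g1 = p22 z/(z+m22), g2 = p33 z/(z+m33), g4 = p31 z/(z+m31),
    h(z,y) = p11 * y g4(z) / (y g4(z) + m11); degradations alpha..eta =
    (a11, a12, a21, a22, a31, a32, a33); kappa = p21, lambda = p32.
    NS: g7 = p11 z/(z+m11), g4 = p33 z/(z+m31), g2 = p34 z/(z+m33),
    nu = p31 (spontaneous x5 -> x6).

    The published equations contain a single input channel (the step u
    multiplying the activation p12(1+u)); the second channel is implemented
    symmetrically as f2(u2) = p13(1+u2), so the default u2 = 0 reproduces
    the printed system exactly.
    """
    if params is None:
        params = weber_parameters(variant)
    if params.variant != variant:
        raise ValueError("parameter set variant does not match model variant")
    p = params
    structure = build_model(variant)
    rates: dict[str, Union[RateFunction, float]] = {
        "s1": p.s1, "s3": p.s3, "s5": p.s5,
        "alpha": p.a11, "beta": p.a12, "gamma": p.a21, "delta": p.a22,
        "epsilon": p.a31, "zeta": p.a32, "eta": p.a33,
        "kappa": p.p21, "lambda": p.p32,
        "f1": AffineRate(a=p.p12, b=1.0),
        "f2": AffineRate(a=p.p13, b=1.0),
        "g1": SaturatingRate(a=p.p22, b=p.m22),
    }
    if variant == SDS:
        rates["g2"] = SaturatingRate(a=p.p33, b=p.m33)
        rates["g4"] = SaturatingRate(a=p.p31, b=p.m31)
        rates["h"] = ComposedRate(a_i=p.p31, b_i=p.m31, a_j=p.p11, b_j=p.m11)
    else:
        rates["g2"] = SaturatingRate(a=p.p34, b=p.m33)
        rates["g4"] = SaturatingRate(a=p.p33, b=p.m31)
        rates["g7"] = SaturatingRate(a=p.p11, b=p.m11)
        rates["nu"] = p.p31
    return ModelInstance(structure=structure, rates=rates)


# ---------------------------------------------------------------------------
# invariant simplex
# ---------------------------------------------------------------------------

def boundedness_box(instance: ModelInstance,
                    initial_state: Sequence[float] | None = None
                    ) -> tuple[float, float, float]:
    """Bounds (k1, k2, k3) of the positively invariant module-sum simplex.

    Each module sum obeys d/dt(sum) = s_module - (degradations), which is
    negative whenever the sum exceeds s_module / min(module degradation
    rates); conversions cancel in the sum.  If an initial condition is given
    and a module sum starts above its ratio bound, the bound is enlarged to
    that starting value (the sum then decays monotonically, so the box stays
    invariant).
    """
    deg = instance.degradation_rates()
    inflow = instance.inflows()
    bounds = []
    for module, idxs in MODULE_SPECIES.items():
        s = sum(inflow.get(i, 0.0) for i in idxs)
        dmin = min(deg[i] for i in idxs)
        k = s / dmin
        if initial_state is not None:
            x0 = np.asarray(initial_state, dtype=float)
            k = max(k, float(sum(x0[i - 1] for i in idxs)))
        bounds.append(k)
    return tuple(bounds)  # type: ignore[return-value]
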