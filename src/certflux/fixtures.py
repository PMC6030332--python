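"""Synthetic inputs for the parameter-free analysis.

The structural claims must hold for *any* positive parameterization and
any rate functions that are non-negative, differentiable and strictly
increasing in each argument on the positive orthant (with the activation
rates strictly positive at zero).  This module draws such inputs
reproducibly: log-uniform positive parameter sets spanning several orders
of magnitude, rate-function instances from the analytically monotone
families, random initial conditions, and two small pedagogical networks
used as independent oracles.

Every fixture is a pure function of the sampler seed, and a numeric-grid
audit rejects any rate function violating the monotone-kinetics contract
before it is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .models import (
    NS,
    SDS,
    AffineRate,
    ComposedRate,
    ConstantRate,
    FlowSpec,
    ModelInstance,
    ModelStructure,
    ParameterSet,
    RateFunction,
    SaturatingRate,
    SpeciesState,
    weber_parameters,
)

__all__ = [
    "SamplerConfig",
    "sample_parameter_set",
    "sample_rate_functions",
    "sample_initial_state",
    "sample_instance",
    "audit_rate_function",
    "minimal_network",
    "minimal_instance",
    "toy_conversion_module",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Seeded sampling ranges; the seed fixes the entire stream."""

    seed: int = 0
    param_range: tuple[float, float] = (1e-3, 1e3)
    ic_box: tuple[float, float] = (0.0, 1e6)

    def __post_init__(self) -> None:
        lo, hi = self.param_range
        if not (0 < lo < hi):
            raise ValueError("param_range must be a positive interval")
        if not (0 <= self.ic_box[0] < self.ic_box[1]):
            raise ValueError("ic_box must be a non-negative interval")

    def rng(self, stream: str = "") -> np.random.Generator:
        import zlib
        return np.random.default_rng((self.seed, zlib.crc32(stream.encode())))

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "param_range": list(self.param_range),
                           "ic_box": list(self.ic_box)})


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def sample_parameter_set(config: SamplerConfig, variant: str) -> ParameterSet:
    """A random positive parameter set with every entry in the configured range."""
    rng = config.rng(f"params:{variant}")
    lo, hi = config.param_range
    fields = [k for k in weber_parameters(variant).as_dict()]
    values = {k: float(_log_uniform(rng, lo, hi)) for k in sorted(fields)}
    return ParameterSet(variant=variant, **values)


def audit_rate_function(fn: RateFunction, grid_points: int = 100,
                        grid_max: float = 10.0) -> None:
    """Numeric-grid audit of the monotone-kinetics contract.

    Checks non-negativity and strict monotonicity in each argument on a
    positive grid, and strict positivity at zero for the activation family.
    Raises ValueError on violation (fixture generation aborts rather than
    emitting a non-compliant function).
    """
    grid = np.linspace(0.0, grid_max, grid_points)
    if fn.family == "composed_h":
        for other in (0.5, 3.0):
            for vals in (np.array([fn(z, other) for z in grid]),
                         np.array([fn(other, y) for y in grid])):
                if (vals < 0).any():
                    raise ValueError("composed rate negative on grid")
                if not (np.diff(vals) > 0).all():
                    raise ValueError("composed rate not strictly increasing")
        return
    if fn.family == "constant":
        if not fn.value > 0:
            raise ValueError("constant rate must be positive")
        return
    vals = np.asarray(fn(grid), dtype=float)
    if (vals < 0).any():
        raise ValueError(f"{fn.family} negative on grid")
    if not (np.diff(vals) > 0).all():
        raise ValueError(f"{fn.family} not strictly increasing on grid")
    if fn.family == "affine_f" and not fn(0.0) > 0:
        raise ValueError("activation rate must be strictly positive at zero")


def sample_rate_functions(config: SamplerConfig, variant: str = SDS
                          ) -> dict[str, RateFunction]:
    """Audited random instances of {f1, f2, g1, g2, g4, h|g7}."""
    rng = config.rng(f"rates:{variant}")
    lo, hi = config.param_range

    def sat() -> SaturatingRate:
        return SaturatingRate(a=float(_log_uniform(rng, lo, hi)),
                              b=float(_log_uniform(rng, lo, hi)))

    def aff() -> AffineRate:
        return AffineRate(a=float(_log_uniform(rng, lo, hi)),
                          b=float(_log_uniform(rng, lo, hi)))

    out: dict[str, RateFunction] = {
        "f1": aff(), "f2": aff(), "g1": sat(), "g2": sat(), "g4": sat(),
    }
    if variant == SDS:
        inner = out["g4"]
        out["h"] = ComposedRate(a_i=inner.a, b_i=inner.b,
                                a_j=float(_log_uniform(rng, lo, hi)),
                                b_j=float(_log_uniform(rng, lo, hi)))
    else:
        out["g7"] = sat()
    for fn in out.values():
        audit_rate_function(fn)
    return out


def sample_initial_state(config: SamplerConfig, n: int = 7) -> np.ndarray:
    rng = config.rng("ic")
    lo, hi = config.ic_box
    return rng.uniform(lo, hi, size=n)


def sample_instance(config: SamplerConfig, variant: str) -> ModelInstance:
    """A full random instantiation: random parameters and rate functions.

    Constants (inflows, degradations, spontaneous rates) come from the
    random parameter set; the tuned rates come from the audited families.
    """
    from .models import build_model

    p = sample_parameter_set(config, variant)
    fns = sample_rate_functions(config, variant)
    rates: dict[str, Union[RateFunction, float]] = {
        "s1": p.s1, "s3": p.s3, "s5": p.s5,
        "alpha": p.a11, "beta": p.a12, "gamma": p.a21, "delta": p.a22,
        "epsilon": p.a31, "zeta": p.a32, "eta": p.a33,
        "kappa": p.p21, "lambda": p.p32,
        **fns,
    }
    if variant == NS:
        rates["nu"] = p.p31
    return ModelInstance(structure=build_model(variant), rates=rates)


# ---------------------------------------------------------------------------
# pedagogical networks
# ---------------------------------------------------------------------------

def minimal_network() -> ModelStructure:
    """The minimal flow-inducing network: one two-species module plus a
    flow-inducing signal.

    Species A and B form a conserved module (no inflow, no degradation);
    the A -> B flow is tuned by the external species E (one meta-arc),
    while the B -> A flow is spontaneous.  With E frozen, a + b is
    conserved and the equilibrium balances the two fluxes.
    """
    species = (
        SpeciesState(index=1, symbol="a", label="A", module_id="AB"),
        SpeciesState(index=2, symbol="b", label="B", module_id="AB"),
        SpeciesState(index=3, symbol="e", label="E", module_id="ENV"),
    )
    flows = (
        FlowSpec(1, 2, "tuned_conversion", "fa", (3,)),
        FlowSpec(2, 1, "spontaneous_conversion", "fb"),
    )
    return ModelStructure(variant="MINIMAL", species=species, flows=flows)


def minimal_instance(fa: RateFunction | None = None,
                     fb_rate: float = 1.0) -> ModelInstance:
    if fa is None:
        fa = SaturatingRate(a=2.0, b=1.0)
    return ModelInstance(structure=minimal_network(),
                         rates={"fa": fa, "fb": fb_rate})


def toy_conversion_module() -> ModelStructure:
    """Two-species module with explicit equilibrium, used as a closed-form
    oracle for the vertex test.

    da/dt = -d1 a + d2 b, db/dt = d1 a - (d2 + d3) b: conversion A -> B at
    rate d1, back-conversion at d2, degradation of B at d3.  With a
    persistent input u on the A equation the equilibrium is b = u / d3, so
    the steady-state influence of the input on B is analytically positive.
    """
    species = (
        SpeciesState(index=1, symbol="a", label="A", module_id="M"),
        SpeciesState(index=2, symbol="b", label="B", module_id="M"),
    )
    flows = (
        FlowSpec(1, 2, "spontaneous_conversion", "d1"),
        FlowSpec(2, 1, "spontaneous_conversion", "d2"),
        FlowSpec(2, "SINK", "degradation", "d3"),
    )
    return ModelStructure(variant="TOY2", species=species, flows=flows)
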