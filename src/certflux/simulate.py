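"""Numeric integration and step-perturbation experiments.

The published parameterizations are stiff (degradation time constants span
four orders of magnitude), so trajectories are computed with a
stiff-capable solver at tight relative tolerance.  Steady states are found
by long-horizon integration polished with a Newton root solve, which makes
the signed steady-state differences of the perturbation experiments
reliable far below the sign-extraction threshold.

A perturbation experiment reproduces the published protocol: integrate to
steady state, apply a persistent step (through an input channel, or as an
additive constant on one state equation), let the system settle, and read
the sign of the steady-state change of every variable and of the
circular-flow output.  The empirical sign grid must never contradict a
determinate structural sign — this is the falsifiability criterion the
structural analysis is built for.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .models import MODULE_SPECIES, ModelInstance, boundedness_box
from .structural import _flow_output_flows, jacobian_template

__all__ = [
    "ExperimentSchedule",
    "Trajectory",
    "PerturbationResult",
    "SimulatedInfluence",
    "FIG6_INITIAL_STATE",
    "FIG7_INITIAL_STATE",
    "flow_output",
    "integrate",
    "find_steady_state",
    "perturbation_experiment",
    "simulated_influence_matrix",
    "default_step_magnitude",
    "sign_of_change",
]

#: initial conditions of the published SDS step experiment (molecules/cell)
FIG6_INITIAL_STATE = np.array([5e5, 2e3, 2e6, 9e4, 5e5, 2e3, 2e3])
#: initial conditions of the published NS step experiment (molecules/cell)
FIG7_INITIAL_STATE = np.array([5.7e5, 6.4e3, 2.07e6, 5.8e4, 4.4e5, 1.6e3, 6.8e4])

#: relative steady-state change below which a response counts as '0'.
#: Steady states are Newton-polished to ~1e-12 relative accuracy, so 1e-9
#: keeps three orders of safety margin over the numerical noise floor while
#: still resolving strongly attenuated cross-module responses (which reach
#: ~1e-9..1e-6 relative at the default 1% input magnitudes).
SIGN_REL_THRESHOLD = 1e-9
#: floor guarding relative changes against zero baselines (molecules/cell)
SIGN_FLOOR = 1e-12


@dataclass(frozen=True)
class ExperimentSchedule:
    """A step-input protocol: settle, step, settle again.

    ``channel`` is "u1", "u2" or a 1-based equation index (additive input on
    that state equation); durations are minutes, magnitude is the step size
    (dimensionless for channels, molecules/cell/min for equation inputs).
    """

    initial_state: Sequence[float]
    pre_step_duration: float
    channel: Union[str, int]
    magnitude: float
    post_step_duration: float

    def __post_init__(self) -> None:
        if not (self.pre_step_duration > 0 and self.post_step_duration > 0):
            raise ValueError("durations must be positive")
        if not self.magnitude > 0:
            raise ValueError("magnitude must be positive")
        if np.any(np.asarray(self.initial_state, dtype=float) < 0):
            raise ValueError("initial state must be non-negative")

    def inputs(self) -> tuple[float, float, np.ndarray | None]:
        """(u1, u2, additive vector) realized after the step."""
        if self.channel == "u1":
            return self.magnitude, 0.0, None
        if self.channel == "u2":
            return 0.0, self.magnitude, None
        add = np.zeros(7)
        add[int(self.channel) - 1] = self.magnitude
        return 0.0, 0.0, add


@dataclass
class Trajectory:
    """A time course: minutes, the seven states, and the flow output."""

    t: np.ndarray
    x: np.ndarray          # shape (7, nt)
    phi: np.ndarray

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("time_min," + ",".join(f"x{i}" for i in range(1, 8)) + ",phi\n")
        for k in range(self.t.size):
            row = [f"{self.t[k]:.10g}"] + [f"{self.x[i, k]:.10g}" for i in range(7)]
            row.append(f"{self.phi[k]:.10g}")
            buf.write(",".join(row) + "\n")
        return buf.getvalue()


@dataclass
class PerturbationResult:
    """Signed steady-state response to one persistent step input."""

    schedule: ExperimentSchedule
    pre_state: np.ndarray
    post_state: np.ndarray
    signs: tuple[str, ...]          # per variable, in {+, -, 0}
    flow_sign: str
    rel_threshold: float
    trajectory: Trajectory | None = None


def flow_output(instance: ModelInstance, x: Sequence[float],
                u1: float = 0.0, u2: float = 0.0):
    """Circular-flow output: total flux on the minimal loop through x7.

    SDS: lambda*x6 + x7*g2(x2) + x5*g4(x4); NS: x6*g4(x4) + x7*g2(x2).
    Accepts a state vector or a (7, nt) array of states.
    """
    template = jacobian_template(instance.structure)
    loop = _flow_output_flows(template)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[:, None] if single else x
    phi = np.zeros(X.shape[1])
    for k in range(X.shape[1]):
        phi[k] = sum(instance.flux(f, X[:, k], u1, u2) for f, _ in loop)
    return float(phi[0]) if single else phi


def _solver_tolerances(instance: ModelInstance, x0: np.ndarray,
                       rtol: float) -> tuple[float, np.ndarray]:
    scale = np.maximum(1.0, np.abs(x0))
    k = boundedness_box(instance, x0)
    for m, (module, idxs) in enumerate(MODULE_SPECIES.items()):
        for i in idxs:
            scale[i - 1] = max(scale[i - 1], k[m])
    return rtol, rtol * scale * 1e-2


def integrate(instance: ModelInstance, t_span: tuple[float, float],
              initial_state: Sequence[float], u1: float = 0.0, u2: float = 0.0,
              add: Sequence[float] | None = None, rtol: float = 1e-8,
              t_eval: Sequence[float] | None = None,
              method: str = "LSODA") -> Trajectory:
    """Integrate the system with a stiff-capable solver (rtol <= 1e-8)."""
    x0 = np.asarray(initial_state, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    rtol, atol = _solver_tolerances(instance, x0, rtol)

    def f(t, x):
        # the solver may step marginally below zero; clip for rate
        # evaluation only (the model itself rejects negative states)
        return instance.rhs(np.maximum(x, 0.0), u1=u1, u2=u2, add=add)

    sol = solve_ivp(f, t_span, x0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.3g} min: "
                           f"{sol.message}")
    x = np.maximum(sol.y, 0.0)
    phi = flow_output(instance, x, u1, u2)
    return Trajectory(t=sol.t, x=x, phi=phi)


def _slowest_timescale(instance: ModelInstance) -> float:
    return 1.0 / min(instance.degradation_rates().values())


def find_steady_state(instance: ModelInstance, initial_state: Sequence[float],
                      u1: float = 0.0, u2: float = 0.0,
                      add: Sequence[float] | None = None,
                      horizon: float | None = None,
                      rtol: float = 1e-8) -> np.ndarray:
    """Equilibrium reached from an initial state.

    Integrates over ten times the slowest degradation time constant (the
    default horizon) and polishes the endpoint with a Newton root solve;
    the result satisfies ||rhs|| <= 1e-9 (1 + ||x||).
    """
    if horizon is None:
        horizon = 10.0 * _slowest_timescale(instance)
    traj = integrate(instance, (0.0, horizon), initial_state,
                     u1=u1, u2=u2, add=add, rtol=rtol)
    x_end = traj.x[:, -1]

    def f(x):
        return instance.rhs(np.maximum(x, 0.0), u1=u1, u2=u2, add=add)

    sol = root(f, x_end, method="hybr", tol=1e-13)
    x_ss = np.maximum(sol.x, 0.0)
    res = np.linalg.norm(instance.rhs(x_ss, u1=u1, u2=u2, add=add))
    if res > 1e-9 * (1.0 + np.linalg.norm(x_ss)):
        raise RuntimeError(f"steady state not reached: residual {res:.3g} "
                           f"after horizon {horizon:.3g} min")
    return x_ss


def sign_of_change(pre: float, post: float,
                   rel_threshold: float = SIGN_REL_THRESHOLD,
                   floor: float = SIGN_FLOOR) -> str:
    """'+', '-' or '0' from the relative steady-state change."""
    rel = (post - pre) / max(abs(pre), floor)
    if rel > rel_threshold:
        return "+"
    if rel < -rel_threshold:
        return "-"
    return "0"


def perturbation_experiment(instance: ModelInstance,
                            schedule: ExperimentSchedule,
                            with_trajectory: bool = True,
                            rtol: float = 1e-8) -> PerturbationResult:
    """Run one settle-step-settle experiment and sign the responses."""
    u1, u2, add = schedule.inputs()
    pre = find_steady_state(instance, schedule.initial_state, rtol=rtol)
    post = find_steady_state(instance, pre, u1=u1, u2=u2, add=add, rtol=rtol)
    signs = tuple(sign_of_change(pre[i], post[i]) for i in range(7))
    flow_sign = sign_of_change(flow_output(instance, pre),
                               flow_output(instance, post, u1, u2))
    trajectory = None
    if with_trajectory:
        t0 = schedule.pre_step_duration
        t1 = t0 + schedule.post_step_duration
        before = integrate(instance, (0.0, t0), schedule.initial_state,
                           rtol=rtol, t_eval=np.linspace(0.0, t0, 201))
        after = integrate(instance, (t0, t1), before.x[:, -1], u1=u1, u2=u2,
                          add=add, rtol=rtol, t_eval=np.linspace(t0, t1, 2001))
        trajectory = Trajectory(t=np.concatenate([before.t, after.t[1:]]),
                                x=np.concatenate([before.x, after.x[:, 1:]], axis=1),
                                phi=np.concatenate([before.phi, after.phi[1:]]))
    return PerturbationResult(schedule=schedule, pre_state=pre, post_state=post,
                              signs=signs, flow_sign=flow_sign,
                              rel_threshold=SIGN_REL_THRESHOLD,
                              trajectory=trajectory)


def default_step_magnitude(instance: ModelInstance, equation: int) -> float:
    """Additive step size for an equation-targeted input.

    One percent of the species' external inflow where one exists, otherwise
    1e3 molecules/cell/min.
    """
    inflow = instance.inflows().get(equation)
    return 0.01 * inflow if inflow is not None else 1e3


@dataclass
class SimulatedInfluence:
    """Empirical sign grid of the perturbation experiments.

    Orientation matches the structural influence matrix: entry (i, j) is
    the signed steady-state change of x_i under an additive step on the
    equation of x_j; ``u1``/``u2`` are per-variable channel columns and
    ``flow`` collects the flow-output signs over (u1, u2, eq1..eq7).
    """

    variant: str
    grid: tuple[tuple[str, ...], ...]
    u1: tuple[str, ...]
    u2: tuple[str, ...]
    flow: tuple[str, ...]
    magnitudes: Mapping[str, float] = field(default_factory=dict)
    orientation: str = "rows=outputs;columns=perturbed_equation"


def simulated_influence_matrix(instance: ModelInstance,
                               initial_state: Sequence[float],
                               channel_magnitude: float = 1e5,
                               equation_magnitudes: Mapping[int, float] | None = None,
                               rtol: float = 1e-8) -> SimulatedInfluence:
    """Empirical influence signs from 7 equation steps plus both channels.

    One shared pre-step steady state is computed from ``initial_state``;
    each experiment then finds the post-step steady state and signs the
    per-variable and flow-output changes against the relative threshold.
    """
    pre = find_steady_state(instance, initial_state, rtol=rtol)
    phi_pre = flow_output(instance, pre)
    magnitudes: dict[str, float] = {}
    columns: list[tuple[str, ...]] = []
    flow_eq: list[str] = []
    for j in range(1, 8):
        mag = (equation_magnitudes or {}).get(j) or default_step_magnitude(instance, j)
        magnitudes[f"eq{j}"] = mag
        add = np.zeros(7)
        add[j - 1] = mag
        post = find_steady_state(instance, pre, add=add, rtol=rtol)
        columns.append(tuple(sign_of_change(pre[i], post[i]) for i in range(7)))
        flow_eq.append(sign_of_change(phi_pre, flow_output(instance, post)))
    channel_signs: dict[str, tuple[str, ...]] = {}
    flow_ch: dict[str, str] = {}
    for ch in ("u1", "u2"):
        magnitudes[ch] = channel_magnitude
        u1, u2 = (channel_magnitude, 0.0) if ch == "u1" else (0.0, channel_magnitude)
        post = find_steady_state(instance, pre, u1=u1, u2=u2, rtol=rtol)
        channel_signs[ch] = tuple(sign_of_change(pre[i], post[i]) for i in range(7))
        flow_ch[ch] = sign_of_change(phi_pre, flow_output(instance, post, u1, u2))
    grid = tuple(tuple(columns[j][i] for j in range(7)) for i in range(7))
    return SimulatedInfluence(variant=instance.structure.variant, grid=grid,
                              u1=channel_signs["u1"], u2=channel_signs["u2"],
                              flow=(flow_ch["u1"], flow_ch["u2"], *flow_eq),
                              magnitudes=magnitudes)
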