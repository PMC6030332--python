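"""Structural (parameter-free) steady-state influence analysis.

Around any asymptotically stable equilibrium, the sign of the steady-state
response of an output ``y = H x`` to a persistent additive input ``E u`` is

    sign det [[-J, -E], [H, 0]],

where ``J`` is the Jacobian at the equilibrium.  For the flow-inducing CERT
networks the Jacobian admits a *BDC decomposition* ``J = sum_i d_i M_i``
with positive scalars ``d_i`` (equilibrium rate values and partial
derivatives) and rank-one matrices ``M_i``, each confined to a single
column.  The bordered determinant is then *multi-affine* in the ``d_i``, so
its sign range over the positive orthant is decided at the vertices of the
unit hypercube: the vertex enumeration yields '+' (structurally positive
for every admissible parameterization), '-', '0' (structural perfect
adaptation) or '?' (parameter-dependent).

All vertex evaluations are integer-exact: determinants are computed in
floating point, rounded, and re-verified with fraction-free (Bareiss)
integer elimination whenever the rounding margin is not comfortable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .models import FlowSpec, ModelStructure

__all__ = [
    "SIGNS",
    "GateWarning",
    "DirectionParameter",
    "JacobianTemplate",
    "BDCDecomposition",
    "BorderedProblem",
    "InfluenceMatrix",
    "ConsistencyReport",
    "jacobian_template",
    "bdc_decompose",
    "multiaffinity_check",
    "vertex_sign",
    "influence_matrix",
    "channel_influence",
    "flow_influence",
    "structural_summary",
    "compare",
    "sampling_oracle",
    "indeterminacy_witness",
    "block_structure_checks",
]

#: the four-symbol alphabet of structural signs
SIGNS = ("+", "-", "0", "?")

_DEFAULT_CHUNK = 1 << 16


class GateWarning(UserWarning):
    """det(-J) is not structurally non-negative over the vertex set.

    The influence-sign formula presumes a stable equilibrium, where
    det(-J) > 0; the hypercube of independent direction parameters
    overapproximates the set of directions realizable at an equilibrium, so
    a negative vertex does not invalidate the sign result, but it is
    reported rather than silently ignored.
    """


# ---------------------------------------------------------------------------
# Jacobian template and BDC decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionParameter:
    """One positive scalar direction of the BDC decomposition.

    ``incidence`` is the signed column pattern the parameter contributes,
    confined to Jacobian column ``column`` (0-based); ``meaning`` records
    which equilibrium quantity it denotes (a rate value, an equilibrium
    concentration times a partial derivative, or a rate constant).
    """

    name: str
    column: int
    incidence: tuple[int, ...]
    meaning: str = ""

    def matrix(self) -> np.ndarray:
        n = len(self.incidence)
        M = np.zeros((n, n), dtype=np.int64)
        M[:, self.column] = self.incidence
        return M


@dataclass(frozen=True)
class JacobianTemplate:
    """The symbolic Jacobian of one model as a sum of rank-one directions.

    ``flow_directions`` maps each conversion flow to the indices of the
    directions its linearization produces (value direction first); it is
    what lets a flow output row be assembled from the template's own
    parameters.
    """

    structure: ModelStructure
    directions: tuple[DirectionParameter, ...]
    flow_directions: Mapping[FlowSpec, tuple[int, ...]] = field(default_factory=dict)

    @property
    def variant(self) -> str:
        return self.structure.variant

    @property
    def n(self) -> int:
        return len(self.directions[0].incidence)

    @property
    def q(self) -> int:
        return len(self.directions)

    def direction_matrices(self) -> np.ndarray:
        """Stacked incidence matrices, shape (q, n, n)."""
        return np.stack([d.matrix() for d in self.directions])

    def assemble(self, d: Sequence[float]) -> np.ndarray:
        """J(d) = sum_i d_i M_i for one positive direction assignment."""
        d = np.asarray(d, dtype=float)
        if d.shape != (self.q,):
            raise ValueError(f"direction vector must have length {self.q}")
        return np.tensordot(d, self.direction_matrices().astype(float), axes=(0, 0))

    def _key(self) -> tuple:
        return tuple((p.name, p.column, p.incidence) for p in self.directions)


#: list of (direction, rank-one matrix) pairs with verified reassembly
BDCDecomposition = list  # of (DirectionParameter, np.ndarray)


def _species_indices(structure: ModelStructure) -> list[int]:
    return [s.index for s in structure.species]


def jacobian_template(model: ModelStructure) -> JacobianTemplate:
    """Build the direction-parameter decomposition of a model's Jacobian.

    Every flow contributes directions confined to single columns:

    * degradation of x_i at rate c: incidence -e_i in column i;
    * spontaneous conversion s -> t at rate c: incidence e_t - e_s in
      column s;
    * tuned conversion s -> t with rate r(tuners): a *value* direction
      r(x̄) in column s, plus one *derivative* direction
      x̄_s ∂r/∂x_k per species tuner k in column k (channel tuners are
      frozen inputs and add no state column).

    Directions with identical (column, incidence) are merged: they multiply
    the same rank-one matrix, so only their sum matters (for both variants
    this merges the equilibrium activation rate with the channel rate f1,
    giving 19 independent directions from 20 raw parameters).
    """
    indices = _species_indices(model)
    pos = {idx: k for k, idx in enumerate(indices)}
    n = len(indices)

    def inc(target_terms: dict[int, int]) -> tuple[int, ...]:
        v = [0] * n
        for idx, sgn in target_terms.items():
            v[pos[idx]] += sgn
        return tuple(v)

    raw: list[tuple[str, int, tuple[int, ...], str, FlowSpec | None]] = []
    for f in model.flows:
        if f.kind == "inflow":
            continue
        if f.kind == "degradation":
            raw.append((f.rate_symbol, pos[f.source], inc({f.source: -1}),
                        f"degradation rate of x{f.source}", None))
        elif f.kind == "spontaneous_conversion":
            raw.append((f.rate_symbol, pos[f.source], inc({f.source: -1, f.target: 1}),
                        f"spontaneous x{f.source}->x{f.target} rate", f))
        else:
            args = ",".join(str(t) if isinstance(t, str) else f"x{t}" for t in f.tuners)
            raw.append((f"{f.rate_symbol}({args})", pos[f.source],
                        inc({f.source: -1, f.target: 1}),
                        f"equilibrium value of {f.rate_symbol} tuning x{f.source}->x{f.target}", f))
            for t in f.tuners:
                if isinstance(t, int):
                    raw.append((f"x{f.source}*d{f.rate_symbol}/dx{t}", pos[t],
                                inc({f.source: -1, f.target: 1}),
                                f"x̄{f.source} times ∂{f.rate_symbol}/∂x{t} at equilibrium", f))
    merged: dict[tuple[int, tuple[int, ...]], list[int]] = {}
    order: list[tuple[int, tuple[int, ...]]] = []
    for k, (_, col, incidence, _, _) in enumerate(raw):
        key = (col, incidence)
        if key not in merged:
            merged[key] = []
            order.append(key)
        merged[key].append(k)
    directions: list[DirectionParameter] = []
    for key in order:
        members = merged[key]
        name = "+".join(raw[k][0] for k in members)
        meaning = "; ".join(raw[k][3] for k in members)
        directions.append(DirectionParameter(name=name, column=key[0],
                                             incidence=key[1], meaning=meaning))
    dir_index = {key: i for i, key in enumerate(order)}
    flow_directions: dict[FlowSpec, tuple[int, ...]] = {}
    for k, (_, col, incidence, _, f) in enumerate(raw):
        if f is not None:
            flow_directions.setdefault(f, ())
            flow_directions[f] += (dir_index[(col, incidence)],)
    return JacobianTemplate(structure=model, directions=tuple(directions),
                            flow_directions=flow_directions)


def _check_single_column(directions: Iterable[DirectionParameter]) -> str | None:
    """Return the name of a parameter spanning several columns, if any."""
    seen: dict[str, int] = {}
    for p in directions:
        for piece in p.name.split("+"):
            if piece in seen and seen[piece] != p.column:
                return piece
            seen[piece] = p.column
    return None


def bdc_decompose(template: JacobianTemplate) -> BDCDecomposition:
    """The list of (direction, rank-one matrix) pairs of the decomposition.

    Rejects templates in which one parameter spans several columns (the
    multi-affine contract of the vertex test would be violated) and
    verifies rank-1 and the reassembly identity on a random positive draw.
    """
    offender = _check_single_column(template.directions)
    if offender is not None:
        raise ValueError(f"parameter {offender!r} spans multiple columns; "
                         "the decomposition is not multi-affine")
    pairs = []
    for p in template.directions:
        M = p.matrix()
        if np.linalg.matrix_rank(M) != 1:
            raise ValueError(f"direction {p.name} is not rank one")
        pairs.append((p, M))
    rng = np.random.default_rng(0)
    d = rng.uniform(0.5, 2.0, size=template.q)
    J = sum(di * M for (_, M), di in zip(pairs, d))
    if not np.allclose(J, template.assemble(d)):
        raise AssertionError("reassembly identity failed")
    return pairs


# ---------------------------------------------------------------------------
# bordered problems
# ---------------------------------------------------------------------------

InputSpec = Union[tuple, str, int]


@dataclass(frozen=True)
class BorderedProblem:
    """One input-output pair for the vertex test.

    ``input_spec``: ``("eq", j)`` for a persistent additive input on the
    dynamic equation of x_j (1-based), or ``"u1"`` / ``"u2"`` for the
    channel patterns -e1+e2 / +e1-e2.

    ``output_spec``: ``("var", i)`` for the i-th state variable, or
    ``"flow"`` for the circular-flow output, whose linearized row is
    assembled from the template's own direction parameters.
    """

    template: JacobianTemplate
    input_spec: InputSpec
    output_spec: InputSpec

    def e_terms(self) -> list[tuple[int, int]]:
        """E as a sparse list of (row, coefficient), 0-based."""
        if self.input_spec == "u1":
            return [(0, -1), (1, 1)]
        if self.input_spec == "u2":
            return [(0, 1), (1, -1)]
        kind, j = self.input_spec
        if kind != "eq" or not 1 <= j <= self.template.n:
            raise ValueError(f"bad input spec {self.input_spec!r}")
        return [(j - 1, 1)]

    def h_terms(self) -> list[tuple[int, int | None]]:
        """H as a sparse list of (column, direction index or None).

        ``None`` stands for a unit coefficient; an integer k means the
        coefficient is the k-th direction parameter d_k (flow outputs).
        """
        if self.output_spec == "flow":
            terms: list[tuple[int, int | None]] = []
            for f, dir_idx in _flow_output_flows(self.template):
                for k in dir_idx:
                    terms.append((self.template.directions[k].column, k))
            return terms
        kind, i = self.output_spec
        if kind != "var" or not 1 <= i <= self.template.n:
            raise ValueError(f"bad output spec {self.output_spec!r}")
        return [(i - 1, None)]


def _flow_output_flows(template: JacobianTemplate) -> list[tuple[FlowSpec, tuple[int, ...]]]:
    """Flows of the minimal conversion loop through TGN-bound CERT (x7).

    The circular-flow output is the sum of the fluxes on the arcs of the
    shortest directed cycle containing species 7; its linearization row is
    exactly the sum of those flows' direction parameters, each placed in
    its own Jacobian column.
    """
    conv = [f for f in template.structure.flows
            if f.kind in ("spontaneous_conversion", "tuned_conversion")
            and not any(isinstance(t, str) for t in f.tuners)]
    target = 7
    adj: dict[int, list[FlowSpec]] = {}
    for f in conv:
        adj.setdefault(f.source, []).append(f)
    # BFS over arcs for the shortest cycle through `target`
    best: list[FlowSpec] | None = None
    frontier: list[tuple[int, list[FlowSpec]]] = [(target, [])]
    seen = {target}
    while frontier and best is None:
        nxt: list[tuple[int, list[FlowSpec]]] = []
        for node, path in frontier:
            for f in adj.get(node, []):
                if f.target == target:
                    best = path + [f]
                    break
                if f.target not in seen:
                    seen.add(f.target)
                    nxt.append((f.target, path + [f]))
            if best is not None:
                break
        frontier = nxt
    if best is None:
        raise ValueError("structure has no conversion loop through x7; "
                         "no flow output is defined")
    out = []
    for f in best:
        idx = template.flow_directions.get(f)
        if idx is None:
            # spontaneous flow: its direction is the rate constant itself
            idx = tuple(k for k, p in enumerate(template.directions)
                        if p.column == f.source - 1 and p.name == f.rate_symbol)
        out.append((f, idx))
    return out


def multiaffinity_check(problem: BorderedProblem,
                        seed: int = 0, tol: float = 1e-8) -> tuple[bool, str]:
    """Audit that the bordered determinant is multi-affine in the directions.

    Structurally: every parameter must be confined to one column of the
    bordered matrix (flow-output H coefficients sit in the same column as
    their Jacobian occurrences, so unit and flow borders both pass).  A
    randomized line test additionally verifies that the determinant is
    affine along each parameter axis.
    """
    offender = _check_single_column(problem.template.directions)
    if offender is not None:
        return False, f"parameter {offender!r} occurs in multiple Jacobian columns"
    for col, k in problem.h_terms():
        if k is not None and problem.template.directions[k].column != col:
            return False, (f"output coefficient of direction "
                           f"{problem.template.directions[k].name!r} sits in column "
                           f"{col}, outside its Jacobian column")
    rng = np.random.default_rng(seed)
    q = problem.template.q
    d0 = rng.uniform(0.2, 2.0, size=q)
    for k in rng.choice(q, size=min(q, 6), replace=False):
        vals = []
        for t in (0.0, 1.0, 2.0):
            d = d0.copy()
            d[k] = t
            vals.append(_bordered_det_numeric(problem, d))
        curvature = vals[2] - 2 * vals[1] + vals[0]
        scale = max(1.0, max(abs(v) for v in vals))
        if abs(curvature) > tol * scale:
            return False, (f"determinant not affine along direction "
                           f"{problem.template.directions[k].name!r}")
    return True, "multi-affine"


def _bordered_det_numeric(problem: BorderedProblem, d: np.ndarray) -> float:
    """det [[-J(d), -E], [H(d), 0]] for one numeric direction assignment."""
    t = problem.template
    n = t.n
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = -t.assemble(d)
    for row, coef in problem.e_terms():
        A[row, n] = -coef
    for col, k in problem.h_terms():
        A[n, col] += 1.0 if k is None else d[k]
    return float(np.linalg.det(A))


# ---------------------------------------------------------------------------
# exact integer determinants
# ---------------------------------------------------------------------------

def _exact_int_det(M: np.ndarray) -> int:
    """Fraction-free Bareiss elimination on Python integers."""
    a = [[int(round(v)) for v in row] for row in M]
    n = len(a)
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            swap = next((r for r in range(k + 1, n) if a[r][k] != 0), None)
            if swap is None:
                return 0
            a[k], a[swap] = a[swap], a[k]
            sign = -sign
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
            a[i][k] = 0
        prev = a[k][k]
    return sign * a[n - 1][n - 1]


def _batched_int_det(A: np.ndarray) -> np.ndarray:
    """Exact integer determinants of a batch of small integer matrices."""
    d = np.linalg.det(A)
    r = np.rint(d)
    bad = np.abs(d - r) > 1e-2
    if bad.any():
        for idx in np.nonzero(bad)[0]:
            r[idx] = float(_exact_int_det(A[idx]))
    return r


# ---------------------------------------------------------------------------
# vertex enumeration engine
# ---------------------------------------------------------------------------

def _vertex_chunks(q: int, chunk: int = _DEFAULT_CHUNK):
    """Yield {0,1}^q vertex blocks as float arrays of shape (B, q)."""
    total = 1 << q
    bits = np.arange(q)
    for start in range(0, total, chunk):
        v = np.arange(start, min(start + chunk, total), dtype=np.int64)
        yield ((v[:, None] >> bits) & 1).astype(np.float64)


def _minor_dets(A: np.ndarray, i: int, j: int) -> np.ndarray:
    """Signed minors adj(A)[i, j] = (-1)^(i+j) det(A del row j del col i)."""
    n = A.shape[-1]
    rows = np.delete(np.arange(n), j)
    cols = np.delete(np.arange(n), i)
    d = _batched_int_det(A[:, rows][:, :, cols])
    return d if (i + j) % 2 == 0 else -d


class _SignAccumulator:
    __slots__ = ("pos", "neg")

    def __init__(self) -> None:
        self.pos = False
        self.neg = False

    def update(self, values: np.ndarray) -> None:
        if not self.pos:
            self.pos = bool((values > 0).any())
        if not self.neg:
            self.neg = bool((values < 0).any())

    def sign(self) -> str:
        if self.pos and self.neg:
            return "?"
        if self.pos:
            return "+"
        if self.neg:
            return "-"
        return "0"


def vertex_sign(problem: BorderedProblem, chunk: int = _DEFAULT_CHUNK,
                check: bool = True) -> str:
    """Structural sign of one steady-state input-output influence.

    Evaluates the bordered determinant at every vertex of {0,1}^q (q merged
    directions) with integer-exact arithmetic and classifies the observed
    sign range.  If det(-J) takes a negative value somewhere on the vertex
    set, a :class:`GateWarning` is attached (the hypercube overapproximates
    the directions realizable at a stable equilibrium).
    """
    if check:
        ok, diag = multiaffinity_check(problem)
        if not ok:
            raise ValueError(f"vertex test inapplicable ({diag}); "
                             "use sampling_oracle instead")
    t = problem.template
    Ms = t.direction_matrices().astype(np.float64)
    e_terms = problem.e_terms()
    h_terms = problem.h_terms()
    needed = sorted({(col, row) for col, _ in h_terms for row, _ in e_terms})
    acc = _SignAccumulator()
    gate = _SignAccumulator()
    for D in _vertex_chunks(t.q, chunk):
        A = -np.tensordot(D, Ms, axes=(1, 0))
        adj = {key: _minor_dets(A, key[0], key[1]) for key in needed}
        det = np.zeros(D.shape[0])
        for col, k in h_terms:
            h = 1.0 if k is None else D[:, k]
            for row, coef in e_terms:
                det += h * coef * adj[(col, row)]
        acc.update(det)
        gate.update(_batched_int_det(A))
    if gate.neg:
        warnings.warn("det(-J) takes negative values on the vertex set; "
                      "sign computed from the bordered determinant alone",
                      GateWarning, stacklevel=2)
    return acc.sign()


# ---------------------------------------------------------------------------
# full structural summary (batched over all input-output pairs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuralSummary:
    """All structural signs of one model from a single vertex sweep."""

    variant: str
    n_directions: int
    grid: tuple[tuple[str, ...], ...]          # rows = outputs x1..x7
    u1: tuple[str, ...]                        # per-output channel signs
    u2: tuple[str, ...]
    flow: tuple[str, ...]                      # (u1, u2, eq1..eq7)
    gate_ok: bool                              # det(-J) >= 0 at all vertices


_SUMMARY_CACHE: dict[tuple, StructuralSummary] = {}


def structural_summary(model: ModelStructure, chunk: int = _DEFAULT_CHUNK
                       ) -> StructuralSummary:
    """Compute every influence sign of a model in one batched vertex sweep.

    Per vertex the full 7x7 adjugate of -J is assembled once; the 49
    variable-to-variable entries, the two channel vectors and the nine
    flow-output entries are all linear combinations of its entries, so one
    sweep covers them (the channel pattern of u2 is the negation of u1, and
    the flow row is built from the template's own direction parameters).
    """
    template = jacobian_template(model)
    key = template._key()
    if key in _SUMMARY_CACHE:
        return _SUMMARY_CACHE[key]
    n = template.n
    Ms = template.direction_matrices().astype(np.float64)
    try:
        flow_h = BorderedProblem(template, ("eq", 1), "flow").h_terms()
    except ValueError:  # structure without a conversion loop through x7
        flow_h = None
    grid_acc = [[_SignAccumulator() for _ in range(n)] for _ in range(n)]
    u1_acc = [_SignAccumulator() for _ in range(n)]
    flow_acc = [_SignAccumulator() for _ in range(1 + n)]  # u1, eq1..eqn
    gate = _SignAccumulator()
    for D in _vertex_chunks(template.q, chunk):
        A = -np.tensordot(D, Ms, axes=(1, 0))
        B = D.shape[0]
        adj = np.empty((B, n, n))
        for i in range(n):
            for j in range(n):
                adj[:, i, j] = _minor_dets(A, i, j)
        gate.update(_batched_int_det(A))
        for i in range(n):
            for j in range(n):
                grid_acc[i][j].update(adj[:, i, j])
        ch = -adj[:, :, 0] + adj[:, :, 1]      # u1 pattern -e1+e2
        for i in range(n):
            u1_acc[i].update(ch[:, i])
        if flow_h is not None:
            H = np.zeros((B, n))
            for col, k in flow_h:
                H[:, col] += D[:, k]
            flow_acc[0].update(np.einsum("bi,bi->b", H, ch))
            for j in range(n):
                flow_acc[1 + j].update(np.einsum("bi,bi->b", H, adj[:, :, j]))
    flip = {"+": "-", "-": "+", "0": "0", "?": "?"}
    u1 = tuple(a.sign() for a in u1_acc)
    flow_u1 = flow_acc[0].sign()
    summary = StructuralSummary(
        variant=model.variant,
        n_directions=template.q,
        grid=tuple(tuple(grid_acc[i][j].sign() for j in range(n)) for i in range(n)),
        u1=u1,
        u2=tuple(flip[s] for s in u1),
        flow=((flow_u1, flip[flow_u1]) + tuple(flow_acc[1 + j].sign() for j in range(n))
              if flow_h is not None else ()),
        gate_ok=not gate.neg,
    )
    _SUMMARY_CACHE[key] = summary
    return summary


# ---------------------------------------------------------------------------
# public result objects
# ---------------------------------------------------------------------------

_ORIENTATION = "rows=outputs;columns=perturbed_equation"


@dataclass(frozen=True)
class InfluenceMatrix:
    """7x7 grid of structural signs; entry (i, j) is the influence on
    variable x_i of a persistent additive input on the equation of x_j."""

    variant: str
    grid: tuple[tuple[str, ...], ...]
    orientation: str = _ORIENTATION
    gate_ok: bool = True

    def __getitem__(self, ij: tuple[int, int]) -> str:
        i, j = ij
        return self.grid[i - 1][j - 1]

    def row(self, i: int) -> tuple[str, ...]:
        return self.grid[i - 1]

    def to_csv(self) -> str:
        header = "output," + ",".join(f"eq_x{j}" for j in range(1, len(self.grid) + 1))
        lines = [header]
        for i, row in enumerate(self.grid, start=1):
            lines.append(f"x{i}," + ",".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self, indent: int | None = 2) -> str:
        import json
        return json.dumps({"variant": self.variant, "orientation": self.orientation,
                           "gate_ok": self.gate_ok,
                           "grid": [list(r) for r in self.grid]}, indent=indent)


def influence_matrix(model: ModelStructure) -> InfluenceMatrix:
    """The structural influence matrix of one model (49 vertex tests)."""
    s = structural_summary(model)
    if not s.gate_ok:
        warnings.warn("det(-J) takes negative values on the vertex set; "
                      "signs computed from the bordered determinant alone",
                      GateWarning, stacklevel=2)
    return InfluenceMatrix(variant=s.variant, grid=s.grid, gate_ok=s.gate_ok)


def channel_influence(model: ModelStructure, channel: str) -> tuple[str, ...]:
    """Per-variable structural signs of a persistent step through u1 or u2."""
    if channel not in ("u1", "u2"):
        raise ValueError("channel must be 'u1' or 'u2'")
    s = structural_summary(model)
    return s.u1 if channel == "u1" else s.u2


def flow_influence(model: ModelStructure, output: str,
                   input_spec: InputSpec) -> str:
    """Structural sign of one influence on a transfer output.

    ``output``: "PHI_SDS" (SDS only), "PHI_NS" or "X7" (NS only).
    ``input_spec``: "u1", "u2" or ("eq", j).
    """
    valid = {"SDS": {"PHI_SDS"}, "NS": {"PHI_NS", "X7"}}
    if output not in valid.get(model.variant, set()):
        raise ValueError(f"output {output!r} incompatible with variant {model.variant}")
    s = structural_summary(model)
    if output == "X7":
        if input_spec == "u1":
            return s.u1[6]
        if input_spec == "u2":
            return s.u2[6]
        return s.grid[6][input_spec[1] - 1]
    if input_spec == "u1":
        return s.flow[0]
    if input_spec == "u2":
        return s.flow[1]
    return s.flow[1 + input_spec[1]]


# ---------------------------------------------------------------------------
# consistency (model-to-model or model-to-experiment comparison)
# ---------------------------------------------------------------------------

_STRONG_PAIRS = {("+", "+"), ("-", "-"), ("0", "0")}


def _entry_class(a: str, b: str) -> str:
    if (a, b) in _STRONG_PAIRS:
        return "strong"
    if a == "?" or b == "?":
        return "weak"
    return "inconsistent"


@dataclass(frozen=True)
class ConsistencyReport:
    """Entrywise and aggregate consistency of two sign objects.

    Two determinate entries agree -> strong; any '?' involved -> weak
    (no contradiction, but a restriction of the parameter space could
    create one); determinate disagreement -> inconsistent.
    """

    classes: tuple[tuple[str, ...], ...]
    counts: Mapping[str, int]
    aggregate: str

    def to_json(self, indent: int | None = 2) -> str:
        import json
        return json.dumps({"classes": [list(r) for r in self.classes],
                           "counts": dict(self.counts),
                           "aggregate": self.aggregate}, indent=indent)


def compare(a, b) -> ConsistencyReport:
    """Classify two equally-shaped sign grids (or vectors) entrywise."""
    ga = _as_grid(a)
    gb = _as_grid(b)
    if isinstance(a, InfluenceMatrix) and isinstance(b, InfluenceMatrix):
        if a.orientation != b.orientation:
            raise ValueError("orientation mismatch between influence matrices")
    if len(ga) != len(gb) or any(len(ra) != len(rb) for ra, rb in zip(ga, gb)):
        raise ValueError("shape mismatch between compared sign objects")
    classes = tuple(tuple(_entry_class(x, y) for x, y in zip(ra, rb))
                    for ra, rb in zip(ga, gb))
    counts = {"strong": 0, "weak": 0, "inconsistent": 0}
    for row in classes:
        for c in row:
            counts[c] += 1
    if counts["inconsistent"]:
        aggregate = "inconsistent"
    elif counts["weak"]:
        aggregate = "weakly consistent"
    else:
        aggregate = "strongly consistent"
    return ConsistencyReport(classes=classes, counts=counts, aggregate=aggregate)


def _as_grid(x) -> tuple[tuple[str, ...], ...]:
    if isinstance(x, InfluenceMatrix):
        return x.grid
    seq = list(x)
    if seq and isinstance(seq[0], str):
        return (tuple(seq),)
    return tuple(tuple(r) for r in seq)


# ---------------------------------------------------------------------------
# sampling oracle (independent numeric cross-check)
# ---------------------------------------------------------------------------

def sampling_oracle(problem: BorderedProblem, n_draws: int = 1000,
                    seed: int = 0, param_range: tuple[float, float] = (1e-3, 1e3)
                    ) -> set[str]:
    """Observed strict signs of the bordered determinant under random draws.

    Direction parameters are drawn log-uniformly from ``param_range``; the
    determinant is evaluated numerically and classified with a scale-aware
    tolerance.  A determinate vertex result is *sound* if the sampled sign
    set never contains the opposite strict sign.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    lo, hi = param_range
    if not (0 < lo < hi):
        raise ValueError("param_range must be a positive interval")
    t = problem.template
    rng = np.random.default_rng(seed)
    d = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_draws, t.q)))
    Ms = t.direction_matrices().astype(np.float64)
    A = -np.tensordot(d, Ms, axes=(1, 0))
    e_terms = problem.e_terms()
    h_terms = problem.h_terms()
    n = t.n
    det = np.zeros(n_draws)
    for col, k in h_terms:
        h = 1.0 if k is None else d[:, k]
        for row, coef in e_terms:
            rows = np.delete(np.arange(n), row)
            cols = np.delete(np.arange(n), col)
            minors = np.linalg.det(A[:, rows][:, :, cols])
            if (col + row) % 2 == 1:
                minors = -minors
            det += h * coef * minors
    scale = max(1.0, float(np.abs(det).max()))
    tol = 1e-12 * scale
    observed: set[str] = set()
    if (det > tol).any():
        observed.add("+")
    if (det < -tol).any():
        observed.add("-")
    if (np.abs(det) <= tol).any():
        observed.add("0")
    return observed


def indeterminacy_witness(problem: BorderedProblem, seed: int = 0,
                          n_local: int = 32, chunk: int = _DEFAULT_CHUNK) -> dict:
    """Witness both strict signs of a '?' influence by local sampling.

    Global log-uniform draws can miss one sign region entirely, so the
    witness first locates two hypercube vertices where the bordered
    determinant has opposite signs, then samples strictly positive
    parameter vectors in their neighbourhoods (active coordinates jittered
    around 1, inactive coordinates pushed to small positive values).
    Returns the two observed signs and one witnessing parameter vector per
    sign; raises if the problem is not actually indeterminate.
    """
    t = problem.template
    Ms = t.direction_matrices().astype(np.float64)
    e_terms = problem.e_terms()
    h_terms = problem.h_terms()
    needed = sorted({(col, row) for col, _ in h_terms for row, _ in e_terms})
    vertex_at: dict[str, np.ndarray] = {}
    for D in _vertex_chunks(t.q, chunk):
        A = -np.tensordot(D, Ms, axes=(1, 0))
        adj = {key: _minor_dets(A, key[0], key[1]) for key in needed}
        det = np.zeros(D.shape[0])
        for col, k in h_terms:
            h = 1.0 if k is None else D[:, k]
            for row, coef in e_terms:
                det += h * coef * adj[(col, row)]
        if "+" not in vertex_at and (det > 0).any():
            vertex_at["+"] = D[int(np.argmax(det > 0))]
        if "-" not in vertex_at and (det < 0).any():
            vertex_at["-"] = D[int(np.argmax(det < 0))]
        if len(vertex_at) == 2:
            break
    if len(vertex_at) < 2:
        raise ValueError("problem is not indeterminate: only one strict sign "
                         "occurs on the vertex set")
    rng = np.random.default_rng(seed)
    witnesses: dict[str, np.ndarray] = {}
    for sgn, vertex in vertex_at.items():
        for _ in range(n_local):
            d = np.where(vertex > 0.5,
                         np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=t.q)),
                         np.exp(rng.uniform(np.log(1e-6), np.log(1e-4), size=t.q)))
            val = _bordered_det_numeric(problem, d)
            if (val > 0 and sgn == "+") or (val < 0 and sgn == "-"):
                witnesses[sgn] = d
                break
        else:
            raise RuntimeError(f"could not witness sign {sgn} near its vertex")
    return {"signs": set(witnesses), "witnesses": witnesses}


# ---------------------------------------------------------------------------
# block-structure checks (monotone subsystems, coupling confinement)
# ---------------------------------------------------------------------------

def block_structure_checks(template: JacobianTemplate, n_samples: int = 100,
                           seed: int = 0) -> dict:
    """Verify the interconnection-of-monotone-subsystems pattern.

    For random positive direction assignments the assembled Jacobian must
    have Metzler diagonal blocks that are column diagonally dominant with
    negative diagonal, and every off-block (coupling) entry confined to the
    positions induced by the declared flow-inducing tuners.
    """
    structure = template.structure
    idx_of = {s.index: k for k, s in enumerate(structure.species)}
    blocks: dict[str, list[int]] = {}
    for s in structure.species:
        blocks.setdefault(s.module_id, []).append(idx_of[s.index])
    allowed = np.zeros((template.n, template.n), dtype=bool)
    module_of_col: dict[int, str] = {}
    for s in structure.species:
        module_of_col[idx_of[s.index]] = s.module_id
    # legitimate coupling positions come from the declared tuned conversions
    # of the structure itself, not from the (possibly corrupted) directions:
    # a tuner x_k of a conversion s -> t may touch rows s, t in column k only
    for f in structure.flows:
        if f.kind != "tuned_conversion":
            continue
        for tuner in f.tuners:
            if isinstance(tuner, int):
                allowed[idx_of[f.source], idx_of[tuner]] = True
                allowed[idx_of[f.target], idx_of[tuner]] = True
    rng = np.random.default_rng(seed)
    violations: list[str] = []
    for it in range(n_samples):
        d = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), size=template.q))
        J = template.assemble(d)
        for module, rows in blocks.items():
            Jb = J[np.ix_(rows, rows)]
            off = Jb - np.diag(np.diag(Jb))
            if (off < 0).any():
                violations.append(f"draw {it}: block {module} not Metzler")
            if (np.diag(Jb) >= 0).any():
                violations.append(f"draw {it}: block {module} has non-negative diagonal")
            colsum = np.abs(off).sum(axis=0)
            if (np.abs(np.diag(Jb)) + 1e-12 < colsum).any():
                violations.append(f"draw {it}: block {module} not column diagonally dominant")
        outside = np.zeros_like(allowed)
        for module, rows in blocks.items():
            for r in rows:
                for c in rows:
                    outside[r, c] = True  # inside blocks: anything goes
        coupling_bad = (J != 0) & ~outside & ~allowed
        if coupling_bad.any():
            r, c = np.argwhere(coupling_bad)[0]
            violations.append(f"draw {it}: coupling entry at ({r + 1},{c + 1}) "
                              "outside the declared tuner positions")
    return {"n_samples": n_samples, "passed": not violations, "violations": violations}
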