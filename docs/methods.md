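# Methods

## Models

Both variants describe the PKD–PI4KIIIβ–CERT interplay at the ER–TGN
membrane contact sites with seven concentrations (molecules/cell, time in
minutes), organised in three modules: PKD {x1 inactive, x2 active},
PI4KIIIβ {x3 inactive, x4 active}, CERT {x5, x6, x7}. External inflows s1,
s3, s5 feed x1, x3, x5; every species self-degrades; all other flows are
conversions *within* a module whose rates may be tuned by species of other
modules (flow-inducing coupling) or by the two input channels.

Shared flows: u1-tuned activation x1→x2 at rate f1(u1), u2-tuned
deactivation x2→x1 at f2(u2), x2-tuned activation x3→x4 at g1(x2) with
spontaneous return x4→x3 (κ), and x2-tuned detachment x7→x6 at g2(x2) with
spontaneous dephosphorylation x6→x5 (λ).

Short distance shuttle (SDS): PI4P produced by active PI4KIIIβ recruits
ER-bound CERT to the TGN, x5→x7 at rate g4(x4); the transfer-generated DAG
feedback activates PKD through the composed rate h(x4, x5) on x1→x2. The
CERT subsystem is a directed cycle x5→x7→x6→x5.

Neck swinging (NS): the PI4P effect converts phosphorylated CERT into the
double-bound state, x6→x7 at g4(x4); x5 and x6 interconvert spontaneously
(ν, λ); the PKD feedback is tuned by double-bound CERT alone, g7(x7) on
x1→x2. The CERT subsystem is a cascaded double switch.

Rate-function families (registry-extensible): affine activation
f(z) = a(1+bz) with f(0) > 0; saturating g(z) = az/(z+b); composed
h(z,y) = g_j[y·g_i(z)]. All are non-negative, differentiable and strictly
increasing in each argument on the positive orthant — the only assumption
the structural results need. The published parameterization maps the
generic symbols to Michaelis–Menten constants; the printed equations carry
a single input channel (the activation multiplier 1+u), and the second
channel is implemented symmetrically as f2(u2) = p13(1+u2) so that u2 = 0
reproduces the printed system exactly. The printed NS parameter list also
contains two constants (a13, a14) that appear in no printed equation; they
are not part of the parameter set here.

Positivity and boundedness: each module-sum derivative equals the module
inflow minus its degradation terms (conversions cancel), so trajectories
stay in the simplex x1+x2 ≤ k1, x3+x4 ≤ k2, x5+x6+x7 ≤ k3 with
k = inflow / min(module degradation rates), enlarged to the initial module
sum when the start lies outside. `boundedness_box` returns these bounds and
the test suite asserts them along every produced trajectory (relative
slack 1e-6 for integrator error).

## Structural influence algorithm

The Jacobian of either model is assembled as J = Σ dᵢ Mᵢ from one positive
direction parameter per flow linearization: a degradation contributes −eᵢ
in its own column; a spontaneous conversion s→t contributes (e_t−e_s) in
column s; a tuned conversion contributes its equilibrium rate value in
column s plus, per species tuner k, the equilibrium source concentration
times the rate derivative in column k. Directions with identical rank-one
matrices are merged (in both variants the feedback-activation value and
f1(ū1) share (e2−e1)e1ᵀ), leaving q = 19 independent directions from 20 raw
parameters.

For an input E (unit equation vector, or the channel patterns −e1+e2 for
u1 and +e1−e2 for u2 — the positive scalar x̄1 f1′ or x̄2 f2′ multiplying
the pattern cannot change the determinant sign) and an output row H (unit
variable row, or the linearized circular-flow row assembled from the loop
flows' own direction parameters), the bordered determinant
det [[−J(d), −E], [H(d), 0]] is multi-affine in d: every parameter is
confined to a single column of the bordered matrix, including the
flow-output coefficients, which sit in the same columns as their Jacobian
occurrences. `multiaffinity_check` audits this structurally and with a
randomized affine-line test before any vertex run.

The sign is classified by evaluating the determinant at all 2^q vertices of
{0,1}^q: all ≥ 0 with one > 0 → `+`; all ≤ 0 with one < 0 → `-`; all zero →
`0`; both strict signs → `?`. Zero vertices are closures of the positive
orthant, and a multi-affine function attains its sign extremes at vertices,
so the classification is exact for the open orthant.

Numerical choices:

* Vertex determinants are integers. They are computed with batched LAPACK
  determinants and rounded; any value whose rounding margin exceeds 1e-2 is
  recomputed with fraction-free Bareiss elimination on Python integers
  (entries are in {−4,…,4}, so the float path is in practice always
  exact, and the fallback makes the guarantee unconditional).
* The full 7×7 adjugate of −J(d) is assembled per vertex in chunks of
  65 536, which yields all 49 unit input–output pairs, both channel vectors
  and the flow row in a single sweep per model (≈15 s on one CPU).
* det(−J(d)) is monitored over the same vertices. The influence-sign
  formula presumes a stable equilibrium, where det(−J) > 0; the hypercube
  of independent directions overapproximates the directions realizable at
  an equilibrium, and det(−J) does reach −1 at some vertices of both
  models. The signs are therefore computed from the bordered determinant
  alone and a `GateWarning` is attached rather than refusing — the choice
  is validated by the sampling oracle and the simulations, which never
  contradict a determinate sign.
* The sampling oracle draws directions log-uniformly from [1e-3, 1e3]
  (default 1000 seeded draws) and classifies strict signs with a
  scale-aware tolerance (1e-12 of the batch maximum). For `?` entries,
  global draws may see only one sign region, so the witness routine locates
  two vertices of opposite determinant sign and samples strictly positive
  neighbourhoods (active coordinates jittered in [0.5, 2], inactive ones in
  [1e-6, 1e-4]).

Consistency between two sign objects follows the strong / weak /
inconsistent trichotomy: equal determinate signs are strong, any `?` is
weak (no contradiction, but parameter-space restrictions could create
one), determinate disagreement is inconsistent; the aggregate verdict is
strong only if every entry is strong, weak if none is inconsistent.

Serialized matrices always carry the orientation tag
`rows=outputs;columns=perturbed_equation`. The per-variable prose summaries
in the source literature do not align entry-for-entry with this orientation
in every place, so the package reports exactly what it computes under the
declared orientation; the headline counts (18/49 strongly consistent
entries, first four u1 entries strong) and the x7-row results hold under
it.

## Simulations

The published parameterizations are stiff (degradation rates span
2.3e-4 … 9.3 per minute), so trajectories use LSODA with relative tolerance
1e-8 and componentwise absolute tolerances scaled by the invariant-box
bounds. Steady states integrate over ten times the slowest degradation
time constant and are polished with a Newton (hybr) root solve to residual
norm ≤ 1e-9·(1+‖x‖), i.e. ~1e-12 relative state accuracy.

Perturbation experiments follow the published protocol: settle to steady
state, apply a persistent step (u1: 0 → 1e5 at t = 50 min for SDS, t = 750
min for NS, from the published initial conditions), settle again, and sign
the per-variable and flow-output changes. Equation-targeted steps are
additive constants on one state equation, defaulting to 1 % of the species'
inflow where one exists and 1e3 molecules/cell/min otherwise.

Sign-extraction threshold: a relative steady-state change
|Δx|/max(x_pre, 1e-12) above 1e-9 is signed, below counts as `0`. The
threshold exists so numerical error cannot masquerade as influence; with
Newton-polished equilibria the noise floor is ~1e-12 relative, and 1e-9
keeps three orders of safety margin while still resolving strongly
attenuated cross-module responses, which genuinely reach ~4e-9 relative at
the default input magnitudes (e.g. the x3 response to a 1 % inflow step on
the x5 equation of the shuttle model). A blanket threshold at 1e-6 would
censor such real responses and falsely contradict their structural signs.

Problem sizes used by the test suite and the acceptance script: full 2^19
vertex sweeps for both models; 1000 oracle draws per input–output problem;
50 random parameterizations (log-uniform in [1e-3, 1e3], initial conditions
uniform in [0, 1e6]) integrated over 1000 min for the invariance checks;
channel-step robustness verified at magnitudes {1e4, 1e5, 1e6}.

## Synthetic fixtures

The samplers emulate exactly what the analysis assumes and nothing more:
positive parameters drawn log-uniformly across six orders of magnitude
(the structural claims must hold across scales), rate functions drawn from
the analytically monotone families and audited on a numeric grid
(non-negativity, strict monotonicity per argument, strict positivity of
the activation rates at zero — violations abort fixture generation), and
non-negative initial conditions in a box. No measurement noise or
fluorescence-trace model is emulated, because the analysis is
parameter-free and consumes no experimental data: passing tests certify
the structural machinery and the model implementations, not agreement with
any particular dataset.

Two pedagogical networks serve as independent oracles: the minimal
flow-inducing network (a conserved two-species module whose A→B flow is
tuned by an external species) and the two-species conversion module with
explicit equilibrium b̄ = u/d3, whose analytic steady-state derivative sign
the vertex algorithm must reproduce.

## Design choices and limitations

* The vertex domain is {0,1}^q after merging identically-structured
  directions; this is the tightest hypercube for which multi-affinity
  guarantees vertex extremality of signs.
* The symbol ν is used in the source models both for the spontaneous NS
  x5→x6 rate and (in the SDS Jacobian) for an equilibrium derivative
  quantity; here the former lives in the model structure (`nu`), the
  latter is the systematically named direction `x1*dh/dx4`.
* `0` entries (perfect adaptation) never occur in these two models; the
  code path is nevertheless exercised by constructed examples.
* The analysis certifies local steady-state response signs at a stable
  equilibrium; it proves neither global stability nor uniqueness (the
  simulations observe a unique attractor numerically, nothing more).
* Reproduction of the published step experiments is qualitative (signs,
  pulse shape) by necessity: no numeric steady-state values are printed
  for them. The NS pulse criterion (transient flow maximum exceeding both
  flanking steady values) is asserted numerically.
* Out of scope: parameter estimation, OSBP/PI4P-extended models, spatial
  (PDE) variants, SBML import/export, and formal monotone-systems
  stability certificates beyond the implemented block checks (Metzler
  diagonal blocks, columnwise diagonal dominance, negative diagonals,
  coupling confinement).
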