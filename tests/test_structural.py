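"""Jacobian templates, BDC decomposition and the vertex sign test."""

import warnings

import numpy as np
import pytest

import certflux as cf
from certflux.structural import _bordered_det_numeric, _exact_int_det

# sign patterns of the two Jacobians, derived entry by entry from the model
# equations (rows = equations, columns = differentiation variables)
SDS_SIGN_PATTERN = [
    [-1, +1, 0, -1, -1, 0, 0],
    [+1, -1, 0, +1, +1, 0, 0],
    [0, -1, -1, +1, 0, 0, 0],
    [0, +1, +1, -1, 0, 0, 0],
    [0, 0, 0, -1, -1, +1, 0],
    [0, +1, 0, 0, 0, -1, +1],
    [0, -1, 0, +1, +1, 0, -1],
]
NS_SIGN_PATTERN = [
    [-1, +1, 0, 0, 0, 0, -1],
    [+1, -1, 0, 0, 0, 0, +1],
    [0, -1, -1, +1, 0, 0, 0],
    [0, +1, +1, -1, 0, 0, 0],
    [0, 0, 0, 0, -1, +1, 0],
    [0, +1, 0, -1, +1, -1, +1],
    [0, -1, 0, +1, 0, +1, -1],
]

MODULE_BLOCKS = [(0, 2), (2, 4), (4, 7)]


def _corrupted_template(template):
    """Move one copy of a parameter into a second column (breaks
    multi-affinity: the same scalar now multiplies two columns)."""
    first = template.directions[0]
    clone = cf.DirectionParameter(name=first.name.split("+")[0],
                                  column=(first.column + 2) % template.n,
                                  incidence=first.incidence)
    return cf.JacobianTemplate(structure=template.structure,
                               directions=template.directions + (clone,),
                               flow_directions=template.flow_directions)


class TestTemplate:
    @pytest.mark.parametrize("variant,pattern", [
        (cf.SDS, SDS_SIGN_PATTERN), (cf.NS, NS_SIGN_PATTERN)])
    def test_sign_pattern(self, variant, pattern):
        template = cf.jacobian_template(cf.build_model(variant))
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = np.exp(rng.uniform(np.log(1e-3), np.log(1e3), size=template.q))
            J = template.assemble(d)
            np.testing.assert_array_equal(np.sign(J), np.array(pattern, dtype=float))

    def test_sds_merges_activation_rates(self, sds_model):
        """The equilibrium feedback-activation rate h(x̄4, x̄5) and the
        channel rate f1(ū1) share the rank-one matrix (e2-e1)e1ᵀ and merge,
        leaving 19 independent directions."""
        template = cf.jacobian_template(sds_model)
        assert template.q == 19
        (merged,) = [p for p in template.directions if "+" in p.name]
        assert {"f1(u1)", "h(x4,x5)"} == set(merged.name.split("+"))
        assert merged.column == 0
        assert merged.incidence == (-1, 1, 0, 0, 0, 0, 0)

    def test_ns_feedback_derivative_direction(self, ns_model):
        """x̄1 ∂g7/∂x7 sits in column 7, negative in row 1, positive in row 2."""
        template = cf.jacobian_template(ns_model)
        assert template.q == 19
        (mu,) = [p for p in template.directions if p.name == "x1*dg7/dx7"]
        assert mu.column == 6
        assert mu.incidence == (-1, 1, 0, 0, 0, 0, 0)

    @pytest.mark.parametrize("variant", [cf.SDS, cf.NS])
    def test_diagonal_blocks_metzler_dominant(self, variant):
        template = cf.jacobian_template(cf.build_model(variant))
        rng = np.random.default_rng(11)
        for _ in range(10):
            J = template.assemble(np.exp(rng.uniform(-3, 3, size=template.q)))
            for lo, hi in MODULE_BLOCKS:
                B = J[lo:hi, lo:hi]
                off = B - np.diag(np.diag(B))
                assert (off >= 0).all()                      # Metzler
                assert (np.diag(B) < 0).all()                # negative diagonal
                assert (np.abs(np.diag(B)) >= off.sum(axis=0) - 1e-12).all()


class TestBDC:
    @pytest.mark.parametrize("variant", [cf.SDS, cf.NS])
    def test_rank_one_and_reassembly(self, variant):
        template = cf.jacobian_template(cf.build_model(variant))
        pairs = cf.bdc_decompose(template)
        assert len(pairs) == template.q
        rng = np.random.default_rng(5)
        d = np.exp(rng.uniform(-2, 2, size=template.q))
        J = sum(di * M for (_, M), di in zip(pairs, d))
        np.testing.assert_allclose(J, template.assemble(d))
        for p, M in pairs:
            assert np.linalg.matrix_rank(M) == 1
            assert set(np.nonzero(M)[1]) == {p.column}

    def test_multi_column_parameter_rejected(self, sds_model):
        broken = _corrupted_template(cf.jacobian_template(sds_model))
        with pytest.raises(ValueError, match="multiple columns"):
            cf.bdc_decompose(broken)


class TestMultiAffinity:
    def test_unit_border_problems_pass(self, ns_model):
        template = cf.jacobian_template(ns_model)
        for spec in [("eq", 3), "u1", "u2"]:
            ok, diag = cf.multiaffinity_check(
                cf.BorderedProblem(template, spec, ("var", 5)))
            assert ok, diag

    def test_flow_output_passes(self, sds_model):
        template = cf.jacobian_template(sds_model)
        ok, diag = cf.multiaffinity_check(
            cf.BorderedProblem(template, "u1", "flow"))
        assert ok, diag

    def test_corrupted_template_fails(self, sds_model):
        broken = _corrupted_template(cf.jacobian_template(sds_model))
        ok, diag = cf.multiaffinity_check(
            cf.BorderedProblem(broken, ("eq", 1), ("var", 2)))
        assert not ok
        assert "column" in diag
        with pytest.raises(ValueError, match="sampling_oracle"):
            cf.vertex_sign(cf.BorderedProblem(broken, ("eq", 1), ("var", 2)))


class TestToyModuleOracle:
    """Two-species module with explicit equilibrium: b = u/d3 under a
    persistent input u on the A equation, so the influence on B is
    analytically positive."""

    def setup_method(self):
        self.template = cf.jacobian_template(cf.toy_conversion_module())
        self.problem = cf.BorderedProblem(self.template, ("eq", 1), ("var", 2))

    def test_vertex_matches_closed_form(self):
        assert cf.vertex_sign(self.problem) == "+"
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = np.exp(rng.uniform(-2, 2, size=3))
            # analytic equilibrium b(u) = u/d3: strictly increasing
            db_du = 1.0 / d[[p.name for p in self.template.directions].index("d3")]
            assert db_du > 0

    def test_bordered_determinant_is_d1(self):
        """Cofactor expansion gives bordered determinant d1 exactly."""
        names = [p.name for p in self.template.directions]
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = np.exp(rng.uniform(-2, 2, size=3))
            det = _bordered_det_numeric(self.problem, d)
            assert det == pytest.approx(d[names.index("d1")], rel=1e-10)

    def test_sampling_oracle_sees_only_positive(self):
        assert cf.sampling_oracle(self.problem, n_draws=500, seed=1) == {"+"}


class TestVertexSigns:
    def test_ns_x7_under_cert_inflow_is_positive(self, ns_model):
        """Feeding any CERT state increases double-bound CERT in the NS
        model, structurally."""
        template = cf.jacobian_template(ns_model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", cf.GateWarning)
            sign = cf.vertex_sign(cf.BorderedProblem(template, ("eq", 5), ("var", 7)))
        assert sign == "+"

    def test_gate_warning_attached(self, ns_model):
        template = cf.jacobian_template(ns_model)
        with pytest.warns(cf.GateWarning):
            cf.vertex_sign(cf.BorderedProblem(template, ("eq", 5), ("var", 7)))

    def test_exact_integer_determinant(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            M = rng.integers(-4, 5, size=(6, 6))
            assert _exact_int_det(M.astype(float)) == round(np.linalg.det(M))

    def test_influence_matrix_deterministic_and_serializable(self, sds_model, sds_summary):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", cf.GateWarning)
            mat = cf.influence_matrix(sds_model)
        assert mat.grid == sds_summary.grid
        assert mat.orientation.startswith("rows=outputs")
        assert set("".join("".join(r) for r in mat.grid)) <= set("+-0?")
        csv = mat.to_csv()
        assert csv.splitlines()[1].startswith("x1,")

    def test_flow_output_variant_compatibility(self, sds_model, ns_model):
        with pytest.raises(ValueError, match="incompatible"):
            cf.flow_influence(sds_model, "PHI_NS", "u1")
        with pytest.raises(ValueError, match="incompatible"):
            cf.flow_influence(ns_model, "PHI_SDS", "u1")


class TestConsistency:
    def test_entry_classes(self):
        rep = cf.compare(["+", "+", "+", "0"], ["+", "?", "-", "0"])
        assert rep.classes == (("strong", "weak", "inconsistent", "strong"),)
        assert rep.aggregate == "inconsistent"

    def test_aggregates(self):
        assert cf.compare(["+", "-"], ["+", "-"]).aggregate == "strongly consistent"
        assert cf.compare(["+", "?"], ["+", "-"]).aggregate == "weakly consistent"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cf.compare(["+", "-"], ["+"])

    def test_transpose_invariant_counts(self, sds_summary, ns_summary):
        a, b = sds_summary.grid, ns_summary.grid
        at = tuple(zip(*a))
        bt = tuple(zip(*b))
        assert cf.compare(a, b).counts == cf.compare(at, bt).counts


class TestSamplingOracle:
    @pytest.mark.parametrize("variant", [cf.SDS, cf.NS])
    def test_determinate_entries_sound_on_spot_checks(self, variant, request):
        summary = request.getfixturevalue(f"{variant.lower()}_summary")
        template = cf.jacobian_template(cf.build_model(variant))
        opposite = {"+": "-", "-": "+"}
        checked = 0
        for i in range(7):
            for j in range(7):
                s = summary.grid[i][j]
                if s == "?" or checked >= 6:
                    continue
                observed = cf.sampling_oracle(
                    cf.BorderedProblem(template, ("eq", j + 1), ("var", i + 1)),
                    n_draws=300, seed=13)
                assert opposite[s] not in observed
                checked += 1
        assert checked == 6

    def test_indeterminate_entry_witnessed_both_ways(self, sds_model):
        """The (x1, eq1) influence of the shuttle model is parameter
        dependent: vertex-neighbourhood sampling exhibits both signs."""
        template = cf.jacobian_template(sds_model)
        problem = cf.BorderedProblem(template, ("eq", 1), ("var", 1))
        out = cf.indeterminacy_witness(problem, seed=3)
        assert out["signs"] == {"+", "-"}
        for d in out["witnesses"].values():
            assert (np.asarray(d) > 0).all()

    def test_determinate_problem_has_no_witness(self):
        template = cf.jacobian_template(cf.toy_conversion_module())
        with pytest.raises(ValueError, match="not indeterminate"):
            cf.indeterminacy_witness(cf.BorderedProblem(template, ("eq", 1), ("var", 2)))

    def test_reproducible_under_seed(self, sds_model):
        template = cf.jacobian_template(sds_model)
        problem = cf.BorderedProblem(template, ("eq", 2), ("var", 5))
        assert (cf.sampling_oracle(problem, n_draws=100, seed=5)
                == cf.sampling_oracle(problem, n_draws=100, seed=5))


class TestBlockChecks:
    @pytest.mark.parametrize("variant", [cf.SDS, cf.NS])
    def test_templates_pass(self, variant):
        report = cf.block_structure_checks(cf.jacobian_template(cf.build_model(variant)))
        assert report["passed"], report["violations"]

    def test_weber_equilibrium_jacobian_passes(self, weber_sds):
        """Numeric Jacobian of the published shuttle system at its
        equilibrium: Metzler dominant blocks, coupling confined."""
        x = cf.find_steady_state(weber_sds, cf.FIG6_INITIAL_STATE)
        eps = 1e-4 * np.maximum(np.abs(x), 1.0)
        J = np.zeros((7, 7))
        for j in range(7):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps[j]
            xm[j] = max(xm[j] - eps[j], 0.0)
            J[:, j] = (weber_sds.rhs(xp) - weber_sds.rhs(xm)) / (xp[j] - xm[j])
        for lo, hi in MODULE_BLOCKS:
            B = J[lo:hi, lo:hi]
            off = B - np.diag(np.diag(B))
            assert (off >= -1e-12).all()
            assert (np.diag(B) < 0).all()
            assert (np.abs(np.diag(B)) >= off.sum(axis=0) - 1e-8).all()
        np.testing.assert_array_equal(
            np.sign(np.where(np.abs(J) > 1e-12, J, 0.0)), SDS_SIGN_PATTERN)

    def test_corrupted_spontaneous_column_fails(self, sds_model):
        template = cf.jacobian_template(sds_model)
        # a positive off-module entry in the column of the spontaneous
        # x6 -> x5 rate (column 6) violates coupling confinement
        bad = cf.DirectionParameter(name="corruption", column=5,
                                    incidence=(0, 1, 0, 0, 0, -1, 0))
        broken = cf.JacobianTemplate(structure=template.structure,
                                     directions=template.directions + (bad,),
                                     flow_directions=template.flow_directions)
        report = cf.block_structure_checks(broken, n_samples=5)
        assert not report["passed"]
        assert any("coupling" in v for v in report["violations"])
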