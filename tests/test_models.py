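"""Model-space: expansions, factoring, effective approximations, reading."""

import json

import numpy as np
import pytest
import sympy

from cartdyn import (
    BindingParameters,
    CoefficientMatrix,
    GrowthParameters,
    ResponseParameters,
    assemble_effective_rhs,
    classify_coefficients,
    effective_binding_coeffs,
    effective_response_coeffs,
    exact_binding_rate,
    expand_growth,
    factor_growth,
)
from cartdyn.models import ParameterError, exact_response, truncated_response

from conftest import XI_HIGH, XI_LOW


class TestExpandGrowth:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (GrowthParameters("logistic", rho=0.75, K=10.0), (0.75, -0.075, 0.0)),
            (
                GrowthParameters("strong_allee", rho=0.75, K=10.0, B=5.0),
                (-0.75, 0.225, -0.015),
            ),
            (GrowthParameters("none"), (0.0, 0.0, 0.0)),
        ],
    )
    def test_worked_examples(self, params, expected):
        np.testing.assert_allclose(expand_growth(params), expected, atol=1e-12)

    def test_weak_allee_limits_to_logistic(self):
        log = expand_growth(GrowthParameters("logistic", rho=0.4, K=7.0))
        weak = expand_growth(
            GrowthParameters("weak_allee", rho=0.4, K=7.0, A=1e9)
        )
        np.testing.assert_allclose(weak, log, atol=1e-9)

    def test_cubic_coefficient_never_positive(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rho, K = rng.uniform(0.05, 2.0), rng.uniform(1.0, 20.0)
            fam = rng.choice(["logistic", "weak_allee", "strong_allee"])
            kw = {}
            if fam == "weak_allee":
                kw["A"] = rng.uniform(0.2, 30.0)
            if fam == "strong_allee":
                kw["B"] = rng.uniform(0.05, 0.95) * K
            c = expand_growth(GrowthParameters(fam, rho=rho, K=K, **kw))
            assert c[2] <= 0
            if fam == "logistic":
                assert c[2] == 0

    def test_matches_symbolic_expansion(self):
        """Dual route: sympy expansion of the factored forms."""
        x, rho, K, A, B = sympy.symbols("x rho K A B", positive=True)
        forms = {
            "logistic": rho * x * (1 - x / K),
            "weak_allee": rho * x * (1 - x / K) * (1 + x / A),
            "strong_allee": rho * x * (1 - x / K) * (x / B - 1),
        }
        subs = {rho: 0.33, K: 8.5, A: 2.75, B: 3.1}
        for fam, expr in forms.items():
            poly = sympy.Poly(sympy.expand(expr.subs(subs)), x)
            coeffs = [float(poly.coeff_monomial(x**p)) for p in (1, 2, 3)]
            got = expand_growth(
                GrowthParameters(
                    fam,
                    rho=subs[rho],
                    K=subs[K],
                    A=subs[A] if fam == "weak_allee" else None,
                    B=subs[B] if fam == "strong_allee" else None,
                )
            )
            np.testing.assert_allclose(got, coeffs, rtol=1e-12)

    def test_missing_allee_parameter_raises(self):
        with pytest.raises(ParameterError):
            GrowthParameters("weak_allee", rho=0.5, K=5.0)
        with pytest.raises(ParameterError):
            GrowthParameters("strong_allee", rho=0.5, K=5.0)


class TestFactorGrowth:
    def test_high_et_cancer_triple(self):
        g = factor_growth(0.121, 0.061, -0.018)
        assert g.family == "weak_allee"
        assert g.rho == pytest.approx(0.121)
        assert g.K == pytest.approx(4.792, rel=0.01)
        # published table prints A = 1.421 but the printed coefficients
        # factor to ~1.403; a 2% band covers the discrepancy
        assert g.A == pytest.approx(1.421, rel=0.02)

    def test_medium_et_cancer_triple(self):
        g = factor_growth(0.237, 0.04, -0.012)
        assert g.family == "weak_allee"
        assert g.K == pytest.approx(6.413, rel=0.01)
        assert g.A == pytest.approx(3.08, rel=0.02)

    def test_low_et_cancer_triple_is_logistic(self):
        g = factor_growth(0.150, -0.012, 0.0)
        assert g.family == "logistic"
        assert g.rho == pytest.approx(0.15)
        assert g.K == pytest.approx(12.5, rel=0.01)

    @pytest.mark.parametrize("family", ["logistic", "weak_allee", "strong_allee"])
    def test_round_trip(self, family):
        rng = np.random.default_rng(11)
        for _ in range(40):
            rho, K = rng.uniform(0.05, 2.0), rng.uniform(1.0, 20.0)
            kw = {}
            if family == "weak_allee":
                kw["A"] = rng.uniform(0.2, 30.0)
            if family == "strong_allee":
                kw["B"] = rng.uniform(0.05, 0.95) * K
            g = GrowthParameters(family, rho=rho, K=K, **kw)
            back = factor_growth(*expand_growth(g))
            assert back.family == family
            assert back.rho == pytest.approx(g.rho, rel=1e-9)
            assert back.K == pytest.approx(g.K, rel=1e-9)
            if family == "weak_allee":
                assert back.A == pytest.approx(g.A, rel=1e-9)
            if family == "strong_allee":
                assert back.B == pytest.approx(g.B, rel=1e-9)

    def test_unmatched_pattern_warns_not_raises(self):
        # c3 = 0 with positive curvature fits no family
        with pytest.warns(UserWarning, match="no growth family"):
            g = factor_growth(0.1, 0.05, 0.0)
        assert g.family == "none"

    def test_all_zero_is_none_silently(self):
        assert factor_growth(0.0, 0.0, 0.0).family == "none"


class TestBinding:
    # rate constants from the double-binding illustration
    BP = BindingParameters(a=20.0, b=5.0, h=16.0, k=2.0)
    BP_EFF = BindingParameters(a=20.0, b=2.75, h=16.0, k=2.0)

    def test_single_binding_rate(self):
        bp = BindingParameters(a=20.0, h=16.0)
        assert exact_binding_rate(bp, 1.0, "single", "cancer") == pytest.approx(1.25)

    def test_no_effectors_no_binding(self):
        assert exact_binding_rate(self.BP, 0.0, "double", "cancer") == 0.0
        assert exact_binding_rate(self.BP, 0.0, "single", "cart") == 0.0

    def test_double_binding_rate(self):
        got = exact_binding_rate(self.BP, 1.0, "double", "cancer")
        assert got == pytest.approx(25.0 / 18.0)

    def test_h_zero_raises(self):
        bp = BindingParameters(a=1.0, h=0.0)
        with pytest.raises(ZeroDivisionError):
            exact_binding_rate(bp, 1.0, "single", "cancer")
        with pytest.raises(ZeroDivisionError):
            effective_binding_coeffs(bp)

    def test_effective_coefficients(self):
        lin, quad = effective_binding_coeffs(self.BP_EFF, "cancer")
        assert lin == pytest.approx(1.25)
        assert quad == pytest.approx((2.75 * 16 - 20 * 2) / 16**2)  # 0.015625

    def test_small_double_death_rates_flag_concavity(self):
        bp = BindingParameters(a=20.0, b=0.0, c=5.0, d=0.0, h=16.0, k=2.0)
        with pytest.warns(UserWarning, match="concavity"):
            _, quad = effective_binding_coeffs(bp, "cancer")
        assert quad < 0
        with pytest.warns(UserWarning):
            _, quad_cart = effective_binding_coeffs(bp, "cart")
        assert quad_cart < 0

    def test_single_binding_limit_quadratic_vanishes(self):
        bp = BindingParameters(a=20.0, b=0.0, h=16.0, k=0.0)
        _, quad = effective_binding_coeffs(bp, "cancer")
        assert quad == 0.0

    def test_effective_close_to_exact_below_one_ci(self):
        """Truncated expansion tracks the rational form for y < 1 CI."""
        y = np.linspace(0.0, 1.0, 201)
        lin, quad = effective_binding_coeffs(self.BP_EFF, "cancer")
        eff = lin * y + quad * y * y
        exact = exact_binding_rate(self.BP_EFF, y, "double", "cancer")
        assert np.max(np.abs(eff - exact)) < 0.05


class TestResponse:
    def test_type_i(self):
        assert effective_response_coeffs(
            ResponseParameters("I", p=1.2)
        ) == pytest.approx((1.2, 0.0))

    def test_type_ii_leading_term_is_type_i_like(self):
        cx, cx2 = effective_response_coeffs(ResponseParameters("II", p=1.0, g=5.0))
        assert cx == pytest.approx(1.0 / 5.0)
        assert cx2 == pytest.approx(-1.0 / 25.0)
        # leading order indistinguishable from a Type I of rate p/g
        x = np.linspace(0, 0.5, 50)
        np.testing.assert_allclose(
            truncated_response(ResponseParameters("II", p=1.0, g=5.0), x, 1),
            exact_response(ResponseParameters("I", p=1.0 / 5.0), x),
            rtol=1e-12,
        )

    def test_type_iii(self):
        assert effective_response_coeffs(
            ResponseParameters("III", p=1.0, g=5.0)
        ) == pytest.approx((0.0, 0.04))

    def test_invalid_threshold_raises(self):
        with pytest.raises(ParameterError):
            ResponseParameters("II", p=1.0, g=0.0)

    @pytest.mark.parametrize("rtype", ["II", "III"])
    def test_truncation_converges_monotonically(self, rtype):
        """Partial sums approach the rational form for x/g < 1."""
        rp = ResponseParameters(rtype, p=1.0, g=5.0)
        x = np.linspace(0.05, 4.5, 90)  # x/g < 1
        exact = exact_response(rp, x)
        errors = [
            np.max(np.abs(truncated_response(rp, x, k) - exact))
            for k in range(1, 12)
        ]
        assert all(e2 <= e1 + 1e-15 for e1, e2 in zip(errors, errors[1:]))
        # geometric convergence: error ratio bounded by (x_max/g)^degree
        assert errors[-1] < errors[0] * 0.9**10 * 1.01
        # deep-expansion regime: fast convergence for x well inside g
        x_small = np.linspace(0.0, 2.5, 40)
        err_small = np.max(
            np.abs(
                truncated_response(rp, x_small, 12)
                - exact_response(rp, x_small)
            )
        )
        assert err_small < 1e-3


class TestAssembleAndClassify:
    def test_growth_only_populates_growth_columns(self):
        xi = assemble_effective_rhs(
            GrowthParameters("logistic", rho=0.5, K=10.0),
            GrowthParameters("logistic", rho=0.2, K=0.5),
        )
        active = {i for i in range(9) if xi.xi[0, i] != 0}
        assert active == {0, 2}
        active_y = {i for i in range(9) if xi.xi[1, i] != 0}
        assert active_y == {1, 4}

    def test_reassembled_high_et_model_matches_printed_matrix(self):
        """Components reverse-engineered from the printed 1:4 model."""
        gx = factor_growth(0.121, 0.061, -0.018)
        gy = factor_growth(0.191, -0.351, 0.0)
        # killing is purely double binding (a=0, b such that b*h/h^2 = 0.593)
        h = 1.0
        bp = BindingParameters(a=0.0, b=0.593 * h, c=0.0, d=0.0, h=h, k=0.0)
        # response: alpha = p/g = 0.035, beta = -p/g^2 = -0.009
        g = 0.035 / 0.009
        rp = ResponseParameters("II", p=0.035 * g, g=g)
        xi = assemble_effective_rhs(gx, gy, bp, rp)
        np.testing.assert_allclose(xi.xi, XI_HIGH, atol=1e-12)

    def test_weak_allee_type_ii_double_sign_pattern(self):
        xi = assemble_effective_rhs(
            GrowthParameters("weak_allee", rho=0.121, K=4.792, A=1.403),
            GrowthParameters("logistic", rho=0.19, K=0.54),
            BindingParameters(a=0.0, b=0.6, h=1.0, k=0.0),
            ResponseParameters("II", p=0.14, g=3.9),
        )
        assert xi.term(0, "x") > 0 and xi.term(0, "x^2") > 0
        assert xi.term(0, "x^3") < 0
        assert xi.term(1, "xy") > 0 and xi.term(1, "x^2y") < 0

    def test_classify_printed_models(self):
        high = classify_coefficients(CoefficientMatrix(XI_HIGH))
        assert high.cancer_growth.family == "weak_allee"
        assert high.cart_growth.family == "logistic"
        assert high.response_type == "II"
        assert high.binding_mode == "double"
        assert high.b_tilde == pytest.approx(0.593)

        low = classify_coefficients(CoefficientMatrix(XI_LOW))
        assert low.cancer_growth.family == "logistic"
        assert low.cart_growth.family == "none"
        assert low.response_type == "III"
        assert low.binding_mode == "mixed"
        assert low.a_tilde == pytest.approx(0.545)
        assert low.c_tilde == pytest.approx(0.063)

    def test_classify_zero_matrix(self):
        interp = classify_coefficients(np.zeros((2, 9)))
        assert interp.cancer_growth.family == "none"
        assert interp.cart_growth.family == "none"
        assert interp.response_type == "none"
        assert interp.binding_mode == "none"

    @pytest.mark.parametrize("gx_fam", ["logistic", "weak_allee", "strong_allee"])
    @pytest.mark.parametrize("bmode", ["single", "double"])
    @pytest.mark.parametrize("rtype", ["I", "II", "III"])
    def test_classify_inverts_assemble(self, gx_fam, bmode, rtype):
        """Every growth x binding x response combination reads back."""
        kw = {"A": 2.0} if gx_fam == "weak_allee" else (
            {"B": 3.0} if gx_fam == "strong_allee" else {}
        )
        gx = GrowthParameters(gx_fam, rho=0.3, K=8.0, **kw)
        gy = GrowthParameters("logistic", rho=0.15, K=0.6)
        bp = BindingParameters(a=0.4, b=0.3, c=0.02, d=0.05, h=1.0, k=0.1)
        rp = ResponseParameters(rtype, p=0.5, g=4.0)
        interp = classify_coefficients(
            assemble_effective_rhs(gx, gy, bp, rp, binding_mode=bmode)
        )
        assert interp.cancer_growth.family == gx_fam
        assert interp.cancer_growth.K == pytest.approx(8.0, rel=1e-6)
        if bmode == "double":
            assert interp.binding_mode == "double"
        else:
            assert interp.binding_mode == "single"
        expected_type = {"I": "I_or_II_leading", "II": "II", "III": "III"}
        assert interp.response_type == expected_type[rtype]


class TestCoefficientMatrixIO:
    def test_json_round_trip(self, tmp_path):
        xi = CoefficientMatrix(XI_HIGH)
        path = tmp_path / "xi.json"
        xi.to_json(path)
        back = CoefficientMatrix.from_json(path)
        assert back == xi
        doc = json.loads(path.read_text())
        assert doc["library_order"][0] == "x"

    def test_permuted_library_order_is_unscrambled(self):
        doc = CoefficientMatrix(XI_HIGH).to_dict()
        perm = list(range(9))[::-1]
        doc_perm = {
            "library_order": [doc["library_order"][i] for i in perm],
            "xi": [[row[i] for i in perm] for row in doc["xi"]],
        }
        back = CoefficientMatrix.from_dict(doc_perm)
        np.testing.assert_array_equal(back.xi, XI_HIGH)

    def test_shape_and_finiteness_validated(self):
        with pytest.raises(ParameterError):
            CoefficientMatrix(np.zeros((3, 9)))
        bad = np.zeros((2, 9))
        bad[0, 0] = np.nan
        with pytest.raises(ParameterError):
            CoefficientMatrix(bad)
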