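"""Feature transforms, published enhancement factors, energy assembly."""

import numpy as np
import pytest

from xcevolve.functionals import (
    B97_PARAMS,
    DEFAULT_LDA,
    GridSystem,
    b97_enhancement,
    b97_program,
    compute_features,
    eq5_enhancement,
    exc_semilocal,
    expand_to_b97,
    combined_fxc,
    gas22_enhancement,
    gas22_functional,
    lda_energy_densities,
    load_wb97mv_coefficients,
    wb97mv_enhancement,
    wb97mv_functional,
    WB97MV_TERM_SUBSETS,
)
from xcevolve.programs import (
    InstructionProgram,
    Instruction,
    Symbol,
    SymbolicFunctional,
    execute_program,
)


class TestFeatures:
    def test_zero_gradient_zeroes_all_gradient_features(self):
        fs = compute_features(np.array([1.0]), grad_norm=np.array([0.0]),
                              gamma=0.004)
        assert fs.x[0] == fs.x2[0] == fs.s[0] == fs.u[0] == 0.0

    def test_wigner_seitz_radius_inverts_density(self):
        rho = 3.0 / (4.0 * np.pi * 125.0)
        fs = compute_features(np.array([rho]), x2=np.array([0.0]))
        assert fs.rs[0] == pytest.approx(5.0, rel=1e-12)

    def test_transform_fixed_point_is_one_half(self):
        for gamma in (0.004, 0.469, 1.7):
            fs = compute_features(np.array([1.0]), x2=np.array([1.0 / gamma]),
                                  gamma=gamma)
            assert fs.u[0] == pytest.approx(0.5, rel=1e-12)

    def test_u_is_increasing_and_bounded(self, rng):
        x2 = np.sort(10.0 ** rng.uniform(-4, 4, 500))
        fs = compute_features(np.ones_like(x2), x2=x2, gamma=0.3)
        assert np.all(np.diff(fs.u) > 0)
        assert np.all((fs.u >= 0) & (fs.u < 1))

    def test_nonpositive_density_is_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            compute_features(np.array([0.0]), x2=np.array([1.0]))


class TestClosedForms:
    def test_b97_limits(self):
        assert b97_enhancement(0.0, *[B97_PARAMS[k] for k in
                                      ("c0", "c1", "c2", "gam")]) == 0.8094
        # u -> 1 limit
        big = b97_enhancement(1e14, 0.8094, 0.5073, 0.7481, 0.004)
        assert big == pytest.approx(0.8094 + 0.5073 + 0.7481, rel=1e-9)

    def test_expansion_reproduces_published_b97_coefficients(self):
        b0, b1, b2 = expand_to_b97(0.8504, 0.7480, 0.3394)
        assert b0 == pytest.approx(0.8094, abs=1e-3)
        assert b1 == pytest.approx(0.5073, abs=1e-3)
        assert b2 == pytest.approx(0.7481, abs=1e-3)

    def test_expansion_degenerate_quadratic(self):
        assert expand_to_b97(0.9, 0.0, 0.5) == (pytest.approx(0.81), 0.0, 0.0)

    def test_expanded_quadratic_is_pointwise_identical(self, rng):
        x2 = 10.0 ** rng.uniform(-4, 4, 1000)
        c0, c1, c2, g = 0.8504, 0.7480, 0.3394, 0.004
        b0, b1, b2 = expand_to_b97(c0, c1, c2)
        np.testing.assert_allclose(
            eq5_enhancement(x2, c0, c1, c2, g),
            b97_enhancement(x2, b0, b1, b2, g),
            rtol=1e-12,
        )

    def test_gas22_anchor_values(self):
        assert gas22_enhancement("x", x2=0.0, w=0.0) == pytest.approx(0.862)
        assert gas22_enhancement("cos", x=0.0, w=0.0) == pytest.approx(0.805)
        assert gas22_enhancement("css", u=0.0, w=0.0, x2=0.0) == 0.0

    def test_gas22_program_matches_closed_form(self, rng):
        functional, params = gas22_functional()
        x2 = 10.0 ** rng.uniform(-4, 4, 1000)
        w = rng.uniform(-1, 1, 1000)
        for ch, kind in (("x", "x"), ("css", "css"), ("cos", "cos")):
            got = execute_program(functional.programs[ch],
                                  {"x2": x2, "w": w}, params)
            want = gas22_enhancement(kind, x2=x2, w=w)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_power_series_term_subsets_are_enforced(self):
        with pytest.raises(ValueError, match="subset"):
            wb97mv_enhancement("x", 0.5, 0.5, {"21": 1.0})

    def test_power_series_values(self, rng):
        assert wb97mv_enhancement("x", 0.3, -0.7, {}) == 0.0
        assert wb97mv_enhancement("x", 0.3, -0.7, {"00": 1.0}) == 1.0
        # brute-force polynomial oracle on the opposite-spin subset
        u, w = rng.uniform(0, 1, 50), rng.uniform(-1, 1, 50)
        coeffs = {t: rng.standard_normal() for t in WB97MV_TERM_SUBSETS["cos"]}
        want = sum(c * w ** int(t[0]) * u ** int(t[1]) for t, c in coeffs.items())
        np.testing.assert_allclose(
            wb97mv_enhancement("cos", u, w, coeffs), want, rtol=1e-12)

    def test_wb97mv_programs_match_power_series(self, rng):
        functional, params = wb97mv_functional()
        table = load_wb97mv_coefficients()
        x2 = 10.0 ** rng.uniform(-4, 4, 500)
        w = rng.uniform(-1, 1, 500)
        for ch in ("x", "css", "cos"):
            g = table["gamma"][ch]
            u = g * x2 / (1 + g * x2)
            coeffs = {t: table["coefficients"][ch][t]
                      for t in WB97MV_TERM_SUBSETS[ch]}
            got = execute_program(functional.programs[ch],
                                  {"x2": x2, "w": w}, params)
            np.testing.assert_allclose(
                got, wb97mv_enhancement(ch, u, w, coeffs), rtol=1e-12)


class TestLdaAndAssembly:
    def test_default_exchange_closed_form_and_scaling(self):
        e_x, e_ss, e_os = lda_energy_densities(np.array([1.0, 2.0]))
        assert e_x[0] == pytest.approx(-0.75 * (3 / np.pi) ** (1 / 3))
        assert e_x[1] / e_x[0] == pytest.approx(2 ** (4 / 3), rel=1e-12)
        assert np.all(e_ss < 0) and np.all(e_os < 0)

    def test_vanishing_density_limit(self):
        e_x, e_ss, e_os = lda_energy_densities(np.array([1e-12]))
        assert abs(e_x[0]) < 1e-12 and abs(e_ss[0]) < 1e-12

    def test_single_point_hand_quadrature(self):
        # one grid point, weight 2, F_x = 1.5 constant, correlation empty:
        # E = 2 * e_x(rho) * 1.5
        ws = (Symbol("x2", "feature"), Symbol("c", "parameter"),
              Symbol("F", "variable"))
        prog = InstructionProgram(
            workspace=ws, instructions=(Instruction("add", "F", ("F", "c")),))
        empty = InstructionProgram(workspace=ws)
        fun = SymbolicFunctional({"x": prog, "css": empty, "cos": empty})
        sys1 = GridSystem("a", rho=[1.0], x2=[0.0], w=[0.0], quad_weights=[2.0])
        e_x = -0.75 * (3 / np.pi) ** (1 / 3)
        got = exc_semilocal(sys1, fun, {"c": 1.5})
        assert got == pytest.approx(2.0 * e_x * 1.5, rel=1e-12)

    def test_zero_functional_gives_zero_energy(self, b97_truth):
        fun, _ = b97_truth
        empty = SymbolicFunctional({
            ch: InstructionProgram(workspace=fun.programs[ch].workspace)
            for ch in ("x", "css", "cos")})
        sys1 = GridSystem("a", rho=[1.0, 2.0], x2=[1.0, 2.0], w=[0.0, 0.0],
                          quad_weights=[1.0, 1.0])
        assert exc_semilocal(sys1, empty, {}) == 0.0

    def test_energy_is_linear_in_the_enhancement_factor(self, rng):
        ws = (Symbol("x2", "feature"), Symbol("c", "parameter"),
              Symbol("F", "variable"))
        prog = InstructionProgram(
            workspace=ws, instructions=(Instruction("add", "F", ("F", "c")),))
        empty = InstructionProgram(workspace=ws)
        fun = SymbolicFunctional({"x": prog, "css": empty, "cos": empty})
        sys1 = GridSystem("a", rho=rng.uniform(0.5, 2, 8),
                          x2=rng.uniform(0, 10, 8), w=np.zeros(8),
                          quad_weights=rng.uniform(0, 1, 8))
        e1 = exc_semilocal(sys1, fun, {"c": 1.0})
        e3 = exc_semilocal(sys1, fun, {"c": 3.0})
        assert e3 == pytest.approx(3.0 * e1, rel=1e-12)

    def test_combined_fxc_is_identity_for_unit_factors(self):
        ws = (Symbol("x2", "feature"), Symbol("c", "parameter"),
              Symbol("F", "variable"))
        unit = InstructionProgram(
            workspace=ws, instructions=(Instruction("add", "F", ("F", "c")),))
        fun = SymbolicFunctional({"x": unit, "css": unit, "cos": unit})
        feats = {"rho": np.array([0.3, 1.0, 4.0]), "x2": np.zeros(3),
                 "w": np.zeros(3)}
        np.testing.assert_allclose(combined_fxc(feats, fun, {"c": 1.0}), 1.0)

    def test_fxc_curves_finite_on_the_plotting_domain(self):
        # s in [0,3] x rs in (0,5] x w in {-1,0,1} for both published forms
        s = np.linspace(0, 3, 100)
        x2 = (2 * (3 * np.pi**2) ** (1 / 3) * s) ** 2
        for functional, params in (gas22_functional(), wb97mv_functional()):
            for rs in (0.5, 1.0, 2.0, 3.0, 5.0):
                rho = 3 / (4 * np.pi * rs**3)
                for w in (-1.0, 0.0, 1.0):
                    feats = {"rho": np.full_like(s, rho), "x2": x2,
                             "w": np.full_like(s, w)}
                    fxc = combined_fxc(feats, functional, params)
                    assert np.all(np.isfinite(fxc))
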