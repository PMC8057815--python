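"""Fixed-point planes, Jacobian structure and vector fields."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import saccadapt as sa
from saccadapt.learning import LearningRates, simulate
from saccadapt.model import ErrorMode, GainState, error_value
from saccadapt.stability import (
    SingularSlice,
    StabilityLabel,
    classify,
    delta_omega,
    fixed_point_omega_m,
    jacobian,
    jacobian_fd,
    vector_field,
)

RATES = LearningRates(5.2e-6, 3.5e-5, 1.8e-5)
gains = st.floats(min_value=0.5, max_value=1.5, allow_nan=False)


class TestFixedPointPlane:
    def test_baseline_identity_point(self):
        assert fixed_point_omega_m(1.0, 1.0, sa.condition("baseline")) == pytest.approx(1.0)

    def test_cts_inward_example(self):
        wm = fixed_point_omega_m(1.0, 1.0, sa.condition("CTS_in"))
        assert wm == pytest.approx(10.0 / 13.0)

    def test_cve_zero_step_degenerate_branch(self):
        p = sa.condition("CVE_in")
        p0 = sa.Paradigm(sa.ParadigmKind.CVE, P1=13.0, Ps=0.0)
        assert fixed_point_omega_m(1.0, 0.8, p0) == 0.0

    @pytest.mark.parametrize(
        "cond, wcd", [("CTS_in", 2.0), ("CVE_out", 1.0)]
    )
    def test_singular_slices_signal(self, cond, wcd):
        with pytest.raises(SingularSlice):
            fixed_point_omega_m(1.0, wcd, sa.condition(cond))

    def test_omega_v_zero_signals(self):
        with pytest.raises(SingularSlice):
            fixed_point_omega_m(0.0, 1.0, sa.condition("CTS_in"))

    @pytest.mark.parametrize("cond", ["CTS_in", "CTS_out", "CVE_in", "CVE_out", "baseline"])
    def test_plane_nullifies_postdiction_error(self, cond):
        """Substituting the plane formula zeroes E_post to 1e-12 over a grid."""
        paradigm = sa.condition(cond)
        for wv in np.linspace(0.8, 1.2, 9):
            for wcd in np.linspace(0.5, 1.5, 11):
                if paradigm.kind.value == "CVE" and abs(wcd - 1.0) < 1e-6:
                    continue
                wm = fixed_point_omega_m(wv, wcd, paradigm)
                e = error_value(GainState(wv, wm, wcd), paradigm, ErrorMode.POSTDICTION)
                assert abs(e) < 1e-12


class TestDeltaOmega:
    def test_zero_on_plane(self):
        p = sa.condition("CTS_out")
        wm = fixed_point_omega_m(1.0, 0.9, p)
        assert delta_omega(GainState(1.0, wm, 0.9), RATES, p) == pytest.approx([0, 0, 0], abs=1e-15)

    def test_unity_state_inward_example(self):
        d = delta_omega(GainState(1, 1, 1), LearningRates(1e-6, 1e-6, 1e-6), sa.condition("CTS_in"))
        assert d == pytest.approx([-7.8e-5, -7.8e-5, 7.8e-5])

    def test_zero_rates(self):
        d = delta_omega(GainState(0.7, 1.2, 0.9), LearningRates(0, 0, 0), sa.condition("CVE_in"))
        assert np.all(d == 0)


class TestJacobian:
    @given(wv=gains, wm=gains, wcd=gains)
    def test_analytic_matches_finite_differences_cts(self, wv, wm, wcd):
        p = sa.condition("CTS_in")
        J = jacobian(GainState(wv, wm, wcd), RATES, p)
        J_fd = jacobian_fd(GainState(wv, wm, wcd), RATES, p)
        assert J == pytest.approx(J_fd, rel=1e-5, abs=1e-12)

    def test_zero_rates_zero_matrix(self):
        J = jacobian(GainState(1, 1, 1), LearningRates(0, 0, 0), sa.condition("CTS_in"))
        assert np.all(J == 0)

    def test_rank_one_structure_at_fixed_point(self):
        """At E = 0 the Jacobian is -2 diag(alpha) g g^T: eigenvalues
        {0, 0, -2 sum alpha_i g_i^2}."""
        p = sa.condition("CTS_out")
        wv, wcd = 1.0, 0.9
        wm = fixed_point_omega_m(wv, wcd, p)
        state = GainState(wv, wm, wcd)
        J = jacobian(state, RATES, p)
        assert np.linalg.matrix_rank(J, tol=1e-12) == 1
        g = np.array(sa.error_gradient(state, p, "postdiction"))
        lam = -2.0 * np.sum(np.array(RATES.as_tuple()) * g**2)
        eig = np.sort_complex(np.linalg.eigvals(J))
        assert eig[0].real == pytest.approx(lam, rel=1e-9)
        assert abs(eig[1]) < 1e-12 and abs(eig[2]) < 1e-12
        assert lam < 0  # transverse direction attracts

    def test_cve_full_differentiation_flag_differs(self):
        p = sa.condition("CVE_in")
        state = GainState(1.0, 0.9, 0.8)
        J_clamped = jacobian(state, RATES, p)
        J_full = jacobian(state, RATES, p, differentiate_through_step=True)
        assert not np.allclose(J_clamped, J_full)


class TestClassify:
    def test_stable_at_cts_fixed_point(self):
        p = sa.condition("CTS_in")
        wm = fixed_point_omega_m(1.0, 1.1, p)
        rep = classify(jacobian(GainState(1.0, wm, 1.1), RATES, p))
        assert rep.label is StabilityLabel.STABLE
        assert rep.tau < 0
        assert rep.discriminant == pytest.approx(rep.tau**2 - 4 * rep.det)

    def test_zero_matrix_marginal(self):
        rep = classify(np.zeros((3, 3)))
        assert rep.label is StabilityLabel.MARGINAL

    def test_constructed_positive_eigenvalue_unstable(self):
        rep = classify(np.diag([1e-3, -1e-3, 0.0]))
        assert rep.label is StabilityLabel.UNSTABLE


class TestVectorField:
    def test_zero_arrow_on_plane_point(self):
        p = sa.condition("CTS_in")
        wm_star = fixed_point_omega_m(1.0, 1.0, p)
        field = vector_field(p, RATES, 1.0, [wm_star], [1.0])
        assert field["d_omega_m"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert field["epost"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_arrows_point_toward_smaller_motor_gain_right_of_curve(self):
        p = sa.condition("CTS_in")
        wm_star = fixed_point_omega_m(1.0, 1.0, p)
        field = vector_field(p, RATES, 1.0, [wm_star + 0.1], [1.0])
        assert field["d_omega_m"].iloc[0] < 0

    def test_linear_in_rates(self):
        p = sa.condition("CVE_out")
        grid_m, grid_cd = np.linspace(0.8, 1.2, 3), np.linspace(0.8, 1.2, 3)
        f1 = vector_field(p, RATES, 1.0, grid_m, grid_cd)
        double = LearningRates(*(2 * a for a in RATES.as_tuple()))
        f2 = vector_field(p, double, 1.0, grid_m, grid_cd)
        assert np.allclose(2 * f1[["d_omega_m", "d_omega_cd"]], f2[["d_omega_m", "d_omega_cd"]])


def test_converged_simulations_end_near_plane():
    """Long postdiction runs terminate within 1e-3 (in omega_m) of the plane."""
    for cond in ("CTS_in", "CTS_out", "CVE_in", "CVE_out"):
        p = sa.condition(cond)
        tr = simulate(GainState(1.0, 0.95, 0.985), RATES, p, 20_000, "postdiction")
        wv, wm, wcd = tr.omega[-1]
        assert abs(wm - fixed_point_omega_m(wv, wcd, p)) < 1e-3
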