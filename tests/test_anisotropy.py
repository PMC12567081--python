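"""Jones-matrix algebra: forward model, both inversions, layer composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from jtez.anisotropy import (
    AnisotropyState,
    ArccosDomainError,
    SingularBranchError,
    generator,
    invert_exact,
    invert_closed_form,
    jones_forward,
    q_modulus,
    stack_product,
)

FIELDS = ("lb_0_90", "lb_45_135", "cb", "ld_0_90", "ld_45_135", "cd")

finite_component = st.floats(-1.5, 1.5, allow_nan=False)
state_strategy = st.builds(AnisotropyState, *([finite_component] * 6))


class TestQModulus:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({}, 0.0),
            ({"lb_0_90": 0.6}, 0.6),
            ({"lb_0_90": 0.3, "lb_45_135": 0.4}, 0.5),
        ],
    )
    def test_values(self, kwargs, expected):
        assert q_modulus(AnisotropyState(**kwargs)) == pytest.approx(expected, abs=1e-15)

    def test_equals_aggregate_form(self):
        s = AnisotropyState(0.3, -0.2, 0.5, 0.1, 0.15, -0.4)
        agg = np.sqrt(float(s.lb) ** 2 + s.cb**2 + float(s.ld) ** 2 + s.cd**2)
        assert q_modulus(s) == pytest.approx(agg, rel=1e-14)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            AnisotropyState(lb_0_90=np.nan)


class TestForward:
    def test_identity_for_isotropic(self):
        np.testing.assert_allclose(jones_forward(AnisotropyState()), np.eye(2), atol=1e-15)

    def test_pure_optical_activity_is_rotation(self):
        theta = 0.7
        W = jones_forward(AnisotropyState(cb=theta))
        R = np.array(
            [[np.cos(theta / 2), np.sin(theta / 2)], [-np.sin(theta / 2), np.cos(theta / 2)]]
        )
        np.testing.assert_allclose(W, R, atol=1e-12)

    def test_matches_matrix_exponential(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            s = AnisotropyState(*rng.uniform(-1, 1, 6))
            W = jones_forward(s)
            np.testing.assert_allclose(W, expm(0.5 * generator(s)), atol=1e-10)

    def test_small_q_series_branch(self):
        s = AnisotropyState(lb_0_90=1e-9, cb=1e-9)
        W = jones_forward(s)
        np.testing.assert_allclose(W, expm(0.5 * generator(s)), atol=1e-14)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(state_strategy)
    def test_unimodular(self, s):
        assert abs(np.linalg.det(jones_forward(s)) - 1.0) < 1e-10

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(finite_component, finite_component, finite_component)
    def test_unitary_iff_phase_only(self, lb0, lb45, cb):
        W = jones_forward(AnisotropyState(lb_0_90=lb0, lb_45_135=lb45, cb=cb))
        np.testing.assert_allclose(W.conj().T @ W, np.eye(2), atol=1e-10)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(-1, 1, (5, 4, 6))
        field = jones_forward(AnisotropyState(*(vals[..., i] for i in range(6))))
        assert field.shape == (5, 4, 2, 2)
        one = jones_forward(AnisotropyState(*vals[2, 1]))
        np.testing.assert_allclose(field[2, 1], one, atol=1e-14)


class TestInvertPaper:
    def test_identity(self):
        agg = invert_closed_form(np.eye(2, dtype=complex))
        for v in (agg.q, agg.lb, agg.cb, agg.ld, agg.cd):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_phase_only(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            lb0, lb45, cb = rng.uniform(-1.5, 1.5, 3)
            s = AnisotropyState(lb_0_90=lb0, lb_45_135=lb45, cb=cb)
            if not 1e-3 < s.q_abs < 2 * np.pi - 1e-3:
                continue
            agg = invert_closed_form(jones_forward(s))
            assert abs(agg.lb - s.lb) < 1e-8
            assert abs(agg.cb - cb) < 1e-8
            assert abs(agg.ld) < 1e-8 and abs(agg.cd) < 1e-8

    def test_weak_dichroism_near_exact(self):
        """Closed-form inversion approaches the exact one for weak dichroism:
        2nd-order-accurate birefringence (<< 5%), 1st-order dichroism (< 10%)."""
        s = AnisotropyState(0.6, 0.5, 0.5, 0.03, 0.02, 0.04)
        ap = invert_closed_form(jones_forward(s))
        _, ex = invert_exact(jones_forward(s))
        for name in ("lb", "cb"):
            a, e = float(getattr(ap, name)), float(getattr(ex, name))
            assert abs(a - e) <= 0.05 * abs(e)
        for name in ("ld", "cd"):
            a, e = float(getattr(ap, name)), float(getattr(ex, name))
            assert abs(a - e) <= 0.10 * abs(e)

    def test_convergence_order_in_dichroism(self):
        """Birefringence readouts are 2nd-order accurate in dichroism, dichroism readouts 1st-order."""

        def errs(ld):
            s = AnisotropyState(lb_0_90=0.7, cb=0.6, ld_0_90=ld, cd=0.5 * ld)
            ap = invert_closed_form(jones_forward(s))
            _, ex = invert_exact(jones_forward(s))
            return {k: abs(float(getattr(ap, k)) - float(getattr(ex, k))) for k in ("lb", "cb", "ld", "cd")}

        e1, e2 = errs(0.1), errs(0.05)
        for k in ("lb", "cb"):
            assert 3.0 <= e1[k] / e2[k] <= 5.0
        for k in ("ld", "cd"):
            assert 1.5 <= e1[k] / e2[k] <= 2.5

    def test_arccos_domain_error_and_clip(self):
        W = jones_forward(AnisotropyState(ld_0_90=1.5))  # strongly dichroic: tr/2 > 1
        with pytest.raises(ArccosDomainError):
            invert_closed_form(W)
        agg = invert_closed_form(W, clip_arccos=True)
        assert np.all(np.isfinite([agg.lb, agg.cb, agg.ld, agg.cd]))

    def test_eq15_convention_swaps_roles(self):
        s = AnisotropyState(lb_0_90=0.5, cb=0.4)
        W = jones_forward(s)
        swapped = invert_closed_form(W, convention="eq15")
        assert abs(swapped.ld - s.lb) < 1e-8  # birefringence read out as dichroism
        assert abs(swapped.cd - s.cb) < 1e-8


class TestInvertExact:
    def test_identity(self):
        st_, agg = invert_exact(np.eye(2, dtype=complex))
        assert q_modulus(st_) == pytest.approx(0.0, abs=1e-12)

    def test_pure_linear_dichroism(self):
        _, agg = invert_exact(jones_forward(AnisotropyState(ld_0_90=0.3)))
        assert agg.ld == pytest.approx(0.3, abs=1e-10)
        for v in (agg.lb, agg.cb, agg.cd):
            assert v == pytest.approx(0.0, abs=1e-10)

    def test_round_trip_1000_states(self):
        rng = np.random.default_rng(9)
        worst = 0.0
        for _ in range(1000):
            direction = rng.normal(size=6)
            direction /= np.linalg.norm(direction)
            vals = direction * rng.uniform(0.0, 6.0)
            s = AnisotropyState(*vals)
            st_, _ = invert_exact(jones_forward(s))
            err = max(abs(float(np.asarray(getattr(st_, f))) - v) for f, v in zip(FIELDS, vals))
            worst = max(worst, err)
        assert worst < 1e-8

    def test_branch_point_rejected(self):
        with pytest.raises(SingularBranchError):
            invert_exact(jones_forward(AnisotropyState(cb=2 * np.pi)))


class TestStackProduct:
    def test_single_layer_unchanged(self):
        field = jones_forward(AnisotropyState(lb_0_90=np.full((4, 4), 0.3)))
        np.testing.assert_array_equal(stack_product([field]), field)

    def test_rotations_compose_additively(self):
        t1, t2 = 0.4, 0.9
        a = jones_forward(AnisotropyState(cb=np.full((3, 3), t1)))
        b = jones_forward(AnisotropyState(cb=np.full((3, 3), t2)))
        both = jones_forward(AnisotropyState(cb=np.full((3, 3), t1 + t2)))
        np.testing.assert_allclose(stack_product([a, b]), both, atol=1e-12)

    def test_layer_and_inverse_give_identity(self):
        field = jones_forward(AnisotropyState(lb_0_90=np.full((3, 3), 0.5), cb=np.full((3, 3), 0.2)))
        inv = np.linalg.inv(field)
        np.testing.assert_allclose(stack_product([field, inv]), np.broadcast_to(np.eye(2), (3, 3, 2, 2)), atol=1e-12)

    def test_grid_mismatch(self):
        a = np.broadcast_to(np.eye(2, dtype=complex), (3, 3, 2, 2))
        b = np.broadcast_to(np.eye(2, dtype=complex), (4, 4, 2, 2))
        with pytest.raises(ValueError):
            stack_product([a, b])
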