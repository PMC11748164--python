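"""Branching plane, projectors and composite gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import seamtube as st
from seamtube.projection import (
    CouplingUnavailableError,
    StationaryGapError,
    branching_plane,
    gp_gradient,
    seam_projector,
    tube_gradient,
    tube_projector,
)

from conftest import fixture_suite, start_point


def _plane_at(model, x):
    return branching_plane(st.evaluate(model, x))


def test_branching_plane_linear_model(cone):
    bp = _plane_at(cone, [1.0, 0.0])
    np.testing.assert_allclose(bp.g, [2.0, 0.0], atol=1e-14)
    np.testing.assert_allclose(np.abs(bp.u), [1.0, 0.0], atol=1e-14)
    np.testing.assert_allclose(np.abs(bp.v), [0.0, 1.0], atol=1e-14)


def test_branching_plane_degrades_without_coupling(linear_fix):
    """V12 = 0 gives h = 0: the plane collapses to the single direction u."""
    bp = _plane_at(linear_fix, [0.5, 0.3, -0.2])
    assert bp.v is None
    assert np.linalg.norm(bp.u) == pytest.approx(1.0, abs=1e-12)


def test_branching_plane_orthonormal_and_spans(fixture1):
    model, spec = fixture1
    rng = np.random.default_rng(3)
    for _ in range(5):
        x = spec.meci_point + rng.uniform(-1, 1, 3)
        bp = _plane_at(model, x)
        assert bp.u @ bp.u == pytest.approx(1.0, abs=1e-12)
        assert bp.v @ bp.v == pytest.approx(1.0, abs=1e-12)
        assert abs(bp.u @ bp.v) < 1e-12
        basis = np.column_stack([bp.u, bp.v])
        for w in (bp.g, bp.h):
            resid = w - basis @ (basis.T @ w)
            assert np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(w), 1.0)


def test_branching_plane_errors_on_stationary_gap(avoided):
    """At the avoided-crossing minimum the gap is stationary: g ~ 0."""
    x = np.zeros(3)  # x1 = 0 -> d(gap) = 0 for this fixture
    with pytest.raises(StationaryGapError):
        _plane_at(avoided, x)


def test_seam_projector_example_and_invariants(fixture1):
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    bp = st.BranchingPlane(g=2 * u, h=v, u=u, v=v)
    p = seam_projector(bp)
    np.testing.assert_allclose(p.matrix, np.diag([0.0, 0.0, 1.0]), atol=1e-14)
    assert p.removed_rank == 2
    assert np.trace(p.matrix) == pytest.approx(1.0, abs=1e-10)  # N - 2


@pytest.mark.parametrize("seed,model,spec", fixture_suite(10))
def test_projectors_annihilate_g_and_h(seed, model, spec):
    x = start_point(spec, 50 + seed)
    ev = st.evaluate(model, x)
    bp = branching_plane(ev)
    ps = seam_projector(bp)
    pt = tube_projector(bp.g)
    gn = np.linalg.norm(bp.g)
    assert np.linalg.norm(ps @ bp.g) < 1e-10 * gn
    assert np.linalg.norm(ps @ bp.h) < 1e-10 * max(np.linalg.norm(bp.h), gn)
    assert np.linalg.norm(pt @ bp.g) < 1e-10 * gn
    n = spec.dimension
    for p, removed in ((ps, 2), (pt, 1)):
        np.testing.assert_allclose(p.matrix @ p.matrix, p.matrix, atol=1e-10)
        np.testing.assert_allclose(p.matrix, p.matrix.T, atol=1e-12)
        assert np.trace(p.matrix) == pytest.approx(n - removed, abs=1e-10)


def test_tube_projector_example():
    p = tube_projector(np.array([2.0, 0.0, 0.0]))
    np.testing.assert_allclose(p.matrix, np.diag([0.0, 1.0, 1.0]), atol=1e-14)
    assert p.removed_rank == 1
    assert np.trace(p.matrix) == pytest.approx(2.0, abs=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(w=hst.lists(hst.floats(-10, 10, allow_nan=False), min_size=4, max_size=4))
def test_tube_projection_is_orthogonal_to_g(w):
    rng = np.random.default_rng(9)
    g = rng.standard_normal(4)
    p = tube_projector(g)
    w = np.asarray(w)
    assert abs((p @ w) @ g) <= 1e-12 * max(np.linalg.norm(w) * np.linalg.norm(g), 1.0)


def test_gp_gradient_requires_coupling(linear_fix):
    ev = st.evaluate(linear_fix, [0.5, 0.0, 0.0])
    ev_nocoup = st.SurfaceEvaluation(
        point=ev.point,
        E_lower=ev.E_lower,
        E_upper=ev.E_upper,
        grad_lower=ev.grad_lower,
        grad_upper=ev.grad_upper,
        eigvec_lower=None,
        eigvec_upper=None,
        coupling_h=None,
    )
    with pytest.raises(CouplingUnavailableError, match="tube"):
        gp_gradient(ev_nocoup)


def test_gp_gradient_vanishes_at_meci(fixture1):
    """Approaching the analytic MECI along the seam-adjacent direction the
    gradient-projection composite goes to zero."""
    model, spec = fixture1
    x = spec.meci_point + np.array([0.0, 1e-10, 0.0])
    G = gp_gradient(st.evaluate(model, x))
    assert G.norm <= 1e-8


def test_gp_gradient_terms_orthogonal(fixture1):
    model, spec = fixture1
    rng = np.random.default_rng(4)
    for _ in range(5):
        x = spec.meci_point + rng.uniform(-1, 1, 3)
        G = gp_gradient(st.evaluate(model, x))
        assert abs(G.gap_term @ G.seam_term) < 1e-10
        np.testing.assert_allclose(
            G.vector, G.gap_term + G.seam_term, atol=1e-15
        )


def test_tube_gradient_zero_on_isotropic_isosurface(cone):
    """Isotropic cone: E_upper = r, so every point of the gap = eps circle
    is an eps-MECI and the tube composite vanishes on the whole circle."""
    eps = 0.2
    for theta in np.linspace(0, 2 * np.pi, 7):
        x = 0.1 * np.array([np.cos(theta), np.sin(theta)])
        G = tube_gradient(st.evaluate(cone, x), eps)
        assert G.norm <= 1e-12


def test_tube_gradient_zero_at_analytic_eps_meci(fixture1):
    model, spec = fixture1
    eps = 0.2
    x = spec.meci_point.copy()
    x[1] = 0.5 * eps / spec.beta  # on the gap = eps ellipse, at the seam center
    G = tube_gradient(st.evaluate(model, x), eps)
    assert abs(st.evaluate(model, x).gap - eps) < 1e-12
    assert G.norm <= 1e-8


def test_tube_gradient_gap_term_dominates_far_from_seam(fixture1):
    """gap >> eps: the constraint-restoring term dominates and a small step
    along -G reduces the gap."""
    model, spec = fixture1
    eps = 0.01
    x = spec.meci_point + np.array([2.0, 2.0, 0.5])
    ev = st.evaluate(model, x)
    assert ev.gap > 50 * eps
    G = tube_gradient(ev, eps)
    assert np.linalg.norm(G.gap_term) > 3 * np.linalg.norm(G.seam_term)
    eta = 1e-3
    ev2 = st.evaluate(model, x - eta * G.vector / G.norm)
    assert ev2.gap < ev.gap


def test_tube_and_seam_terms_differ_along_h(fixture1):
    """Near the seam, P_tube and P_seam differ by the single extra removed
    direction, so the difference of their projected gradients lies along h."""
    model, spec = fixture1
    x = spec.meci_point + np.array([0.0, 1e-8, 0.0])
    ev = st.evaluate(model, x)
    bp = branching_plane(ev)
    diff = tube_projector(bp.g) @ ev.grad_upper - seam_projector(bp) @ ev.grad_upper
    hhat = ev.coupling_h / np.linalg.norm(ev.coupling_h)
    off_h = diff - (diff @ hhat) * hhat
    assert np.linalg.norm(off_h) <= 1e-10 * max(np.linalg.norm(diff), 1.0)


def test_tube_gradient_rejects_bad_epsilon(cone):
    ev = st.evaluate(cone, [1.0, 0.0])
    with pytest.raises(ValueError):
        tube_gradient(ev, 0.0)
    with pytest.raises(StationaryGapError):
        tube_projector(np.zeros(2))
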