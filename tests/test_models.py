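"""Model surfaces: closed-form eigenproblem, gradients, fixtures, YAML."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import minimize

import seamtube as st
from seamtube.models import (
    DegenerateEvaluationWarning,
    PolyField,
    StencilOrderingWarning,
)

from conftest import fixture_suite


def test_linear_model_closed_form(cone):
    """V11=x1, V22=-x1, V12=x2 at (1,0): eigenvalues -1/+1, g=(2,0), h=(0,1)."""
    ev = st.evaluate(cone, [1.0, 0.0])
    assert ev.E_lower == pytest.approx(-1.0, abs=1e-14)
    assert ev.E_upper == pytest.approx(1.0, abs=1e-14)
    np.testing.assert_allclose(ev.g_vector, [2.0, 0.0], atol=1e-14)
    np.testing.assert_allclose(np.abs(ev.coupling_h), [0.0, 1.0], atol=1e-14)
    # eigenvectors orthonormal
    V = np.column_stack([ev.eigvec_lower, ev.eigvec_upper])
    np.testing.assert_allclose(V.T @ V, np.eye(2), atol=1e-12)


def test_exact_degeneracy_flagged(cone):
    with pytest.warns(DegenerateEvaluationWarning):
        ev = st.evaluate(cone, [0.0, 0.0])
    assert ev.degenerate
    assert ev.coupling_h is None
    assert ev.eigvec_lower is None
    assert ev.E_lower == ev.E_upper == 0.0


@pytest.mark.parametrize("seed", [2, 3, 4])
def test_analytic_gradients_match_finite_differences(seed):
    """Hellmann-Feynman gradients vs central differences, step 1e-5."""
    model, spec = st.conical_fixture(seed, 4)
    rng = np.random.default_rng(seed)
    checked = 0
    while checked < 5:
        x = spec.meci_point + rng.uniform(-2, 2, 4)
        ev = st.evaluate(model, x)
        if ev.gap <= 1e-3:
            continue
        fd = st.finite_difference_eval(model, x, step=1e-5)
        np.testing.assert_allclose(ev.grad_lower, fd.grad_lower, atol=1e-6)
        np.testing.assert_allclose(ev.grad_upper, fd.grad_upper, atol=1e-6)
        checked += 1


def test_finite_difference_linear_model_tight(cone):
    """On an exactly linear surface the central difference is exact to 1e-9."""
    ev = st.evaluate(cone, [1.0, 0.0])
    fd = st.finite_difference_eval(cone, [1.0, 0.0], step=1e-5)
    np.testing.assert_allclose(fd.grad_upper, ev.grad_upper, atol=1e-9)
    np.testing.assert_allclose(fd.grad_lower, ev.grad_lower, atol=1e-9)
    assert fd.coupling_h is None


def test_finite_difference_warns_when_stencil_straddles_seam(cone):
    """Tiny gap + wide stencil: adiabatic ordering may swap inside it."""
    with pytest.warns(StencilOrderingWarning):
        st.finite_difference_eval(cone, [5e-9, 0.0], step=1e-5)


@pytest.mark.parametrize("seed,model,spec", fixture_suite(10))
def test_fixture_meci_matches_brute_force_seam_minimum(seed, model, spec):
    """Independent oracle: numerically minimize E_upper restricted to the
    seam {x1 = x2 = 0}; must agree with the stored analytic MECI to 1e-8."""
    n = spec.dimension

    def seam_energy(t):
        x = np.concatenate([[0.0, 0.0], t])
        lo, up = st.evaluate_batch(model, x[None, :])
        return float(up[0])

    res = minimize(
        seam_energy,
        np.zeros(n - 2),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    np.testing.assert_allclose(res.x, spec.seam_center, atol=1e-8)
    assert abs(res.fun - spec.meci_upper_energy) < 1e-8


def test_fixture_gap_is_linear_cone(fixture1):
    """gap((r/alpha') cos, (r/beta') sin, t0) is exactly linear in r."""
    model, spec = fixture1
    theta = 0.7
    direction = np.array(
        [np.cos(theta) / spec.alpha, np.sin(theta) / spec.beta, 0.0]
    )
    gaps = []
    for r in (1e-1, 1e-2, 1e-3):
        x = spec.meci_point + r * direction
        lo, up = st.evaluate_batch(model, x[None, :])
        gaps.append(float(up[0] - lo[0]) / r)
    np.testing.assert_allclose(gaps, gaps[0], rtol=1e-10)


def test_fixture_coupling_orthogonal_to_g_near_seam(fixture1):
    """g and h span the branching plane: h is orthogonal to ghat at the seam."""
    model, spec = fixture1
    for delta in (1e-4, 1e-6):
        x = spec.meci_point + np.array([0.0, delta, 0.0])
        ev = st.evaluate(model, x)
        ghat = ev.g_vector / np.linalg.norm(ev.g_vector)
        cosang = abs(ev.coupling_h @ ghat) / np.linalg.norm(ev.coupling_h)
        assert cosang < 1e-10


def test_linear_intersection_gap_and_coupling(linear_fix):
    """Glancing case: gap = 2 alpha |x1| and the coupling vanishes."""
    rng = np.random.default_rng(0)
    slopes = []
    for _ in range(5):
        x = rng.uniform(-2, 2, 3)
        ev = st.evaluate(linear_fix, x)
        np.testing.assert_allclose(ev.coupling_h, 0.0, atol=1e-14)
        if abs(x[0]) > 1e-3:
            slopes.append(ev.gap / abs(x[0]))
    np.testing.assert_allclose(slopes, slopes[0], rtol=1e-10)


def test_avoided_crossing_min_gap_on_grid(avoided):
    """Minimum gap over a dense grid equals 2*c0 = 0.3 to grid resolution."""
    axes = [np.linspace(-1, 1, 81)] * 3
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    lo, up = st.evaluate_batch(avoided, pts)
    assert abs((up - lo).min() - 0.3) < 2e-3
    # for eps < 2 c0 there is no isosurface at all
    assert np.all(up - lo >= 0.3 - 1e-12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    x=hst.lists(
        hst.floats(-5, 5, allow_nan=False), min_size=3, max_size=3
    )
)
def test_gap_identity_and_ordering(x):
    """E_upper - E_lower = 2 sqrt(((V11-V22)/2)^2 + V12^2) >= 0 everywhere."""
    model, _ = st.conical_fixture(11, 3)
    x = np.asarray(x)
    v11 = model.v11.value(x)
    v22 = model.v22.value(x)
    v12 = model.v12.value(x)
    expect = 2.0 * np.sqrt((0.5 * (v11 - v22)) ** 2 + v12**2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateEvaluationWarning)
        ev = st.evaluate(model, x)
    assert ev.gap >= 0.0
    assert ev.gap == pytest.approx(expect, rel=1e-12, abs=1e-12)


def test_polyfield_rejects_asymmetric_quadratic():
    with pytest.raises(ValueError, match="symmetric"):
        PolyField(0.0, np.zeros(2), np.array([[0.0, 1.0], [0.0, 0.0]]))


def test_yaml_roundtrip_and_validation(tmp_path, fixture1):
    model, _ = fixture1
    path = tmp_path / "model.yaml"
    st.model_to_yaml(model, path)
    back = st.model_from_yaml(path)
    assert back.dimension == model.dimension
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = rng.uniform(-2, 2, 3)
        for name in ("v11", "v22", "v12"):
            a = getattr(model, name).value(x)
            b = getattr(back, name).value(x)
            assert a == pytest.approx(b, rel=1e-12, abs=1e-12)
    # unknown keys rejected with names listed
    bad = tmp_path / "bad.yaml"
    bad.write_text("dimension: 2\nv99: {constant: 1.0}\n")
    with pytest.raises(ValueError, match="v99"):
        st.model_from_yaml(bad)
    # unspecified blocks default to zero
    minimal = tmp_path / "minimal.yaml"
    minimal.write_text("dimension: 2\nv12: {linear: [0.0, 1.0]}\n")
    m = st.model_from_yaml(minimal)
    assert m.v11.value(np.ones(2)) == 0.0
    assert m.v12.value(np.array([0.0, 2.0])) == 2.0
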