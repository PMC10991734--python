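"""Strain estimator: affine exactness, objectivity, principal strains, ROI medians."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osseodic.exceptions import EmptyROIError, StrainWindowError
from osseodic.geometry import SpecimenGeometry
from osseodic.strain import (
    DisplacementGrid,
    ROIMask,
    classify_strain,
    compute_strain,
    default_rois,
    principal_strains,
    roi_median,
)


def _grid(nr=20, nc=20, spacing=1.0):
    z, x = np.meshgrid(np.arange(nr) * spacing, np.arange(nc) * spacing, indexing="ij")
    pos = np.stack([x, z], axis=-1)
    return pos, spacing


def _affine_grid(A, b=(0.0, 0.0), nr=20, nc=20, spacing=1.0):
    """Displacement u = A @ [x, z] + b on a regular grid."""
    pos, h = _grid(nr, nc, spacing)
    disp = pos @ np.asarray(A).T + np.asarray(b)
    return DisplacementGrid(inplane_mm=pos, disp_mm=disp, spacing_mm=h)


def test_uniform_translation_has_zero_strain():
    g = _affine_grid(np.zeros((2, 2)), b=(0.5, -0.3))
    f = compute_strain(g, window=7)
    for comp in (f.e_xx, f.e_zz, f.e_xz):
        np.testing.assert_allclose(comp[f.valid & ~f.edge], 0.0, atol=1e-15)


def test_uniaxial_stretch_along_cc():
    g = _affine_grid([[0.0, 0.0], [0.0, 1000e-6]])  # e_zz = 1000 microstrain
    f = compute_strain(g, window=7)
    interior = f.valid & ~f.edge
    np.testing.assert_allclose(f.e_zz[interior] * 1e6, 1000.0, atol=1e-9)
    np.testing.assert_allclose(f.e_xx[interior], 0.0, atol=1e-15)
    np.testing.assert_allclose(f.e_xz[interior], 0.0, atol=1e-15)


@pytest.mark.parametrize("window", [3, 5, 7, 9])
@settings(max_examples=15, derandomize=True)
@given(seed=st.integers(0, 5000))
def test_affine_field_reproduced_exactly_any_window(window, seed):
    """Affine exactness: the plane fit returns the analytic gradient to 1e-9."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(-2e-3, 2e-3, (2, 2))
    g = _affine_grid(A, b=rng.uniform(-1, 1, 2), spacing=1.19)
    f = compute_strain(g, window=window)
    interior = f.valid & ~f.edge
    np.testing.assert_allclose(f.e_xx[interior], A[0, 0], atol=1e-9)
    np.testing.assert_allclose(f.e_zz[interior], A[1, 1], atol=1e-9)
    np.testing.assert_allclose(f.e_xz[interior], 0.5 * (A[0, 1] + A[1, 0]), atol=1e-9)


@pytest.mark.parametrize("window", [2, 1, 4])
def test_invalid_window_rejected(window):
    g = _affine_grid(np.zeros((2, 2)))
    with pytest.raises(StrainWindowError):
        compute_strain(g, window=window)


def test_superposition_of_displacement_fields(rng):
    """The estimator is linear: strain(u+v) = strain(u) + strain(v)."""
    pos, h = _grid()
    u = rng.normal(0, 1e-3, pos.shape)
    v = rng.normal(0, 1e-3, pos.shape)
    f_u = compute_strain(DisplacementGrid(pos, u, h), 5)
    f_v = compute_strain(DisplacementGrid(pos, v, h), 5)
    f_uv = compute_strain(DisplacementGrid(pos, u + v, h), 5)
    np.testing.assert_allclose(f_uv.e_xx, f_u.e_xx + f_v.e_xx, atol=1e-9)
    np.testing.assert_allclose(f_uv.e_xz, f_u.e_xz + f_v.e_xz, atol=1e-9)


def test_frame_objectivity_of_principal_strains(rng):
    """Rotating the material frame leaves e1, e2 unchanged within 1e-9."""
    A = rng.uniform(-2e-3, 2e-3, (2, 2))
    A = 0.5 * (A + A.T)
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    f1 = principal_strains(compute_strain(_affine_grid(A), 5))
    f2 = principal_strains(compute_strain(_affine_grid(R @ A @ R.T), 5))
    m = f1.valid & ~f1.edge
    np.testing.assert_allclose(f1.e1_micro[m], f2.e1_micro[m], atol=1e-9)
    np.testing.assert_allclose(f1.e2_micro[m], f2.e2_micro[m], atol=1e-9)


# ---------------------------------------------------------------------------
# principal strains
# ---------------------------------------------------------------------------

def test_pure_shear_principal_strains():
    T = np.array([[0.0, 200e-6], [200e-6, 0.0]])  # engineering shear 400 microstrain
    f = principal_strains(T[None, ...])
    np.testing.assert_allclose(f.e1_micro, 200.0, atol=1e-9)
    np.testing.assert_allclose(f.e2_micro, -200.0, atol=1e-9)


def test_isotropic_strain():
    T = 300e-6 * np.eye(2)
    f = principal_strains(T[None, ...])
    np.testing.assert_allclose(f.e1_micro, 300.0, atol=1e-9)
    np.testing.assert_allclose(f.e2_micro, 300.0, atol=1e-9)


def test_principal_strains_match_eigendecomposition_oracle(rng):
    T = rng.normal(0, 1e-3, (50, 2, 2))
    T = 0.5 * (T + np.swapaxes(T, -1, -2))
    f = principal_strains(T)
    w = np.linalg.eigvalsh(T) * 1e6  # ascending
    np.testing.assert_allclose(f.e1_micro, w[:, 1], atol=1e-9)
    np.testing.assert_allclose(f.e2_micro, w[:, 0], atol=1e-9)
    assert np.all(f.e1_micro >= f.e2_micro - 1e-12)
    # principal directions are orthogonal by construction (angle parameterisation)


def test_asymmetric_tensor_rejected():
    T = np.array([[1e-3, 1e-4], [2e-4, 1e-3]])
    with pytest.raises(StrainWindowError):
        principal_strains(T[None, ...])


# ---------------------------------------------------------------------------
# ROI medians and classification
# ---------------------------------------------------------------------------

def _constant_field(value_micro, nr=20, nc=20, spacing=2.0):
    g = _affine_grid([[0.0, 0.0], [0.0, value_micro * 1e-6]], nr=nr, nc=nc, spacing=spacing)
    return principal_strains(compute_strain(g, 5)), g


def test_constant_field_roi_median():
    field, g = _constant_field(500.0)
    roi = ROIMask("ROI", (0.0, 100.0))
    s = roi_median(field, roi, g.cc_mm)
    assert s.median_e1_micro == pytest.approx(500.0, abs=1e-6)
    assert s.n_nodes > 0


def test_roi_median_robust_to_outlier_nodes(rng):
    """10 percent of nodes corrupted 10x move the ROI median < 5 percent."""
    field, g = _constant_field(500.0)
    dirty = field.e1_micro.copy()
    m = field.valid & ~field.edge
    idx = np.flatnonzero(m.ravel())
    bad = rng.choice(idx, size=int(0.1 * len(idx)), replace=False)
    dirty.ravel()[bad] *= 10.0
    field.e1_micro = dirty
    s = roi_median(field, ROIMask("ROI", (0.0, 100.0)), g.cc_mm)
    assert abs(s.median_e1_micro - 500.0) / 500.0 < 0.05


def test_empty_roi_rejected():
    field, g = _constant_field(500.0)
    with pytest.raises(EmptyROIError):
        roi_median(field, ROIMask("far", (1000.0, 1020.0)), g.cc_mm)


def test_default_rois_follow_geometry():
    geo = SpecimenGeometry.default(grid_shape=(20, 20))
    roi1, roi2 = default_rois(geo)
    assert roi1.cc_interval_mm == (40.0, 60.0)
    assert roi2.cc_interval_mm == (0.0, 20.0)


@pytest.mark.parametrize(
    "e1, e2, expected",
    [
        (1604.0, -730.0, "physiological"),
        (8000.0, -2000.0, "fracture-risk"),
        (0.0, 0.0, "below-physiological"),
        (550.0, -360.0, "below-physiological"),
        (2500.0, -900.0, "hyper-physiological"),
    ],
)
def test_strain_classification(e1, e2, expected):
    from osseodic.strain import ROISummary

    assert classify_strain(ROISummary("R", e1, e2, 10)) == expected


def test_edge_nodes_flagged():
    g = _affine_grid(np.zeros((2, 2)), nr=15, nc=15)
    f = compute_strain(g, window=7)
    assert f.edge[0, 0] and f.edge[2, 7] and f.edge[7, -1]
    assert not f.edge[7, 7]


def test_invalid_nodes_mask_their_neighbourhood():
    pos, h = _grid(15, 15)
    disp = np.zeros_like(pos)
    disp[7, 7] = np.nan
    g = DisplacementGrid(pos, disp, h)
    f = compute_strain(g, window=5)
    assert not f.valid[7, 7]
    assert not f.valid[6, 6]   # window touches the invalid node
    assert f.valid[3, 3] and f.valid[11, 11]  # distant nodes unaffected
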