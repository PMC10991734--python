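"""Full-field surface strain: tensor estimation, principal strains, ROI medians.

The strain estimator is a local least-squares plane fit: within a square
window of speckle nodes centred on each node, each in-plane displacement
component is fitted with an affine function of the in-plane coordinates and
the infinitesimal strain tensor is assembled from the fitted gradients.  On a
regular grid with an odd window this reduces to separable convolutions, is
exact for affine displacement fields regardless of window size, and is linear
in the displacements (so strain superposes).

Finite-strain correction: for displacement gradient H the Green-Lagrange
tensor is ``E = (H + H^T + H^T H)/2``; at the magnitudes measured here
(<= 1e4 microstrain) the quadratic term is below 1 percent of the linear one,
so the infinitesimal tensor ``(H + H^T)/2`` is used throughout.

Nodes whose fit window reaches the border of the correlated region are
flagged as edge nodes and excluded from ROI statistics, mirroring the larger
error of DIC strains at the edges of the correlated region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import EmptyROIError, StrainWindowError
from .geometry import SpecimenGeometry

#: strain classification cut-offs, microstrain
PHYSIOLOGICAL_LOW_MICRO = 1000.0
PHYSIOLOGICAL_PEAK_MICRO = 2000.0
FAILURE_MICRO = 7000.0


@dataclass
class DisplacementGrid:
    """In-plane displacements of the speckle grid relative to the reference frame."""

    inplane_mm: np.ndarray        # (rows, cols, 2) node positions, (x, z), z along CC
    disp_mm: np.ndarray           # (rows, cols, 2) in-plane displacement
    spacing_mm: float
    valid: np.ndarray = None      # (rows, cols) bool
    cc_mm: np.ndarray = None      # (rows, cols) CC coordinate, for ROI membership

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.disp_mm).all(axis=-1)
        if self.cc_mm is None:
            self.cc_mm = self.inplane_mm[..., 1]
        if self.spacing_mm <= 0:
            raise StrainWindowError("grid spacing must be positive")

    @classmethod
    def from_sequence(cls, seq, frame: int, reference: int = 0) -> "DisplacementGrid":
        """Displacement field of ``frame`` relative to ``reference`` of a sequence."""
        bg = seq.geometry.bone_grid
        basis = bg.basis
        pos = (seq.grid_xyz_mm[reference] @ basis).reshape(*bg.shape, 2)
        disp = ((seq.grid_xyz_mm[frame] - seq.grid_xyz_mm[reference]) @ basis).reshape(
            *bg.shape, 2
        )
        cc = seq.grid_xyz_mm[reference][:, 2].reshape(bg.shape)
        return cls(inplane_mm=pos, disp_mm=disp, spacing_mm=bg.spacing_mm, cc_mm=cc)


@dataclass
class StrainTensorField:
    """Per-node in-plane infinitesimal strain tensor (dimensionless)."""

    e_xx: np.ndarray
    e_zz: np.ndarray
    e_xz: np.ndarray
    valid: np.ndarray
    edge: np.ndarray

    def tensors(self) -> np.ndarray:
        """Stack into (..., 2, 2) symmetric tensors."""
        return np.stack(
            [
                np.stack([self.e_xx, self.e_xz], axis=-1),
                np.stack([self.e_xz, self.e_zz], axis=-1),
            ],
            axis=-2,
        )


@dataclass
class PrincipalStrainField:
    """Maximum and minimum principal strains (microstrain) with directions."""

    e1_micro: np.ndarray
    e2_micro: np.ndarray
    theta1_rad: np.ndarray        # angle of the e1 direction from the x axis
    valid: np.ndarray
    edge: np.ndarray

    def interior_values(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.valid & ~self.edge
        return self.e1_micro[m], self.e2_micro[m]


@dataclass(frozen=True)
class ROIMask:
    """Region of interest as a half-open CC interval ``[lower, upper)``."""

    name: str
    cc_interval_mm: tuple[float, float]

    def membership(self, cc_mm: np.ndarray) -> np.ndarray:
        lo, hi = self.cc_interval_mm
        return (cc_mm >= lo) & (cc_mm < hi)


@dataclass(frozen=True)
class ROISummary:
    name: str
    median_e1_micro: float
    median_e2_micro: float
    n_nodes: int


def default_rois(geometry: SpecimenGeometry) -> tuple[ROIMask, ROIMask]:
    """The two reporting regions: stem-tip band and supra-osteotomy band.

    ROI 1 covers 10 mm proximal to 10 mm distal of the stem tip; ROI 2 the
    20 mm of femur immediately proximal to the osteotomy.
    """
    tip, ost = geometry.stem_tip_level_mm, geometry.osteotomy_level_mm
    return (
        ROIMask("ROI1", (tip - 10.0, tip + 10.0)),
        ROIMask("ROI2", (ost, ost + 20.0)),
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _slope_kernels(window: int, spacing: float):
    half = window // 2
    off = np.arange(-half, half + 1, dtype=float)
    w_slope = off / (spacing * np.sum(off**2))
    w_mean = np.full(window, 1.0 / window)
    return w_slope, w_mean


def compute_strain(grid: DisplacementGrid, window: int = 7) -> StrainTensorField:
    """Least-squares plane-fit strain over a ``window x window`` node patch.

    ``window`` must be odd and >= 3.  Nodes whose window contains any invalid
    node are masked; nodes whose window extends past the grid border are
    flagged as edge nodes.
    """
    if window < 3 or window % 2 == 0:
        raise StrainWindowError(f"window must be an odd integer >= 3, got {window}")
    nr, nc = grid.disp_mm.shape[:2]
    if min(nr, nc) < window:
        raise StrainWindowError(
            f"grid of shape {(nr, nc)} is smaller than the {window}x{window} window"
        )
    w_slope, w_mean = _slope_kernels(window, grid.spacing_mm)

    def gradient(u, axis_slope):
        # separable least-squares plane fit: slope kernel along one axis,
        # averaging kernel along the other
        out = ndimage.correlate1d(u, w_slope, axis=axis_slope, mode="nearest")
        return ndimage.correlate1d(out, w_mean, axis=1 - axis_slope, mode="nearest")

    u_x, u_z = np.ascontiguousarray(grid.disp_mm[..., 0]), np.ascontiguousarray(
        grid.disp_mm[..., 1]
    )
    u_x = np.where(grid.valid, u_x, 0.0)
    u_z = np.where(grid.valid, u_z, 0.0)
    # axes: 0 = rows = z (CC), 1 = cols = x
    dux_dx = gradient(u_x, 1)
    dux_dz = gradient(u_x, 0)
    duz_dx = gradient(u_z, 1)
    duz_dz = gradient(u_z, 0)

    full_window = ndimage.uniform_filter(
        grid.valid.astype(float), size=window, mode="constant"
    ) > 1.0 - 0.5 / window**2
    half = window // 2
    edge = np.zeros((nr, nc), dtype=bool)
    edge[:half, :] = edge[-half:, :] = True
    edge[:, :half] = edge[:, -half:] = True
    edge |= ~full_window

    return StrainTensorField(
        e_xx=dux_dx,
        e_zz=duz_dz,
        e_xz=0.5 * (dux_dz + duz_dx),
        valid=grid.valid & full_window,
        edge=edge,
    )


def principal_strains(tensor_field) -> PrincipalStrainField:
    """Closed-form eigendecomposition of the 2x2 in-plane strain tensors.

    Accepts a :class:`StrainTensorField` or an array of shape ``(..., 2, 2)``
    (which must be symmetric within 1e-9).  Returns principal strains in
    microstrain, sorted ``e1 >= e2``, with the e1 direction angle; the result
    is invariant under in-plane rotation of the coordinate frame.
    """
    if isinstance(tensor_field, StrainTensorField):
        e_xx, e_zz, e_xz = tensor_field.e_xx, tensor_field.e_zz, tensor_field.e_xz
        valid, edge = tensor_field.valid, tensor_field.edge
    else:
        T = np.asarray(tensor_field, dtype=float)
        if T.shape[-2:] != (2, 2):
            raise StrainWindowError("expected tensors of shape (..., 2, 2)")
        if np.max(np.abs(T[..., 0, 1] - T[..., 1, 0])) > 1e-9:
            raise StrainWindowError("strain tensors must be symmetric within 1e-9")
        e_xx, e_zz, e_xz = T[..., 0, 0], T[..., 1, 1], T[..., 0, 1]
        valid = np.ones(e_xx.shape, dtype=bool)
        edge = np.zeros(e_xx.shape, dtype=bool)
    m = 0.5 * (e_xx + e_zz)
    d = 0.5 * (e_xx - e_zz)
    r = np.hypot(d, e_xz)
    theta = 0.5 * np.arctan2(2.0 * e_xz, e_xx - e_zz)
    return PrincipalStrainField(
        e1_micro=(m + r) * 1e6,
        e2_micro=(m - r) * 1e6,
        theta1_rad=theta,
        valid=valid,
        edge=edge,
    )


def roi_median(field: PrincipalStrainField, roi: ROIMask, cc_mm: np.ndarray) -> ROISummary:
    """Median principal strains over the valid, non-edge nodes of a ROI."""
    m = roi.membership(cc_mm) & field.valid & ~field.edge
    if not m.any():
        raise EmptyROIError(f"ROI {roi.name} contains no valid node")
    return ROISummary(
        name=roi.name,
        median_e1_micro=float(np.median(field.e1_micro[m])),
        median_e2_micro=float(np.median(field.e2_micro[m])),
        n_nodes=int(m.sum()),
    )


def classify_strain(
    summary: ROISummary,
    low_micro: float = PHYSIOLOGICAL_LOW_MICRO,
    physiological_micro: float = PHYSIOLOGICAL_PEAK_MICRO,
    failure_micro: float = FAILURE_MICRO,
) -> str:
    """Classify the dominant ROI strain magnitude against bone-biology cut-offs.

    ``below-physiological`` < ``low`` <= ``physiological`` < 2000 microstrain
    <= ``hyper-physiological`` < 7000 microstrain <= ``fracture-risk``.
    The physiological peak (2000) and failure (7000) cut-offs are the accepted
    cortical-bone levels; the lower bound separating habitual from
    below-habitual loading is a configurable convention (default 1000).
    """
    mag = max(abs(summary.median_e1_micro), abs(summary.median_e2_micro))
    if mag >= failure_micro:
        return "fracture-risk"
    if mag >= physiological_micro:
        return "hyper-physiological"
    if mag >= low_micro:
        return "physiological"
    return "below-physiological"


def analyze_strain(
    seq,
    window: int = 7,
    rois: tuple[ROIMask, ...] | None = None,
    peak_frame: int | None = None,
    reference_frame: int = 0,
):
    """Strain analysis of a tracked sequence at peak load.

    The displacement field at the (first) maximal-load frame relative to the
    fully unloaded reference is differentiated into the principal strain
    field; ROI medians are reported for the default (or given) ROIs.
    Returns ``(PrincipalStrainField, {name: ROISummary})``.
    """
    if peak_frame is None:
        peak_frame = int(np.argmax(seq.loads_n))
    grid = DisplacementGrid.from_sequence(seq, peak_frame, reference_frame)
    field = principal_strains(compute_strain(grid, window=window))
    if rois is None:
        rois = default_rois(seq.geometry)
    summaries = {roi.name: roi_median(field, roi, grid.cc_mm) for roi in rois}
    return field, summaries
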