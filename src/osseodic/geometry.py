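"""Virtual specimen geometry: anatomical frame, marker set, bone speckle grid.

Conventions (fixed throughout the package):

* Right-handed anatomical frame with axes medio-lateral (ML), antero-posterior
  (AP) and cranio-caudal (CC); CC points proximally and ``ML x AP = CC``.
  Lab coordinates are millimetres; by default the anatomical frame coincides
  with the lab frame (ML = x, AP = y, CC = z).
* The osteotomy plane sits at CC = ``osteotomy_level_mm``; the residual femur
  occupies CC above it, the prosthesis (and its marker set) protrudes below.
* The DIC-visible bone face is represented as a planar speckle patch,
  parameterised by an in-plane (ML, CC) node grid stored row-major
  (rows = CC, columns = ML).  A developed plane is sufficient because the
  strain estimator operates in the surface tangent plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGeometryError, NonOrthonormalFrameError

#: component labels of every 6-DOF output, in reporting order
DOF_LABELS = ("t_ML", "t_CC", "t_AP", "r_ML", "r_CC", "r_AP")


def check_anatomical_frame(frame: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate a 3x3 matrix whose columns are the ML, AP, CC unit vectors."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (3, 3):
        raise NonOrthonormalFrameError(f"anatomical frame must be 3x3, got {frame.shape}")
    g = frame.T @ frame
    if not np.allclose(g, np.eye(3), atol=tol):
        raise NonOrthonormalFrameError("anatomical axes are not orthonormal")
    if np.linalg.det(frame) < 0:
        raise NonOrthonormalFrameError("anatomical frame must be right-handed (ML x AP = CC)")
    return frame


def check_markers(marker_xyz: np.ndarray, min_points: int = 4) -> np.ndarray:
    """Require at least ``min_points`` non-collinear marker positions."""
    pts = np.asarray(marker_xyz, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < min_points:
        raise DegenerateGeometryError(
            f"need >= {min_points} 3D markers, got array of shape {pts.shape}"
        )
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("marker set is collinear")
    return pts


def cylinder_markers(
    n_markers: int = 25,
    radius_mm: float = 25.0,
    length_mm: float = 60.0,
    center_cc_mm: float = -40.0,
) -> np.ndarray:
    """Fiducial markers on a cylinder around the CC axis (prosthesis extension).

    The default layout (25 markers, radius 25 mm, length 60 mm, centred 40 mm
    distal to the osteotomy) stands in for the ring of passive markers glued to
    the distal prosthesis; the number and placement of markers are declared
    defaults, not measured values.
    """
    n_rings = max(2, int(round(np.sqrt(n_markers))))
    per_ring = int(np.ceil(n_markers / n_rings))
    zs = np.linspace(center_cc_mm - length_mm / 2, center_cc_mm + length_mm / 2, n_rings)
    pts = []
    for i, z in enumerate(zs):
        # stagger rings so markers are not axially aligned
        phis = 2 * np.pi * (np.arange(per_ring) + 0.5 * (i % 2)) / per_ring
        for phi in phis:
            pts.append((radius_mm * np.cos(phi), radius_mm * np.sin(phi), z))
    return np.asarray(pts[:n_markers])


@dataclass(frozen=True)
class BoneGrid:
    """Planar speckle-node grid on the DIC-visible bone face."""

    xyz_mm: np.ndarray          # (n_nodes, 3), row-major over (rows=CC, cols=ML)
    shape: tuple[int, int]      # (n_rows, n_cols)
    spacing_mm: float
    #: in-plane tangent basis, columns = (ML-like, CC-like) unit vectors
    basis: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.0],
                                                                [0.0, 0.0],
                                                                [0.0, 1.0]]))

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def inplane_mm(self) -> np.ndarray:
        """Node positions projected on the tangent basis, shape (rows, cols, 2)."""
        uv = self.xyz_mm @ self.basis
        return uv.reshape(*self.shape, 2)

    def cc_mm(self) -> np.ndarray:
        """CC coordinate of every node, shape (rows, cols)."""
        return self.xyz_mm[:, 2].reshape(self.shape)


def planar_bone_grid(
    spacing_mm: float = 1.19,
    cc_range_mm: tuple[float, float] = (0.0, 80.0),
    ml_range_mm: tuple[float, float] = (-20.0, 20.0),
    ap_offset_mm: float = 15.0,
) -> BoneGrid:
    """Regular speckle grid on the anterior bone face.

    The default spacing, 1.19 mm, is the facet grid spacing of 17 pixels at the
    0.07 mm pixel size of the imaging setup.
    """
    if spacing_mm <= 0:
        raise DegenerateGeometryError("grid spacing must be positive")
    cc = np.arange(cc_range_mm[0], cc_range_mm[1] + 0.5 * spacing_mm, spacing_mm)
    ml = np.arange(ml_range_mm[0], ml_range_mm[1] + 0.5 * spacing_mm, spacing_mm)
    mm, cc2 = np.meshgrid(ml, cc)  # rows = CC, cols = ML
    xyz = np.column_stack([mm.ravel(), np.full(mm.size, ap_offset_mm), cc2.ravel()])
    return BoneGrid(xyz_mm=xyz, shape=(len(cc), len(ml)), spacing_mm=spacing_mm)


def solve_lever_arm(
    load_max_n: float = 850.0,
    flexion_deg: float = 10.0,
    adduction_deg: float = 10.0,
    target_moment_nm: float = 30.0,
) -> float:
    """Lever arm (mm) from load application point to stem tip.

    The rig applies a vertical force to a specimen tilted in flexion and
    adduction; the transverse component of the force times this lever arm is
    the bending moment at the stem tip.  The lever arm is solved from the
    declared peak bending moment (30 Nm at 850 N with a 10 deg + 10 deg tilt)
    because it is a free parameter of the rig, not a printed dimension.
    """
    f, a = np.deg2rad(flexion_deg), np.deg2rad(adduction_deg)
    # vertical load direction expressed in the tilted anatomical frame
    direction = np.array([-np.sin(a), np.sin(f) * np.cos(a), -np.cos(f) * np.cos(a)])
    transverse = load_max_n * np.hypot(direction[0], direction[1])
    if transverse <= 0:
        raise DegenerateGeometryError("tilt angles produce no transverse force component")
    return target_moment_nm / transverse * 1e3


def bending_moment_at_stem_tip(
    load_n: float,
    lever_arm_mm: float,
    flexion_deg: float = 10.0,
    adduction_deg: float = 10.0,
) -> float:
    """Bending moment (Nm) at the stem tip for a vertical load on the tilted specimen."""
    f, a = np.deg2rad(flexion_deg), np.deg2rad(adduction_deg)
    direction = np.array([-np.sin(a), np.sin(f) * np.cos(a), -np.cos(f) * np.cos(a)])
    return load_n * np.hypot(direction[0], direction[1]) * lever_arm_mm * 1e-3


@dataclass(frozen=True)
class SpecimenGeometry:
    """Geometry of one virtual implanted femur."""

    marker_xyz_mm: np.ndarray
    bone_grid: BoneGrid
    anatomical_frame: np.ndarray = field(default_factory=lambda: np.eye(3))
    osteotomy_level_mm: float = 0.0
    stem_tip_level_mm: float = 50.0
    flexion_deg: float = 10.0
    adduction_deg: float = 10.0
    lever_arm_mm: float | None = None

    def __post_init__(self):
        check_markers(self.marker_xyz_mm)
        check_anatomical_frame(self.anatomical_frame)
        if not self.stem_tip_level_mm > self.osteotomy_level_mm:
            raise DegenerateGeometryError(
                "stem tip must be proximal (CC above) to the osteotomy"
            )
        if self.lever_arm_mm is None:
            object.__setattr__(
                self,
                "lever_arm_mm",
                solve_lever_arm(flexion_deg=self.flexion_deg, adduction_deg=self.adduction_deg),
            )

    @classmethod
    def default(
        cls,
        n_markers: int = 25,
        grid_spacing_mm: float = 1.19,
        grid_shape: tuple[int, int] | None = None,
    ) -> "SpecimenGeometry":
        """Default virtual specimen.

        ``grid_shape`` overrides the dense speckle grid with a coarser regular
        grid covering the same bone patch (used e.g. for zero-displacement
        trials, where 400 nodes are representative and cheap).
        """
        if grid_shape is None:
            grid = planar_bone_grid(spacing_mm=grid_spacing_mm)
        else:
            nr, nc = grid_shape
            cc = np.linspace(0.0, 80.0, nr)
            ml = np.linspace(-20.0, 20.0, nc)
            mm, cc2 = np.meshgrid(ml, cc)
            xyz = np.column_stack([mm.ravel(), np.full(mm.size, 15.0), cc2.ravel()])
            grid = BoneGrid(xyz_mm=xyz, shape=(nr, nc), spacing_mm=float(cc[1] - cc[0]))
        return cls(marker_xyz_mm=cylinder_markers(n_markers), bone_grid=grid)

    @property
    def marker_centroid_mm(self) -> np.ndarray:
        return self.marker_xyz_mm.mean(axis=0)
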