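"""Rigid-body kinematics: pose estimation, 6-DOF decomposition, stability metrics.

The prosthesis is tracked through discrete fiducial markers and the host bone
through its speckle grid.  Each body's pose relative to the reference frame is
the least-squares rigid transform (Kabsch/SVD); the implant-vs-bone motion is
the composition ``bone^-1 o prosthesis``, decomposed into three translations
(micrometres) and three rotations (degrees) along the ML/CC/AP anatomical
axes.

Primary-stability metrics follow the peak/valley scheme of the loading
protocol:

* *inducible micromotion*: for every acquired cycle, position at the load peak
  of cycle N+1 minus position at the valley terminating cycle N, summarised by
  the per-component median (robust against outlier cycles);
* *permanent migration*: median position over the last acquisition window's
  peaks minus the median over the first window's peaks.  Using the windowed
  median rather than the single first/last peak keeps the estimate within the
  repeatability of the protocol; the choice is documented in docs/methods.md.

Rotations use the intrinsic Cardan sequence ML -> AP -> CC.  At the
sub-degree magnitudes relevant here the sequence is immaterial (the
decomposition order changes the angles by far less than 1e-4 deg below 1 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import (
    DegenerateGeometryError,
    FrameMismatchError,
    NoCyclesError,
    NonOrthonormalFrameError,
)
from .geometry import DOF_LABELS, check_anatomical_frame
from .protocol import LoadProtocol

MICROMOTION_THRESHOLD_UM = 150.0  # fibrous-tissue-formation threshold


@dataclass(frozen=True)
class RigidPose:
    """Proper rigid transform ``x -> R x + t`` with an optional frame index."""

    rotation: np.ndarray
    translation_mm: np.ndarray
    frame_index: int | None = None
    residual_rms_mm: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise DegenerateGeometryError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise NonOrthonormalFrameError("rotation matrix is not orthogonal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise NonOrthonormalFrameError("rotation matrix must be proper (det = +1)")

    @classmethod
    def identity(cls, frame_index: int | None = None) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3), frame_index)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        return points_mm @ np.asarray(self.rotation).T + np.asarray(self.translation_mm)

    def inverse(self) -> "RigidPose":
        R = np.asarray(self.rotation)
        return RigidPose(R.T, -R.T @ np.asarray(self.translation_mm), self.frame_index)


def estimate_pose(
    reference_mm: np.ndarray,
    current_mm: np.ndarray,
    frame_index: int | None = None,
) -> RigidPose:
    """Least-squares rigid registration of corresponded point sets (Kabsch/SVD).

    Minimises ``sum_i |R p_i + t - q_i|^2`` over proper rigid transforms.
    Rows with non-finite coordinates in either set are dropped; at least three
    non-collinear correspondences must remain.
    """
    P = np.asarray(reference_mm, dtype=float)
    Q = np.asarray(current_mm, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateGeometryError(f"point sets must share shape (n, 3): {P.shape} vs {Q.shape}")
    ok = np.isfinite(P).all(axis=1) & np.isfinite(Q).all(axis=1)
    P, Q = P[ok], Q[ok]
    if len(P) < 3:
        raise DegenerateGeometryError(f"need >= 3 corresponded points, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    s = np.linalg.svd(Pc, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("reference points are collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rms = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    return RigidPose(R, t, frame_index, residual_rms_mm=rms)


def relative_pose(prosthesis: RigidPose, bone: RigidPose) -> RigidPose:
    """Pose of the implant with respect to the host bone: ``bone^-1 o prosthesis``.

    Rigidly co-moving bodies give the identity.  Both poses must refer to the
    same frame index when indices are set.
    """
    if (
        prosthesis.frame_index is not None
        and bone.frame_index is not None
        and prosthesis.frame_index != bone.frame_index
    ):
        raise FrameMismatchError(
            f"poses from different frames: {prosthesis.frame_index} vs {bone.frame_index}"
        )
    Rb = np.asarray(bone.rotation)
    R = Rb.T @ np.asarray(prosthesis.rotation)
    t = Rb.T @ (np.asarray(prosthesis.translation_mm) - np.asarray(bone.translation_mm))
    return RigidPose(R, t, prosthesis.frame_index)


# ---------------------------------------------------------------------------
# 6-DOF decomposition in the anatomical frame
# ---------------------------------------------------------------------------

def decompose(pose: RigidPose, anatomical_frame: np.ndarray | None = None) -> np.ndarray:
    """Decompose a pose into ``(t_ML, t_CC, t_AP, r_ML, r_CC, r_AP)``.

    Translations are the projections of the pose translation on the anatomical
    axes, in micrometres; rotations are intrinsic ML -> AP -> CC Cardan angles
    in degrees.  ``anatomical_frame`` has the ML, AP, CC unit vectors as
    columns (identity by default).
    """
    A = np.eye(3) if anatomical_frame is None else check_anatomical_frame(anatomical_frame)
    t_anat = A.T @ np.asarray(pose.translation_mm)          # (ML, AP, CC), mm
    R_anat = A.T @ np.asarray(pose.rotation) @ A
    ang = Rotation.from_matrix(R_anat).as_euler("XYZ", degrees=True)  # ML, AP, CC
    return np.array([
        t_anat[0] * 1e3, t_anat[2] * 1e3, t_anat[1] * 1e3,
        ang[0], ang[2], ang[1],
    ])


def compose(six: np.ndarray, anatomical_frame: np.ndarray | None = None) -> RigidPose:
    """Inverse of :func:`decompose`: build a pose from a 6-DOF vector (um, deg)."""
    A = np.eye(3) if anatomical_frame is None else check_anatomical_frame(anatomical_frame)
    six = np.asarray(six, dtype=float)
    t_anat = np.array([six[0], six[2], six[1]]) * 1e-3      # mm, (ML, AP, CC)
    ang = np.array([six[3], six[5], six[4]])                # ML, AP, CC
    R_anat = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
    return RigidPose(A @ R_anat @ A.T, A @ t_anat)


# ---------------------------------------------------------------------------
# Cycle events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleEvents:
    """Frame indices of the load peak and valley of each acquired cycle.

    ``peak_frames[k]`` is the frame of the peak of cycle ``k``;
    ``valley_frames[k]`` the frame of the valley terminating cycle ``k``.
    """

    peak_frames: dict[int, int]
    valley_frames: dict[int, int]

    def micromotion_pairs(self) -> list[tuple[int, int, int]]:
        """Acquired ``(cycle N, valley_N frame, peak_{N+1} frame)`` triples."""
        out = []
        for k, v in sorted(self.valley_frames.items()):
            if k + 1 in self.peak_frames:
                out.append((k, v, self.peak_frames[k + 1]))
        return out


def extract_peaks_valleys(
    loads_n: np.ndarray,
    times_s: np.ndarray,
    protocol: LoadProtocol,
    load_tolerance_frac: float = 0.25,
) -> CycleEvents:
    """Locate the load peak and valley frame of each acquired cycle.

    The peak of cycle ``k`` is the frame of maximal load among frames within
    that cycle's period; the valley of cycle ``k`` the minimal-load frame
    within half a period of its analytic valley time.  Ties break to the
    earliest frame (``argmax`` semantics).  Events whose load deviates from
    the protocol extremes by more than ``load_tolerance_frac`` of the load
    range are rejected, so a constant or truncated channel raises
    :class:`NoCyclesError`.
    """
    loads = np.asarray(loads_n, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if loads.shape != times.shape:
        raise FrameMismatchError("load channel length must equal frame count")
    rng = protocol.load_max_n - protocol.load_min_n
    if np.ptp(loads) < 0.5 * rng:
        raise NoCyclesError("load channel shows no loading cycles")
    t0, T = protocol.cycles_start_s, protocol.period_s
    tol = load_tolerance_frac * rng
    peaks: dict[int, int] = {}
    valleys: dict[int, int] = {}
    for k in range(1, protocol.n_cycles + 1):
        in_peak = (times >= t0 + (k - 1) * T) & (times < t0 + k * T)
        if in_peak.any():
            idx = np.flatnonzero(in_peak)
            j = idx[np.argmax(loads[idx])]
            if abs(loads[j] - protocol.load_max_n) <= tol:
                peaks[k] = int(j)
        in_valley = (times >= t0 + (k - 0.5) * T) & (times < t0 + (k + 0.5) * T)
        if in_valley.any():
            idx = np.flatnonzero(in_valley)
            j = idx[np.argmin(loads[idx])]
            if abs(loads[j] - protocol.load_min_n) <= tol:
                valleys[k] = int(j)
    if not peaks or not valleys:
        raise NoCyclesError("no complete loading cycle detected in the load channel")
    return CycleEvents(peak_frames=peaks, valley_frames=valleys)


# ---------------------------------------------------------------------------
# Stability metrics
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Permanent migrations and inducible micromotions, 6 DOF each.

    Translations in micrometres, rotations in degrees, components ordered as
    :data:`osseodic.geometry.DOF_LABELS`.
    """

    permanent_migration: np.ndarray            # (6,)
    inducible_per_cycle: np.ndarray            # (n_cycles_acquired, 6)
    inducible_cycles: np.ndarray               # cycle index of each row
    inducible_median: np.ndarray               # (6,)
    inducible_sd: np.ndarray                   # (6,), sample SD (n-1)
    labels: tuple[str, ...] = field(default=DOF_LABELS)

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "permanent_migration": self.permanent_migration.tolist(),
            "inducible_median": self.inducible_median.tolist(),
            "inducible_sd": self.inducible_sd.tolist(),
            "n_cycles": int(len(self.inducible_per_cycle)),
        }


def permanent_migration(
    peak_six: dict[int, np.ndarray],
    windows: tuple[tuple[int, int], ...],
) -> np.ndarray:
    """Windowed-median permanent migration.

    ``peak_six`` maps cycle index to the decomposed 6-DOF position at that
    cycle's load peak.  The migration is the component-wise median position
    over the last acquisition window minus that over the first.
    """
    if len(windows) < 2:
        raise NoCyclesError("permanent migration needs at least two acquisition windows")

    def window_median(lo: int, hi: int) -> np.ndarray:
        rows = [peak_six[k] for k in range(lo, hi + 1) if k in peak_six]
        if not rows:
            raise NoCyclesError(f"no acquired peaks in window ({lo}, {hi})")
        return np.median(np.asarray(rows), axis=0)

    first = window_median(*min(windows))
    last = window_median(*max(windows))
    return last - first


def inducible_micromotion(
    peak_six: dict[int, np.ndarray],
    valley_six: dict[int, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle Peak_{N+1} - Valley_N micromotions with median and SD summary."""
    rows, cycles = [], []
    for k in sorted(valley_six):
        if k + 1 in peak_six:
            rows.append(peak_six[k + 1] - valley_six[k])
            cycles.append(k)
    if not rows:
        raise NoCyclesError("no complete peak-valley pair acquired")
    per_cycle = np.asarray(rows)
    med = np.median(per_cycle, axis=0)
    sd = per_cycle.std(axis=0, ddof=1) if len(per_cycle) > 1 else np.zeros(6)
    return per_cycle, np.asarray(cycles), med, sd


def classify_stability(
    result: StabilityResult,
    threshold_um: float = MICROMOTION_THRESHOLD_UM,
) -> dict:
    """Stable/unstable call per translation axis against the micromotion threshold.

    An axis is unstable when the magnitude of its median inducible translation
    reaches the threshold (boundary inclusive).  The report carries the margin
    ``threshold - |value|`` per axis.
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    per_axis = {}
    for i, lab in enumerate(result.labels[:3]):
        value = abs(float(result.inducible_median[i]))
        per_axis[lab] = {
            "micromotion_um": value,
            "margin_um": threshold_um - value,
            "stable": value < threshold_um,
        }
    return {
        "threshold_um": threshold_um,
        "per_axis": per_axis,
        "stable": all(v["stable"] for v in per_axis.values()),
    }


# ---------------------------------------------------------------------------
# Sequence-level driver
# ---------------------------------------------------------------------------

def pose_series(seq, frames: list[int]) -> dict[int, np.ndarray]:
    """Decomposed implant-vs-bone position for selected frames of a sequence.

    The body frame origin is placed at the reference-frame marker centroid
    (the distal end of the prosthesis), so the translation components read as
    the displacement of that point relative to the bone.  Frame 0 of the
    sequence is the reference configuration.
    """
    c = np.nanmean(seq.marker_xyz_mm[0], axis=0)
    ref_m = seq.marker_xyz_mm[0] - c
    ref_g = seq.grid_xyz_mm[0] - c
    A = seq.anatomical_frame
    out: dict[int, np.ndarray] = {}
    for f in frames:
        pose_p = estimate_pose(ref_m, seq.marker_xyz_mm[f] - c, frame_index=f)
        pose_b = estimate_pose(ref_g, seq.grid_xyz_mm[f] - c, frame_index=f)
        out[f] = decompose(relative_pose(pose_p, pose_b), A)
    return out


def analyze_stability(seq, threshold_um: float = MICROMOTION_THRESHOLD_UM):
    """Full primary-stability analysis of a tracked sequence.

    Returns ``(StabilityResult, classification, CycleEvents)``.
    """
    events = extract_peaks_valleys(seq.loads_n, seq.times_s, seq.protocol)
    frames = sorted(set(events.peak_frames.values()) | set(events.valley_frames.values()))
    six = pose_series(seq, frames)
    peak_six = {k: six[f] for k, f in events.peak_frames.items()}
    valley_six = {k: six[f] for k, f in events.valley_frames.items()}
    migration = permanent_migration(peak_six, seq.protocol.acquisition_windows)
    per_cycle, cycles, med, sd = inducible_micromotion(peak_six, valley_six)
    result = StabilityResult(
        permanent_migration=migration,
        inducible_per_cycle=per_cycle,
        inducible_cycles=cycles,
        inducible_median=med,
        inducible_sd=sd,
    )
    return result, classify_stability(result, threshold_um), events
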