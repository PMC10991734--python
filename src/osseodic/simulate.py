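"""Virtual-specimen simulator.

Generates tracked marker/speckle sequences with known ground truth, standing
in for the cadaver + stereo-DIC hardware so the whole analysis chain can be
exercised and its measurement errors quantified at desk scale.

Ground-truth model
------------------
The prosthesis moves rigidly relative to the (otherwise fixed) bone:

* an *inducible* component proportional to the instantaneous load above the
  valley load (zero at or below the valley), reaching the stated 6-DOF
  amplitude at the load peak;
* a *permanent migration* component that accumulates with the cycle count
  following a monotone drift profile (saturating exponential by default:
  press-fit implants migrate mostly in the first cycles).

The bone surface carries a strain field that scales linearly with load from
zero in the fully unloaded reference; speckle nodes are displaced by the
corresponding in-plane displacement field.

Measurement noise is zero-mean isotropic Gaussian, independent per point, per
frame and per axis: 15 um SD for the prosthesis fiducial markers and 0.7 um SD
for the speckle nodes by default.  The two magnitudes differ because a DIC
system localises a high-contrast speckle facet to a hundredth of a pixel
(0.01 x 70 um) while small circular markers carry a larger centroiding error;
the defaults are calibrated so the downstream zero-displacement / zero-strain
analyses land at the error levels typical of this class of experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .exceptions import DegenerateGeometryError, InvalidProtocolError
from .geometry import SpecimenGeometry
from .kinematics import compose
from .protocol import LoadProtocol, event_times, generate_load_signal


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def saturating_exponential(cycle: np.ndarray, n_cycles: int, tau_cycles: float = 20.0):
    """Drift profile rising from 0 at cycle 0 to 1 at the last cycle."""
    c = np.clip(np.asarray(cycle, dtype=float), 0.0, n_cycles)
    return (1.0 - np.exp(-c / tau_cycles)) / (1.0 - np.exp(-n_cycles / tau_cycles))


def ramp_profile(flat_until: float = 10.0, flat_after: float = 90.0):
    """Drift profile flat during the first and last acquisition windows.

    Returns a profile that is 0 up to ``flat_until`` cycles, 1 from
    ``flat_after`` on, linear in between.  With the default acquisition
    windows the windowed-median migration estimator then reads back exactly
    the injected migration (useful for round-trip checks); the saturating
    default instead spreads part of the drift across the windows, as a real
    press-fit implant does.
    """

    def profile(cycle):
        c = np.asarray(cycle, dtype=float)
        return np.clip((c - flat_until) / (flat_after - flat_until), 0.0, 1.0)

    return profile


@dataclass(frozen=True)
class GroundTruthKinematics:
    """Injected implant-vs-bone motion (translations um, rotations deg).

    Components ordered (t_ML, t_CC, t_AP, r_ML, r_CC, r_AP).
    """

    inducible_amplitude: np.ndarray = field(default_factory=lambda: np.zeros(6))
    migration_drift: np.ndarray = field(default_factory=lambda: np.zeros(6))
    drift_tau_cycles: float = 20.0
    drift_profile: Callable | None = None

    def six_at(self, load_n: np.ndarray, cycle_frac: np.ndarray, protocol: LoadProtocol):
        """Ground-truth 6-DOF position for each sample, shape (n, 6)."""
        amp = np.asarray(self.inducible_amplitude, dtype=float)
        drift = np.asarray(self.migration_drift, dtype=float)
        lam = (np.asarray(load_n) - protocol.load_min_n) / (
            protocol.load_max_n - protocol.load_min_n
        )
        lam = np.clip(lam, 0.0, None)  # no inducible response below the valley load
        if self.drift_profile is not None:
            prof = self.drift_profile(cycle_frac)
        else:
            prof = saturating_exponential(cycle_frac, protocol.n_cycles, self.drift_tau_cycles)
        return np.outer(lam, amp) + np.outer(prof, drift)

    def expected_migration(self, protocol: LoadProtocol) -> np.ndarray:
        """Analytic value the windowed-median migration estimator reads back.

        The estimator differences the median peak position of the last and
        first acquisition windows, so for a drift profile still rising inside
        those windows the observable is smaller than the total injected drift.
        """
        def window_median_profile(lo, hi):
            peaks = np.array([k - 0.5 for k in range(lo, hi + 1)])
            if self.drift_profile is not None:
                return np.median(self.drift_profile(peaks))
            return np.median(
                saturating_exponential(peaks, protocol.n_cycles, self.drift_tau_cycles)
            )

        first = window_median_profile(*min(protocol.acquisition_windows))
        last = window_median_profile(*max(protocol.acquisition_windows))
        return (last - first) * np.asarray(self.migration_drift, dtype=float)


@dataclass(frozen=True)
class GroundTruthStrainField:
    """Analytic surface strain field at peak load, scaling linearly with load.

    The longitudinal (CC) strain follows a Gaussian bump centred near the stem
    tip; the transverse strain is ``-transverse_ratio`` times it.  Defaults
    emulate the reported specimen-median magnitudes (ROI-1 median e1 about
    1600 microstrain, decreasing distally towards the osteotomy), i.e. a bone
    loaded within the physiological range with load transfer concentrated at
    the stem tip.

    Positions are the in-plane patch coordinates ``(x, z)`` in mm, ``z`` along
    CC.  Strains are dimensionless (multiply by 1e6 for microstrain).
    """

    amplitude: float = 1632e-6
    center_cc_mm: float = 50.0
    width_mm: float = 38.4
    transverse_ratio: float = 0.455

    def _g(self, z):
        return np.exp(-(((np.asarray(z, dtype=float) - self.center_cc_mm) / self.width_mm) ** 2))

    def tensor_at(self, x, z):
        """Peak-load in-plane strain tensor components ``(e_xx, e_zz, e_xz)``."""
        x = np.asarray(x, dtype=float)
        g = self._g(z)
        e_zz = self.amplitude * g
        e_xx = -self.transverse_ratio * e_zz
        gp = g * (-2.0 * (np.asarray(z, dtype=float) - self.center_cc_mm) / self.width_mm**2)
        e_xz = -0.5 * self.transverse_ratio * self.amplitude * gp * x
        return e_xx, e_zz, e_xz

    def principal_at(self, x, z):
        """Analytic peak-load principal strains ``(e1, e2)``, e1 >= e2."""
        e_xx, e_zz, e_xz = self.tensor_at(x, z)
        m = 0.5 * (e_xx + e_zz)
        r = np.sqrt((0.5 * (e_zz - e_xx)) ** 2 + e_xz**2)
        return m + r, m - r

    def displacement_at(self, x, z):
        """Peak-load in-plane displacement field ``(u_x, u_z)`` in mm.

        ``u_z`` integrates the longitudinal strain profile from z = 0;
        ``u_x = -ratio * e_zz(z) * x`` contracts the patch transversally.  The
        symmetric gradient of this field is exactly :meth:`tensor_at`.
        """
        from scipy.special import erf

        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        w, z0 = self.width_mm, self.center_cc_mm
        u_z = (
            self.amplitude
            * w
            * np.sqrt(np.pi)
            / 2.0
            * (erf((z - z0) / w) - erf((0.0 - z0) / w))
        )
        u_x = -self.transverse_ratio * self.amplitude * self._g(z) * x
        return u_x, u_z

    def scaled(self, factor: float) -> "GroundTruthStrainField":
        return replace(self, amplitude=self.amplitude * factor)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise, zero mean, independent per point/frame/axis."""

    marker_noise_um: float = 15.0
    grid_noise_um: float = 0.7
    strain_window: int = 7
    seed: int | None = None

    def __post_init__(self):
        if self.marker_noise_um < 0 or self.grid_noise_um < 0:
            raise InvalidProtocolError("noise SDs must be >= 0")
        if self.strain_window < 3 or self.strain_window % 2 == 0:
            raise InvalidProtocolError("strain window must be an odd integer >= 3")


# ---------------------------------------------------------------------------
# Tracked sequences
# ---------------------------------------------------------------------------

@dataclass
class TrackedSequence:
    """Per-frame marker and speckle-node coordinates with a synchronous load channel.

    This is the simulator's output and the analyzer's input; it stands in for
    the image stream of a stereo-DIC acquisition after point tracking.
    Coordinates are lab-frame millimetres.
    """

    times_s: np.ndarray                # (n_frames,)
    loads_n: np.ndarray                # (n_frames,)
    cycle_index: np.ndarray            # (n_frames,)
    marker_xyz_mm: np.ndarray          # (n_frames, n_markers, 3); NaN = dropped point
    grid_xyz_mm: np.ndarray            # (n_frames, n_nodes, 3)
    geometry: SpecimenGeometry | None = None
    protocol: LoadProtocol | None = None
    ground_truth: GroundTruthKinematics | None = None
    strain_truth: GroundTruthStrainField | None = None
    noise: NoiseModel | None = None
    seed: int | None = None
    marker_ids: list[str] = field(default_factory=list)
    grid_ids: list[str] = field(default_factory=list)
    grid_shape: tuple[int, int] | None = None
    flagged_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.times_s)
        if not (len(self.loads_n) == n == len(self.marker_xyz_mm) == len(self.grid_xyz_mm)):
            raise InvalidProtocolError("all per-frame arrays must share the frame count")
        if not self.marker_ids:
            self.marker_ids = [f"M{i:03d}" for i in range(self.marker_xyz_mm.shape[1])]
        if not self.grid_ids:
            self.grid_ids = [f"S{i:05d}" for i in range(self.grid_xyz_mm.shape[1])]
        if self.grid_shape is None and self.geometry is not None:
            self.grid_shape = self.geometry.bone_grid.shape

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def anatomical_frame(self) -> np.ndarray:
        if self.geometry is None:
            return np.eye(3)
        return self.geometry.anatomical_frame


@dataclass(frozen=True)
class SpecimenSpec:
    """Everything needed to simulate one specimen's trial."""

    geometry: SpecimenGeometry
    kinematics: GroundTruthKinematics = field(default_factory=GroundTruthKinematics)
    strain: GroundTruthStrainField | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    protocol: LoadProtocol = field(default_factory=LoadProtocol)

    @classmethod
    def default(cls, **kwargs) -> "SpecimenSpec":
        kwargs.setdefault("geometry", SpecimenGeometry.default())
        kwargs.setdefault("strain", GroundTruthStrainField())
        kwargs.setdefault(
            "kinematics",
            GroundTruthKinematics(
                inducible_amplitude=np.array([10.0, 25.0, 8.0, 0.02, 0.03, 0.01]),
                migration_drift=np.array([2.0, 5.0, 1.5, 0.004, 0.006, 0.002]),
            ),
        )
        return cls(**kwargs)


def _child_rng(seed: int | None, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(0 if seed is None else int(seed), spawn_key=key)
    return np.random.default_rng(ss)


def simulate_trial(
    spec: SpecimenSpec,
    seed: int,
    frame_policy: str = "dense",
) -> TrackedSequence:
    """Simulate one cyclic-loading trial.

    ``frame_policy``:

    * ``"dense"`` - every camera frame inside the acquisition windows (plus the
      unloaded/preload segment) at the protocol sampling rate;
    * ``"events"`` - only the unloaded reference, the preload frame, and the
      analytic peak/valley frames of acquired cycles (the frames the stability
      and strain analyses consume; statistically identical, far cheaper).
    """
    geo, protocol, noise = spec.geometry, spec.protocol, spec.noise
    if len(geo.marker_xyz_mm) < 4:
        raise DegenerateGeometryError("need at least 4 prosthesis markers")
    if frame_policy == "dense":
        sig = generate_load_signal(protocol, restrict_to_windows=True)
        times, loads, cycles = sig.times_s, sig.loads_n, sig.cycle_index
    elif frame_policy == "events":
        times, cycles = event_times(protocol)
        loads = protocol.load_at(times)
    else:
        raise InvalidProtocolError(f"unknown frame policy {frame_policy!r}")

    # continuous cycle coordinate for the drift profile
    cycle_frac = np.clip(
        (times - protocol.cycles_start_s) * protocol.frequency_hz, 0.0, protocol.n_cycles
    )
    six = spec.kinematics.six_at(loads, cycle_frac, protocol)

    # markers: rigid ground-truth pose about the marker centroid
    c = geo.marker_centroid_mm
    m0 = geo.marker_xyz_mm - c
    markers = np.empty((len(times), len(m0), 3))
    for i in range(len(times)):
        pose = compose(six[i], geo.anatomical_frame)
        markers[i] = pose.apply(m0) + c

    # speckle nodes: load-scaled strain-field displacement.  The best-fit
    # rigid component of the deformation over the patch is removed, so the
    # tracked bone frame stays put and the injected kinematics are defined
    # relative to it — which is what the relative-pose analysis measures.
    grid0 = geo.bone_grid.xyz_mm
    grid = np.broadcast_to(grid0, (len(times), *grid0.shape)).copy()
    if spec.strain is not None:
        from .kinematics import estimate_pose

        uv = grid0 @ geo.bone_grid.basis           # in-plane coords (x, z)
        u_x, u_z = spec.strain.displacement_at(uv[:, 0], uv[:, 1])
        disp3 = np.column_stack([u_x, u_z]) @ geo.bone_grid.basis.T   # back to 3D
        rigid = estimate_pose(grid0, grid0 + disp3)
        disp3 = (grid0 + disp3) - rigid.apply(grid0)
        lam = loads / protocol.load_max_n
        grid = grid + lam[:, None, None] * disp3[None, :, :]

    rng = _child_rng(seed)
    if noise.marker_noise_um > 0:
        markers = markers + rng.normal(0.0, noise.marker_noise_um * 1e-3, markers.shape)
    if noise.grid_noise_um > 0:
        grid = grid + rng.normal(0.0, noise.grid_noise_um * 1e-3, grid.shape)

    return TrackedSequence(
        times_s=times,
        loads_n=loads,
        cycle_index=cycles,
        marker_xyz_mm=markers,
        grid_xyz_mm=grid,
        geometry=geo,
        protocol=protocol,
        ground_truth=spec.kinematics,
        strain_truth=spec.strain,
        noise=noise,
        seed=seed,
    )


def simulate_zero_pair(
    geometry: SpecimenGeometry,
    noise: NoiseModel,
    seed: int,
) -> TrackedSequence:
    """Two frames of the fully unloaded specimen: identical truth, independent noise.

    The zero-displacement / zero-strain analyses run on such pairs; any
    non-zero output is, by construction, measurement error.
    """
    if len(geometry.marker_xyz_mm) < 4:
        raise DegenerateGeometryError("need at least 4 prosthesis markers")
    rng = _child_rng(seed)
    markers = np.broadcast_to(
        geometry.marker_xyz_mm, (2, *geometry.marker_xyz_mm.shape)
    ).copy()
    grid = np.broadcast_to(
        geometry.bone_grid.xyz_mm, (2, *geometry.bone_grid.xyz_mm.shape)
    ).copy()
    if noise.marker_noise_um > 0:
        markers = markers + rng.normal(0.0, noise.marker_noise_um * 1e-3, markers.shape)
    if noise.grid_noise_um > 0:
        grid = grid + rng.normal(0.0, noise.grid_noise_um * 1e-3, grid.shape)
    return TrackedSequence(
        times_s=np.array([0.0, 0.01]),
        loads_n=np.zeros(2),
        cycle_index=np.zeros(2, dtype=int),
        marker_xyz_mm=markers,
        grid_xyz_mm=grid,
        geometry=geometry,
        noise=noise,
        seed=seed,
    )


def simulate_repetitions(
    spec: SpecimenSpec,
    n_reps: int = 4,
    seed: int = 0,
    frame_policy: str = "dense",
) -> list[TrackedSequence]:
    """Mount/remount repetitions: identical ground truth, independent noise."""
    if n_reps < 2:
        raise InvalidProtocolError("repeatability needs n_reps >= 2")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    return [simulate_trial(spec, s, frame_policy=frame_policy) for s in seeds]


@dataclass(frozen=True)
class PopulationSpec:
    """Between-specimen variation of the virtual population.

    Per-specimen ground truths are drawn once per specimen; defaults emulate
    the inter-specimen spread reported for cadaveric femurs (inducible
    translations a few tens of um with SDs in the 10-30 um range, rotations
    about 0.1 deg SD, migrations of a few um, ROI-1 peak strain median about
    1600 +/- 700 microstrain) while keeping every specimen far below the
    150 um instability threshold.
    """

    inducible_translation_mean_um: np.ndarray = field(
        default_factory=lambda: np.array([15.0, 30.0, 15.0])
    )
    inducible_translation_sd_um: np.ndarray = field(
        default_factory=lambda: np.array([13.0, 27.0, 27.0])
    )
    inducible_rotation_mean_deg: np.ndarray = field(
        default_factory=lambda: np.array([0.05, 0.05, 0.05])
    )
    inducible_rotation_sd_deg: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.15, 0.12])
    )
    migration_translation_sd_um: np.ndarray = field(
        default_factory=lambda: np.array([5.0, 1.0, 5.0])
    )
    migration_rotation_sd_deg: np.ndarray = field(
        default_factory=lambda: np.array([0.02, 0.02, 0.02])
    )
    roi1_e1_median_micro: float = 1604.0
    roi1_e1_sd_micro: float = 700.0

    def draw(self, rng: np.random.Generator, base: SpecimenSpec) -> SpecimenSpec:
        t = np.abs(
            rng.normal(self.inducible_translation_mean_um, self.inducible_translation_sd_um)
        )
        r = np.abs(rng.normal(self.inducible_rotation_mean_deg, self.inducible_rotation_sd_deg))
        mig_t = rng.normal(np.zeros(3), self.migration_translation_sd_um)
        mig_r = rng.normal(np.zeros(3), self.migration_rotation_sd_deg)
        kin = GroundTruthKinematics(
            inducible_amplitude=np.concatenate([t, r]),
            migration_drift=np.concatenate([mig_t, mig_r]),
        )
        strain = base.strain if base.strain is not None else GroundTruthStrainField()
        target = max(rng.normal(self.roi1_e1_median_micro, self.roi1_e1_sd_micro), 50.0)
        strain = strain.scaled(target / self.roi1_e1_median_micro)
        return replace(base, kinematics=kin, strain=strain)


def simulate_population(
    n_specimens: int = 5,
    variation: PopulationSpec | None = None,
    seed: int = 0,
    base: SpecimenSpec | None = None,
    frame_policy: str = "dense",
) -> list[TrackedSequence]:
    """Simulate a population of specimens tested under identical conditions."""
    if n_specimens < 2:
        raise InvalidProtocolError("a population needs n_specimens >= 2")
    variation = variation if variation is not None else PopulationSpec()
    base = base if base is not None else SpecimenSpec.default()
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_specimens)):
        rng = np.random.default_rng(child)
        spec_i = variation.draw(rng, base)
        trial_seed = int(child.generate_state(2)[1] % (2**31))
        out.append(simulate_trial(spec_i, trial_seed, frame_policy=frame_policy))
    return out
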