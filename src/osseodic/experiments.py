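"""Canonical virtual error-quantification experiments.

These drivers bundle the study conditions of the measurement-error protocol
into reproducible desk-scale experiments: the zero-displacement and
zero-strain analyses on simulated unloaded pairs, and the four-repetition
mount/remount repeatability experiments for micromotions, migrations and
ROI-median strains.  They are used by the acceptance script and tests, and
are convenient entry points for sensitivity studies (e.g. how the error
figures respond to a different marker count or noise level).

All randomness derives from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every experiment is exactly
reproducible.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    ErrorReport,
    intra_specimen_repeatability,
    stability_components,
    strain_components,
    zero_displacement_errors,
    zero_strain_errors,
)
from .geometry import SpecimenGeometry
from .kinematics import analyze_stability
from .simulate import (
    GroundTruthKinematics,
    GroundTruthStrainField,
    NoiseModel,
    SpecimenSpec,
    simulate_repetitions,
    simulate_zero_pair,
)
from .strain import analyze_strain

#: inducible ground truth used by the repeatability experiments:
#: 40/60/20 um translations, 0.05 deg rotations, no migration
REPEATABILITY_AMPLITUDE = np.array([40.0, 60.0, 20.0, 0.05, 0.05, 0.05])


def _spawn_seeds(seed: int, key: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def zero_displacement_experiment(
    n_pairs: int = 100,
    seed: int = 1,
    n_markers: int = 25,
    grid_shape: tuple[int, int] = (20, 20),
    noise: NoiseModel | None = None,
) -> ErrorReport:
    """Zero-displacement analysis on ``n_pairs`` simulated unloaded pairs.

    25 cylinder markers (15 um noise) and a 400-node bone patch (0.7 um
    speckle noise) by default — the declared noise calibration.
    """
    geometry = SpecimenGeometry.default(n_markers=n_markers, grid_shape=grid_shape)
    noise = noise if noise is not None else NoiseModel()
    pairs = [
        simulate_zero_pair(geometry, noise, s)
        for s in _spawn_seeds(seed, 1, n_pairs)
    ]
    return zero_displacement_errors(pairs)


def zero_strain_experiment(
    n_pairs: int = 50,
    seed: int = 1,
    grid_spacing_mm: float = 1.19,
    noise: NoiseModel | None = None,
    window: int = 7,
) -> ErrorReport:
    """Zero-strain analysis on simulated unloaded pairs of the speckle grid."""
    geometry = SpecimenGeometry.default(grid_spacing_mm=grid_spacing_mm)
    noise = noise if noise is not None else NoiseModel()
    pairs = [
        simulate_zero_pair(geometry, noise, s)
        for s in _spawn_seeds(seed, 2, n_pairs)
    ]
    return zero_strain_errors(pairs, window=window)


def repeatability_experiment(
    n_seed_replicates: int = 25,
    n_reps: int = 4,
    seed: int = 1,
    amplitude: np.ndarray | None = None,
) -> dict[str, float]:
    """Mount/remount repeatability of stability metrics, averaged over seeds.

    Simulates one specimen (no true migration) tested ``n_reps`` times,
    computes the per-component SD of the median inducible micromotion and of
    the windowed-median permanent migration across repetitions, and averages
    those SDs over ``n_seed_replicates`` independent replicates of the whole
    experiment to stabilise the few-degrees-of-freedom SD estimate.
    """
    amplitude = REPEATABILITY_AMPLITUDE if amplitude is None else np.asarray(amplitude)
    spec = SpecimenSpec(
        geometry=SpecimenGeometry.default(grid_shape=(20, 20)),
        kinematics=GroundTruthKinematics(inducible_amplitude=amplitude),
        strain=None,
        noise=NoiseModel(),
    )
    sd_rows = []
    for s in _spawn_seeds(seed, 3, n_seed_replicates):
        reps = simulate_repetitions(spec, n_reps=n_reps, seed=s, frame_policy="events")
        comps = [stability_components(analyze_stability(r)[0]) for r in reps]
        report = intra_specimen_repeatability(comps)
        keys = list(comps[0])
        sd_rows.append([report.random[k] for k in keys])
    return dict(zip(keys, np.mean(sd_rows, axis=0)))


def strain_repeatability_experiment(
    n_seed_replicates: int = 25,
    n_reps: int = 4,
    seed: int = 1,
    roi1_e1_target_micro: float = 1600.0,
) -> dict[str, float]:
    """Mount/remount repeatability of the ROI-median principal strains.

    The ground-truth field is scaled so that the noise-free ROI-1 median of
    the maximum principal strain equals ``roi1_e1_target_micro`` at peak
    load; the per-ROI SD of the median e1/e2 across repetitions is averaged
    over seed replicates.
    """
    base_field = GroundTruthStrainField()
    # the default field's noise-free ROI-1 median e1 is its reference median
    spec = SpecimenSpec(
        geometry=SpecimenGeometry.default(),
        kinematics=GroundTruthKinematics(),
        strain=base_field.scaled(roi1_e1_target_micro / 1604.0),
        noise=NoiseModel(),
    )
    sd_rows, keys = [], None
    for s in _spawn_seeds(seed, 4, n_seed_replicates):
        reps = simulate_repetitions(spec, n_reps=n_reps, seed=s, frame_policy="events")
        comps = [strain_components(analyze_strain(r)[1]) for r in reps]
        keys = list(comps[0])
        mat = np.array([[c[k] for k in keys] for c in comps])
        sd_rows.append(mat.std(axis=0, ddof=1))
    return dict(zip(keys, np.mean(sd_rows, axis=0)))
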