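"""File formats, configuration and the end-to-end pipeline driver.

Track files are long-format CSV with the fixed column set
``frame, time_s, load_N, point_id, point_class, x_mm, y_mm, z_mm``
(``point_class`` is ``marker`` or ``speckle``; decimal point, UTF-8, header
row mandatory).  A leading ``# osseodic-meta: {...}`` comment line carries the
structural metadata (grid shape, spacing, protocol) that a flat table cannot;
files without it still import, with the metadata left unset.  A lossless
single-file binary container is provided through HDF5.

Configurations are YAML validated by pydantic models with unknown keys
rejected; every pipeline output embeds the configuration hash and seed so a
re-run reproduces byte-identical result files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import strain as strain_mod
from .errors import (
    stability_components,
    strain_components,
    zero_displacement_errors,
)
from .exceptions import IntegrityError, SchemaError
from .geometry import SpecimenGeometry
from .kinematics import analyze_stability
from .protocol import LoadProtocol
from .simulate import (
    GroundTruthKinematics,
    GroundTruthStrainField,
    NoiseModel,
    SpecimenSpec,
    TrackedSequence,
    simulate_trial,
)

TRACK_COLUMNS = ["frame", "time_s", "load_N", "point_id", "point_class", "x_mm", "y_mm", "z_mm"]
_META_PREFIX = "# osseodic-meta: "


# ---------------------------------------------------------------------------
# CSV tracks
# ---------------------------------------------------------------------------

def sequence_to_csv(seq: TrackedSequence, path) -> None:
    """Write a tracked sequence as long-format CSV (numerically lossless)."""
    frames = []
    for f in range(seq.n_frames):
        for ids, cls, xyz in (
            (seq.marker_ids, "marker", seq.marker_xyz_mm[f]),
            (seq.grid_ids, "speckle", seq.grid_xyz_mm[f]),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "frame": f,
                        "time_s": seq.times_s[f],
                        "load_N": seq.loads_n[f],
                        "point_id": ids,
                        "point_class": cls,
                        "x_mm": xyz[:, 0],
                        "y_mm": xyz[:, 1],
                        "z_mm": xyz[:, 2],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    meta = {
        "grid_shape": list(seq.grid_shape) if seq.grid_shape else None,
        "grid_spacing_mm": seq.geometry.bone_grid.spacing_mm if seq.geometry else None,
        "cycle_index": np.asarray(seq.cycle_index).tolist(),
        "seed": seq.seed,
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_META_PREFIX + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def import_tracks(
    path,
    protocol: LoadProtocol | None = None,
    geometry: SpecimenGeometry | None = None,
) -> TrackedSequence:
    """Read a point-track CSV export into a :class:`TrackedSequence`.

    The frame set of point identities is taken from the first frame; frames
    missing a point are flagged (the point's coordinates become NaN there and
    pose estimation proceeds from the remaining markers).  A point identity
    never seen in frame 0 is an integrity error.
    """
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith(_META_PREFIX):
            meta = json.loads(first[len(_META_PREFIX):])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns and c != "load_N"]
    if missing:
        raise SchemaError(f"track file is missing mandatory column(s): {', '.join(missing)}")
    if "load_N" not in df.columns:
        df["load_N"] = 0.0

    frames = np.sort(df["frame"].unique())
    f0 = df[df["frame"] == frames[0]]
    marker_ids = f0.loc[f0["point_class"] == "marker", "point_id"].tolist()
    grid_ids = f0.loc[f0["point_class"] == "speckle", "point_id"].tolist()
    known = set(marker_ids) | set(grid_ids)
    alien = set(df["point_id"]) - known
    if alien:
        bad_frames = sorted(df.loc[df["point_id"].isin(alien), "frame"].unique().tolist())
        raise IntegrityError(
            f"point identities {sorted(alien)[:5]} absent from the first frame",
            frames=bad_frames,
        )

    n = len(frames)
    times = np.empty(n)
    loads = np.empty(n)
    markers = np.full((n, len(marker_ids), 3), np.nan)
    grid = np.full((n, len(grid_ids), 3), np.nan)
    m_index = {pid: i for i, pid in enumerate(marker_ids)}
    g_index = {pid: i for i, pid in enumerate(grid_ids)}
    flagged = []
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f]
        times[k] = sub["time_s"].iloc[0]
        loads[k] = sub["load_N"].iloc[0]
        for _, row in sub.iterrows():
            xyz = (row["x_mm"], row["y_mm"], row["z_mm"])
            if row["point_class"] == "marker":
                markers[k, m_index[row["point_id"]]] = xyz
            else:
                grid[k, g_index[row["point_id"]]] = xyz
        if len(sub) != len(marker_ids) + len(grid_ids):
            flagged.append(int(k))

    cycle = np.asarray(meta.get("cycle_index", np.zeros(n, dtype=int)))
    if len(cycle) != n:
        cycle = np.zeros(n, dtype=int)
    return TrackedSequence(
        times_s=times,
        loads_n=loads,
        cycle_index=cycle,
        marker_xyz_mm=markers,
        grid_xyz_mm=grid,
        geometry=geometry,
        protocol=protocol,
        marker_ids=[str(i) for i in marker_ids],
        grid_ids=[str(i) for i in grid_ids],
        grid_shape=tuple(meta["grid_shape"]) if meta.get("grid_shape") else None,
        flagged_frames=flagged,
        seed=meta.get("seed"),
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def sequence_to_hdf5(seq: TrackedSequence, path) -> None:
    """Lossless single-file container for a tracked sequence."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times_s", data=seq.times_s)
        h5.create_dataset("loads_n", data=seq.loads_n)
        h5.create_dataset("cycle_index", data=np.asarray(seq.cycle_index, dtype=np.int64))
        h5.create_dataset("marker_xyz_mm", data=seq.marker_xyz_mm)
        h5.create_dataset("grid_xyz_mm", data=seq.grid_xyz_mm)
        h5.attrs["marker_ids"] = json.dumps(seq.marker_ids)
        h5.attrs["grid_ids"] = json.dumps(seq.grid_ids)
        if seq.grid_shape:
            h5.attrs["grid_shape"] = list(seq.grid_shape)
        if seq.seed is not None:
            h5.attrs["seed"] = int(seq.seed)


def sequence_from_hdf5(path, protocol=None, geometry=None) -> TrackedSequence:
    with h5py.File(path, "r") as h5:
        return TrackedSequence(
            times_s=h5["times_s"][...],
            loads_n=h5["loads_n"][...],
            cycle_index=h5["cycle_index"][...],
            marker_xyz_mm=h5["marker_xyz_mm"][...],
            grid_xyz_mm=h5["grid_xyz_mm"][...],
            marker_ids=json.loads(h5.attrs["marker_ids"]),
            grid_ids=json.loads(h5.attrs["grid_ids"]),
            grid_shape=tuple(h5.attrs["grid_shape"]) if "grid_shape" in h5.attrs else None,
            seed=int(h5.attrs["seed"]) if "seed" in h5.attrs else None,
            protocol=protocol,
            geometry=geometry,
        )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    preload_n: float = 150.0
    load_min_n: float = 150.0
    load_max_n: float = 850.0
    frequency_hz: float = 1.0
    n_cycles: int = 100
    sampling_rate_hz: float = 100.0
    acquisition_windows: list[tuple[int, int]] = Field(
        default_factory=lambda: [(1, 10), (45, 55), (90, 100)]
    )

    def build(self) -> LoadProtocol:
        return LoadProtocol(
            preload_n=self.preload_n,
            load_min_n=self.load_min_n,
            load_max_n=self.load_max_n,
            frequency_hz=self.frequency_hz,
            n_cycles=self.n_cycles,
            sampling_rate_hz=self.sampling_rate_hz,
            acquisition_windows=tuple(tuple(w) for w in self.acquisition_windows),
        )


class GeometryConfig(_Strict):
    n_markers: int = 25
    grid_spacing_mm: float = 1.19
    grid_shape: tuple[int, int] | None = None

    def build(self) -> SpecimenGeometry:
        return SpecimenGeometry.default(
            n_markers=self.n_markers,
            grid_spacing_mm=self.grid_spacing_mm,
            grid_shape=self.grid_shape,
        )


class KinematicsConfig(_Strict):
    inducible_amplitude: list[float] = Field(default_factory=lambda: [10, 25, 8, 0.02, 0.03, 0.01])
    migration_drift: list[float] = Field(
        default_factory=lambda: [2, 5, 1.5, 0.004, 0.006, 0.002]
    )
    drift_tau_cycles: float = 20.0

    def build(self) -> GroundTruthKinematics:
        return GroundTruthKinematics(
            inducible_amplitude=np.asarray(self.inducible_amplitude, float),
            migration_drift=np.asarray(self.migration_drift, float),
            drift_tau_cycles=self.drift_tau_cycles,
        )


class StrainFieldConfig(_Strict):
    amplitude_micro: float = 1632.0
    center_cc_mm: float = 50.0
    width_mm: float = 38.4
    transverse_ratio: float = 0.455

    def build(self) -> GroundTruthStrainField:
        return GroundTruthStrainField(
            amplitude=self.amplitude_micro * 1e-6,
            center_cc_mm=self.center_cc_mm,
            width_mm=self.width_mm,
            transverse_ratio=self.transverse_ratio,
        )


class NoiseConfig(_Strict):
    marker_noise_um: float = 15.0
    grid_noise_um: float = 0.7
    strain_window: int = 7

    def build(self) -> NoiseModel:
        return NoiseModel(
            marker_noise_um=self.marker_noise_um,
            grid_noise_um=self.grid_noise_um,
            strain_window=self.strain_window,
        )


class AnalysisConfig(_Strict):
    """Full pipeline configuration (YAML-serialisable, unknown keys rejected)."""

    seed: int = 1
    frame_policy: str = "events"
    tracks_csv: str | None = None       # analyse an existing export instead of simulating
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    kinematics: KinematicsConfig = Field(default_factory=KinematicsConfig)
    strain_field: StrainFieldConfig = Field(default_factory=StrainFieldConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    micromotion_threshold_um: float = 150.0
    strain_window: int = 7
    n_zero_pairs: int = 0               # >0: run a zero-displacement analysis too
    output_dir: str = "osseodic-out"
    write_tracks_csv: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(data)
        except Exception as exc:  # pydantic ValidationError
            raise SchemaError(f"invalid configuration {path}: {exc}") from exc

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def build_spec(self) -> SpecimenSpec:
        return SpecimenSpec(
            geometry=self.geometry.build(),
            kinematics=self.kinematics.build(),
            strain=self.strain_field.build(),
            noise=self.noise.build(),
            protocol=self.protocol.build(),
        )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig) -> dict:
    """Simulate (or load), analyse stability and strain, write all outputs.

    Deterministic for a given configuration: every output embeds the config
    hash and seed, and contains no timestamps, so re-running reproduces
    byte-identical files.  Returns the result dictionary that was written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed}

    if config.tracks_csv:
        seq = import_tracks(
            config.tracks_csv,
            protocol=config.protocol.build(),
            geometry=config.geometry.build(),
        )
        stage = "import"
    else:
        spec = config.build_spec()
        seq = simulate_trial(spec, seed=config.seed, frame_policy=config.frame_policy)
        stage = "simulate"
        if config.write_tracks_csv:
            sequence_to_csv(seq, out / "tracks.csv")

    try:
        stability, classification, _ = analyze_stability(
            seq, threshold_um=config.micromotion_threshold_um
        )
    except Exception as exc:
        raise type(exc)(f"[stage: stability after {stage}] {exc}") from exc
    try:
        _, roi_summaries = strain_mod.analyze_strain(seq, window=config.strain_window)
    except Exception as exc:
        raise type(exc)(f"[stage: strain after {stage}] {exc}") from exc

    results = {
        "provenance": provenance,
        "stability": stability.as_dict(),
        "classification": classification,
        "roi_summaries": {
            name: {
                "median_e1_micro": s.median_e1_micro,
                "median_e2_micro": s.median_e2_micro,
                "n_nodes": s.n_nodes,
                "class": strain_mod.classify_strain(s),
            }
            for name, s in roi_summaries.items()
        },
        "components": {
            **stability_components(stability),
            **strain_components(roi_summaries),
        },
    }

    if config.n_zero_pairs > 0 and not config.tracks_csv:
        from .simulate import simulate_zero_pair

        geo = config.geometry.build()
        noise = config.noise.build()
        ss = np.random.SeedSequence(config.seed, spawn_key=(99,))
        pairs = [
            simulate_zero_pair(geo, noise, int(c.generate_state(1)[0] % 2**31))
            for c in ss.spawn(config.n_zero_pairs)
        ]
        report = zero_displacement_errors(pairs)
        report.meta.update(provenance)
        results["zero_displacement"] = report.as_dict()

    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    # flat CSV of the stability summary
    pd.DataFrame(
        {
            "component": list(stability.labels),
            "permanent_migration": stability.permanent_migration,
            "inducible_median": stability.inducible_median,
            "inducible_sd": stability.inducible_sd,
            "unit": ["um"] * 3 + ["deg"] * 3,
            "config_hash": provenance["config_hash"],
            "seed": provenance["seed"],
        }
    ).to_csv(out / "stability.csv", index=False, float_format="%.17g")
    return results
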