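"""Measurement-error protocol: zero-displacement / zero-strain analyses,
intra-specimen repeatability, inter-specimen variability.

Estimator conventions (declared, since the protocol itself does not fix them):

* *systematic* error is the signed mean of the estimates across repeated
  zero pairs; *random* error is their sample standard deviation;
* every SD in this module uses the n-1 normalisation;
* repeatability is the per-component sample SD across repetitions of the same
  specimen; inter-specimen variability the median and sample SD across
  specimens.

For the zero-strain analysis the report additionally carries the signed
in-plane tensor components (e_xx, e_zz, e_xz).  Because the principal values
are sorted (e1 >= e2), pure measurement noise gives e1 a positive mean (a
Rayleigh-type bias of the maximum eigenvalue) even when every signed
component is unbiased; the tensor components separate pipeline bias from this
ordering artefact.  See docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import DOF_LABELS
from .kinematics import StabilityResult, pose_series
from .strain import DisplacementGrid, ROISummary, compute_strain, principal_strains


@dataclass
class ErrorReport:
    """Systematic (mean) and random (sample SD) error per component."""

    kind: str                      # e.g. "zero-displacement", "zero-strain"
    systematic: dict[str, float]
    random: dict[str, float]
    units: dict[str, str]
    n: int                         # pairs / repetitions / specimens
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n": self.n,
            "systematic": self.systematic,
            "random": self.random,
            "units": self.units,
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [f"{self.kind} error analysis (n = {self.n})", "-" * 44]
        for k in self.systematic:
            lines.append(
                f"{k:12s} systematic {self.systematic[k]:+10.3f} "
                f"random {self.random[k]:10.3f} {self.units.get(k, '')}"
            )
        return "\n".join(lines)


_DOF_UNITS = {lab: ("um" if lab.startswith("t_") else "deg") for lab in DOF_LABELS}


def zero_displacement_errors(pairs: list) -> ErrorReport:
    """Intrinsic displacement/rotation errors from zero-load frame pairs.

    Each pair is a two-frame :class:`TrackedSequence` of the fully unloaded
    specimen; the implant-vs-bone 6-DOF displacement between its frames is
    estimated exactly as in a loaded trial.  The truth being zero, the mean
    and SD of the estimates across pairs are the systematic and random error
    per component.
    """
    if not pairs:
        raise ValueError("need at least one zero-displacement pair")
    rows = np.asarray([pose_series(seq, [1])[1] for seq in pairs])
    systematic = rows.mean(axis=0)
    random = rows.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(6)
    return ErrorReport(
        kind="zero-displacement",
        systematic={lab: float(systematic[i]) for i, lab in enumerate(DOF_LABELS)},
        random={lab: float(random[i]) for i, lab in enumerate(DOF_LABELS)},
        units=dict(_DOF_UNITS),
        n=len(rows),
        meta={"estimates": rows.tolist()} if len(rows) <= 200 else {},
    )


def zero_strain_errors(pairs: list, window: int = 7) -> ErrorReport:
    """Intrinsic strain errors from zero-load frame pairs.

    Pools every interior (valid, non-edge) node of every pair; reports
    systematic/random error of e1 and e2 plus the signed tensor components.
    """
    if not pairs:
        raise ValueError("need at least one zero-strain pair")
    vals: dict[str, list[np.ndarray]] = {k: [] for k in ("e1", "e2", "e_xx", "e_zz", "e_xz")}
    for seq in pairs:
        grid = DisplacementGrid.from_sequence(seq, frame=1, reference=0)
        tens = compute_strain(grid, window=window)
        psf = principal_strains(tens)
        m = psf.valid & ~psf.edge
        vals["e1"].append(psf.e1_micro[m])
        vals["e2"].append(psf.e2_micro[m])
        vals["e_xx"].append(tens.e_xx[m] * 1e6)
        vals["e_zz"].append(tens.e_zz[m] * 1e6)
        vals["e_xz"].append(tens.e_xz[m] * 1e6)
    pooled = {k: np.concatenate(v) for k, v in vals.items()}
    return ErrorReport(
        kind="zero-strain",
        systematic={k: float(v.mean()) for k, v in pooled.items()},
        random={k: float(v.std(ddof=1)) for k, v in pooled.items()},
        units={k: "microstrain" for k in pooled},
        n=len(pairs),
        meta={"n_interior_nodes": int(len(pooled["e1"]) // len(pairs)), "window": window},
    )


# ---------------------------------------------------------------------------
# Repeatability / variability
# ---------------------------------------------------------------------------

def stability_components(result: StabilityResult) -> dict[str, float]:
    """Flatten a stability result into labelled scalar components."""
    out = {}
    for i, lab in enumerate(result.labels):
        out[f"inducible_{lab}"] = float(result.inducible_median[i])
        out[f"migration_{lab}"] = float(result.permanent_migration[i])
    return out


def strain_components(summaries: dict[str, ROISummary]) -> dict[str, float]:
    """Flatten ROI summaries into labelled scalar components."""
    out = {}
    for name, s in sorted(summaries.items()):
        out[f"{name}_e1"] = s.median_e1_micro
        out[f"{name}_e2"] = s.median_e2_micro
    return out


def _component_matrix(results: list[dict[str, float]]) -> tuple[list[str], np.ndarray]:
    keys = list(results[0])
    for r in results:
        if list(r) != keys:
            raise ValueError("all results must share the same component labels")
    return keys, np.asarray([[r[k] for k in keys] for r in results])


def intra_specimen_repeatability(results: list[dict[str, float]]) -> ErrorReport:
    """Per-component SD across mount/remount repetitions of one specimen.

    ``results`` holds one labelled component dict per repetition (use
    :func:`stability_components` or :func:`strain_components`).
    """
    if len(results) < 2:
        raise ValueError("repeatability needs >= 2 repetitions")
    keys, mat = _component_matrix(results)
    sd = mat.std(axis=0, ddof=1)
    return ErrorReport(
        kind="intra-specimen repeatability",
        systematic={k: float(mat.mean(axis=0)[i]) for i, k in enumerate(keys)},
        random={k: float(sd[i]) for i, k in enumerate(keys)},
        units={k: _unit_for(k) for k in keys},
        n=len(results),
    )


def inter_specimen_variability(results: list[dict[str, float]]) -> ErrorReport:
    """Per-component median and SD across specimens tested identically."""
    if len(results) < 2:
        raise ValueError("variability needs >= 2 specimens")
    keys, mat = _component_matrix(results)
    med = np.median(mat, axis=0)
    sd = mat.std(axis=0, ddof=1)
    return ErrorReport(
        kind="inter-specimen variability",
        systematic={k: float(med[i]) for i, k in enumerate(keys)},  # median across specimens
        random={k: float(sd[i]) for i, k in enumerate(keys)},
        units={k: _unit_for(k) for k in keys},
        n=len(results),
        meta={"central_estimate": "median"},
    )


def _unit_for(label: str) -> str:
    if "_t_" in label or label.startswith("t_"):
        return "um"
    if "_r_" in label or label.startswith("r_"):
        return "deg"
    return "microstrain"


# ---------------------------------------------------------------------------
# Uncertainty vs biological thresholds
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {
    "um": 150.0,            # inducible micromotion / fibrous tissue formation
    "microstrain": 2000.0,  # physiological peak strain of cortical bone
}


def uncertainty_vs_threshold(
    report: ErrorReport,
    thresholds: dict[str, float] | None = None,
    pass_ratio: float = 0.1,
):
    """Margin of every uncertainty component against its biological threshold.

    A component passes when its random error is at most ``pass_ratio`` (one
    order of magnitude margin by default) of the threshold matching its unit.
    Components without a matching threshold (e.g. rotations) are skipped.
    Returns a list of row dicts (component, uncertainty, threshold, ratio, pass).
    """
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    rows = []
    for comp, value in report.random.items():
        unit = report.units.get(comp, "")
        if unit not in thresholds:
            continue
        thr = thresholds[unit]
        ratio = abs(value) / thr
        rows.append(
            {
                "component": comp,
                "uncertainty": float(value),
                "unit": unit,
                "threshold": thr,
                "ratio": float(ratio),
                "pass": bool(ratio <= pass_ratio),
            }
        )
    return rows
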