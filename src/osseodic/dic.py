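"""Minimal 2D subset-based image correlation and speckle synthesis.

This module exists to demonstrate the facet-size / grid-spacing trade-off of
a DIC acquisition: larger facets average more speckle texture and reduce the
displacement uncertainty, at the cost of spatial resolution.  The correlation
kernel is the standard one — normalised cross-correlation of a square facet
(subset) with subpixel localisation by a quadratic fit to the 3x3 NCC peak
neighbourhood — and is documented as a replaceable stand-in for the
proprietary engines of commercial stereo systems.  Only single-camera 2D
correlation is provided; the main pipeline consumes 3D point tracks directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .exceptions import SchemaError

DEFAULT_FACET_SIZE = 40     # pixels
DEFAULT_GRID_SPACING = 17   # pixels


@dataclass(frozen=True)
class SpeckleImage:
    """Grayscale speckle image, intensities in [0, 1]."""

    pixels: np.ndarray
    pixel_size_mm: float = 0.07

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise SchemaError("speckle image must be a 2D grayscale array")
        if self.pixel_size_mm <= 0:
            raise SchemaError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FacetGrid:
    """Square facet (subset) size and node spacing, both in pixels."""

    facet_size: int = DEFAULT_FACET_SIZE
    grid_spacing: int = DEFAULT_GRID_SPACING

    def __post_init__(self):
        if self.facet_size < 11:
            raise SchemaError(f"facet size must be >= 11 px, got {self.facet_size}")
        if self.grid_spacing < 1:
            raise SchemaError(f"grid spacing must be >= 1 px, got {self.grid_spacing}")

    def nodes(self, image_shape: tuple[int, int], margin: int = 0) -> np.ndarray:
        """Node centres (row, col) fully inside the image with an extra margin."""
        half = self.facet_size // 2 + margin
        rows = np.arange(half, image_shape[0] - half, self.grid_spacing)
        cols = np.arange(half, image_shape[1] - half, self.grid_spacing)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])


def imaging_geometry(fov_width_mm: float, sensor_width_px: int) -> float:
    """Pixel size (mm) from field-of-view width and sensor width, 2-decimal rounded."""
    if fov_width_mm <= 0 or sensor_width_px <= 0:
        raise SchemaError("field of view and sensor width must be positive")
    return round(fov_width_mm / sensor_width_px, 2)


def synthesize_speckle(
    width_px: int,
    height_px: int,
    dot_density_per_mm2: float = 4.0,
    dot_diameter_mean_mm: float = 0.35,
    dot_diameter_sd_mm: float = 0.10,
    pixel_size_mm: float = 0.07,
    seed: int = 0,
    blur_sigma_px: float = 0.6,
) -> SpeckleImage:
    """White-on-black airbrushed speckle pattern.

    Dots are ellipses with log-normal diameters (parameterised by the stated
    mean and SD of the physical dot size), random aspect ratio in [0.7, 1]
    and random orientation, on a black background; a slight Gaussian blur
    provides the subpixel intensity gradients correlation needs.  A coverage
    above 80 percent is degenerate for DIC and raises a warning.
    """
    if width_px <= 0 or height_px <= 0:
        raise SchemaError("image dimensions must be positive")
    rng = np.random.default_rng(seed)
    img = np.zeros((height_px, width_px))
    area_mm2 = width_px * height_px * pixel_size_mm**2
    n_dots = rng.poisson(dot_density_per_mm2 * area_mm2)
    if dot_diameter_mean_mm <= 0:
        raise SchemaError("dot diameter must be positive")
    # log-normal parameters from the stated mean / SD of the diameter
    cv2_ = (dot_diameter_sd_mm / dot_diameter_mean_mm) ** 2
    sigma = np.sqrt(np.log1p(cv2_))
    mu = np.log(dot_diameter_mean_mm) - 0.5 * sigma**2
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    for _ in range(n_dots):
        cy, cx = rng.uniform(0, height_px), rng.uniform(0, width_px)
        diam_px = rng.lognormal(mu, sigma) / pixel_size_mm
        a = max(diam_px / 2.0, 0.5)
        b = a * rng.uniform(0.7, 1.0)
        phi = rng.uniform(0, np.pi)
        # bounding box restricted stamp
        r0, r1 = int(max(cy - a - 2, 0)), int(min(cy + a + 3, height_px))
        c0, c1 = int(max(cx - a - 2, 0)), int(min(cx + a + 3, width_px))
        if r0 >= r1 or c0 >= c1:
            continue
        dy, dx = yy[r0:r1, c0:c1] - cy, xx[r0:r1, c0:c1] - cx
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        img[r0:r1, c0:c1][(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1.0
    coverage = img.mean()
    if coverage > 0.8:
        warnings.warn(
            f"speckle coverage {coverage:.2f} exceeds 0.8: pattern degenerate for DIC",
            stacklevel=2,
        )
    if blur_sigma_px > 0 and n_dots > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, blur_sigma_px)
        img = np.clip(img / max(img.max(), 1e-12), 0.0, 1.0)
    return SpeckleImage(pixels=img, pixel_size_mm=pixel_size_mm)


def coverage_fraction(image: SpeckleImage, threshold: float = 0.5) -> float:
    """Fraction of pixels covered by speckle dots."""
    return float((image.pixels > threshold).mean())


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _quadratic_subpixel(ncc: np.ndarray, peak: tuple[int, int]) -> np.ndarray:
    """Subpixel offset from a separable quadratic fit to the 3x3 peak neighbourhood."""
    r, c = peak
    offset = np.zeros(2)
    for axis, (lo, mid, hi) in enumerate(
        [
            (ncc[r - 1, c], ncc[r, c], ncc[r + 1, c]),
            (ncc[r, c - 1], ncc[r, c], ncc[r, c + 1]),
        ]
    ):
        denom = lo - 2.0 * mid + hi
        if denom < -1e-12:
            offset[axis] = float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))
    return offset


def correlate_pair(
    reference: SpeckleImage,
    deformed: SpeckleImage,
    grid: FacetGrid | None = None,
    search_radius_px: int = 8,
    score_threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Track every facet of ``grid`` from the reference to the deformed image.

    Returns arrays ``nodes_rc`` (row, col), ``disp_px`` (d_row, d_col),
    ``score`` (peak NCC) and ``valid``.  A facet with no intensity variance,
    a search window leaving the image, or a peak score below the threshold is
    flagged invalid (its displacement is NaN) rather than propagating NaNs.
    Integer displacements of an exactly resampled image are recovered exactly:
    when the peak correlation is numerically 1 the subpixel refinement is a
    no-op by construction.
    """
    grid = grid if grid is not None else FacetGrid()
    ref, dfm = np.asarray(reference.pixels, float), np.asarray(deformed.pixels, float)
    if ref.shape != dfm.shape:
        raise SchemaError("reference and deformed images must share their shape")
    half = grid.facet_size // 2
    nodes = grid.nodes(ref.shape, margin=search_radius_px)
    disp = np.full((len(nodes), 2), np.nan)
    score = np.zeros(len(nodes))
    valid = np.zeros(len(nodes), dtype=bool)
    for i, (r, c) in enumerate(nodes):
        tmpl = ref[r - half : r + half + 1, c - half : c + half + 1]
        if tmpl.std() < 1e-12:
            continue  # featureless facet
        win = dfm[
            r - half - search_radius_px : r + half + search_radius_px + 1,
            c - half - search_radius_px : c + half + search_radius_px + 1,
        ]
        if win.std() < 1e-12:
            continue
        ncc = match_template(win, tmpl, pad_input=False)
        pk = np.unravel_index(np.argmax(ncc), ncc.shape)
        score[i] = float(ncc[pk])
        if score[i] < score_threshold:
            continue
        d = np.array(pk, dtype=float) - search_radius_px
        interior = 0 < pk[0] < ncc.shape[0] - 1 and 0 < pk[1] < ncc.shape[1] - 1
        if interior and score[i] < 1.0 - 1e-12:
            d = d + _quadratic_subpixel(ncc, pk)
        disp[i] = d
        valid[i] = True
    return {"nodes_rc": nodes, "disp_px": disp, "score": score, "valid": valid}


def uncertainty_sweep(
    facet_sizes=(15, 25, 40),
    grid_spacings=(17,),
    n_pairs: int = 10,
    noise_sd: float = 0.02,
    image_px: int = 220,
    seed: int = 0,
    search_radius_px: int = 4,
):
    """Zero-displacement error of the correlator per facet/grid combination.

    For each combination, ``n_pairs`` independent noisy re-acquisitions of the
    same speckle pattern are correlated against a noisy reference; the mean
    and SD of the (truth: zero) displacements over all nodes and pairs are the
    systematic and random error in pixels.  Facets that do not fit into the
    image are skipped with a warning.  Returns a list of row dicts.
    """
    if not facet_sizes or not grid_spacings:
        raise SchemaError("need at least one facet size / grid spacing combination")
    rng = np.random.default_rng(seed)
    base = synthesize_speckle(image_px, image_px, seed=int(rng.integers(2**31)))
    rows = []
    for facet in facet_sizes:
        for spacing in grid_spacings:
            if facet + 2 * search_radius_px >= image_px:
                warnings.warn(
                    f"facet {facet} px does not fit a {image_px} px image: skipped",
                    stacklevel=2,
                )
                continue
            grid = FacetGrid(facet_size=facet, grid_spacing=spacing)
            errs = []
            for _ in range(n_pairs):
                im_a = SpeckleImage(
                    np.clip(base.pixels + rng.normal(0, noise_sd, base.pixels.shape), 0, 1),
                    base.pixel_size_mm,
                )
                im_b = SpeckleImage(
                    np.clip(base.pixels + rng.normal(0, noise_sd, base.pixels.shape), 0, 1),
                    base.pixel_size_mm,
                )
                res = correlate_pair(im_a, im_b, grid, search_radius_px=search_radius_px)
                errs.append(res["disp_px"][res["valid"]])
            errs = np.concatenate(errs)
            rows.append(
                {
                    "facet_size": facet,
                    "grid_spacing": spacing,
                    "systematic_px": float(errs.mean()),
                    "random_px": float(errs.std(ddof=1)),
                    "n_estimates": int(errs.size),
                }
            )
    return rows
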