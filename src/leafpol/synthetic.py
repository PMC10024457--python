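"""Synthetic leaf-surface data with retained ground truth.

Three generators emulate the measurement chain so every downstream stage can
be tested without real leaves:

* :func:`generate_surface` builds a micrometre-scale epidermal height field
  (periodic cell domes with wavy margins, optional trichomes and wax) plus a
  reflectance texture image.
* :func:`generate_focus_stack` defocuses that texture slice by slice as a
  microscope stage would, with blur growing with the stage-height offset.
* :func:`generate_polarized_scanset` produces a 19-orientation polarized
  reflectance table R(theta, lambda) = D(lambda) + S(lambda) sin^2(theta -
  theta0) + ripple + noise with the diffuse/specular decomposition retained.
* :func:`generate_feature_dataset` draws labeled (R_Qav, DIFF_R) clouds for
  the four surface phenotypes.

Every generator is a pure function of (spec, seed) and always returns its
ground truth alongside the synthetic observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DimensionError, ParameterError

__all__ = [
    "SurfaceSpec",
    "SurfaceTruth",
    "ScanSetSpec",
    "ScanTruth",
    "ClassCloud",
    "FeatureCloudSpec",
    "PHENOTYPE_LABELS",
    "generate_surface",
    "generate_focus_stack",
    "generate_polarized_scanset",
    "generate_feature_dataset",
    "default_feature_spec",
]

PHENOTYPE_LABELS = ("glossy", "glaucous", "hairy", "glabrous")


# ---------------------------------------------------------------------------
# surface / focus stack
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of a synthetic epidermal surface patch.

    Lengths are in micrometres except ``pixel_scale_mm`` (mm/pixel). The
    default patch is sampled at 1 um/pixel so a 128 px field holds a few
    dozen 30-um cells at desk scale; real 500x microscope data instead use
    the 9.8e-5 mm/pixel calibration.
    """

    cell_pitch_um: float = 30.0
    cell_amplitude_um: float = 5.0
    margin_waviness: float = 0.3
    trichome_density: float = 0.0
    trichome_length_um: float = 100.0
    trichome_orientation: Literal["vertical", "horizontal"] = "vertical"
    wax_mode: Literal["none", "glossy_fill", "glaucous_scatter"] = "none"
    field_size: tuple[int, int] = (128, 128)
    pixel_scale_mm: float = 1e-3

    def validate(self) -> None:
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise ParameterError("field_size must be positive")
        if self.pixel_scale_mm <= 0:
            raise ParameterError("pixel_scale_mm must be positive")
        if self.cell_pitch_um <= 0:
            raise ParameterError("cell_pitch_um must be positive")
        if not 0.0 <= self.trichome_density <= 1.0:
            raise ParameterError("trichome_density must lie in [0, 1]")
        if not 0.0 <= self.margin_waviness <= 1.0:
            raise ParameterError("margin_waviness must lie in [0, 1]")
        if self.wax_mode not in ("none", "glossy_fill", "glaucous_scatter"):
            raise ParameterError(f"unknown wax_mode {self.wax_mode!r}")
        if self.trichome_orientation not in ("vertical", "horizontal"):
            raise ParameterError(
                f"unknown trichome_orientation {self.trichome_orientation!r}"
            )


@dataclass
class SurfaceTruth:
    """Ground truth returned with every synthetic surface."""

    height_mm: np.ndarray  # (H, W) surface height in mm
    texture: np.ndarray  # (H, W) reflectance texture in [0, 1]
    cell_polygons: list[np.ndarray]  # ordered (x_px, y_px) rings, one per cell
    trichome_mask: np.ndarray  # (H, W) bool
    spec: SurfaceSpec


def _cell_boundary(
    center: np.ndarray, radius: float, waviness: float, lobes: int, phase: float,
    n_vertices: int = 48,
) -> np.ndarray:
    """Polygon ring of one cell margin; a circle when waviness is zero."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = radius * (1.0 - 0.30 * waviness * (1.0 + np.sin(lobes * phi + phase)) / 2.0)
    return np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])


def generate_surface(spec: SurfaceSpec, seed: int) -> SurfaceTruth:
    """Generate a ground-truth height field and reflectance texture.

    The surface is a grid of cell domes at ``cell_pitch_um`` spacing with
    margins that undulate according to ``margin_waviness``; glossy wax fills
    the inter-cellular grooves (lowering height variance), glaucous wax adds
    fine scattering roughness, and trichomes add ridges plus a coverage mask.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h_px, w_px = spec.field_size
    pitch_px = spec.cell_pitch_um * 1e-3 / spec.pixel_scale_mm
    radius_px = 0.5 * pitch_px

    ny = max(1, int(np.ceil(h_px / pitch_px)) + 2)
    nx = max(1, int(np.ceil(w_px / pitch_px)) + 2)
    gy, gx = np.mgrid[0:ny, 0:nx]
    centers_y = (gy - 0.5) * pitch_px + rng.uniform(-0.08, 0.08, (ny, nx)) * pitch_px
    centers_x = (gx - 0.5) * pitch_px + rng.uniform(-0.08, 0.08, (ny, nx)) * pitch_px
    lobes = rng.integers(4, 8, (ny, nx))
    phases = rng.uniform(0.0, 2.0 * np.pi, (ny, nx))

    rows, cols = np.mgrid[0:h_px, 0:w_px]
    # nearest cell among the 3x3 neighbourhood of the regular grid slot
    base_i = np.clip(np.round(rows / pitch_px).astype(int), 0, ny - 1)
    base_j = np.clip(np.round(cols / pitch_px).astype(int), 0, nx - 1)
    best_d2 = np.full((h_px, w_px), np.inf)
    best_i = base_i.copy()
    best_j = base_j.copy()
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii = np.clip(base_i + di, 0, ny - 1)
            jj = np.clip(base_j + dj, 0, nx - 1)
            d2 = (rows - centers_y[ii, jj]) ** 2 + (cols - centers_x[ii, jj]) ** 2
            closer = d2 < best_d2
            best_d2 = np.where(closer, d2, best_d2)
            best_i = np.where(closer, ii, best_i)
            best_j = np.where(closer, jj, best_j)

    dy = rows - centers_y[best_i, best_j]
    dx = cols - centers_x[best_i, best_j]
    dist = np.sqrt(best_d2)
    phi = np.arctan2(dy, dx)
    k = lobes[best_i, best_j]
    ph = phases[best_i, best_j]
    r_eff = radius_px * (
        1.0 - 0.30 * spec.margin_waviness * (1.0 + np.sin(k * phi + ph)) / 2.0
    )
    frac = np.clip(dist / np.maximum(r_eff, 1e-9), 0.0, 1.0)
    dome = np.cos(0.5 * np.pi * frac) ** 2  # 1 at the cell centre, 0 at the margin
    height_um = spec.cell_amplitude_um * dome

    # wax acts on the cellular relief before trichomes are added
    if spec.wax_mode == "glossy_fill" and spec.cell_amplitude_um > 0:
        fill = 0.75 * spec.cell_amplitude_um
        height_um = np.maximum(height_um, fill)
        height_um = gaussian_filter(height_um, sigma=1.5, mode="nearest")
    elif spec.wax_mode == "glaucous_scatter":
        speckle = rng.normal(0.0, 1.0, height_um.shape)
        speckle = gaussian_filter(speckle, sigma=1.0, mode="nearest")
        height_um = height_um + 0.4 * speckle

    texture = 0.50 + 0.28 * dome + 0.08 * rng.uniform(-1.0, 1.0, (h_px, w_px))

    trichome_mask = np.zeros((h_px, w_px), dtype=bool)
    if spec.trichome_density > 0:
        trichome_mask = _draw_trichomes(spec, rng, (h_px, w_px))
        tri_height_um = (
            spec.trichome_length_um
            if spec.trichome_orientation == "vertical"
            else 0.1 * spec.trichome_length_um
        )
        height_um = np.where(trichome_mask, height_um + tri_height_um, height_um)
        texture = np.where(trichome_mask, 0.9, texture)

    texture = np.clip(texture, 0.0, 1.0)

    # ground-truth cell margin polygons for cells whose centre is in-field
    polygons: list[np.ndarray] = []
    for i in range(ny):
        for j in range(nx):
            cy, cx = centers_y[i, j], centers_x[i, j]
            if 0 <= cy < h_px and 0 <= cx < w_px:
                polygons.append(
                    _cell_boundary(
                        np.array([cx, cy]), radius_px, spec.margin_waviness,
                        int(lobes[i, j]), float(phases[i, j]),
                    )
                )

    return SurfaceTruth(
        height_mm=height_um * 1e-3,
        texture=texture,
        cell_polygons=polygons,
        trichome_mask=trichome_mask,
        spec=spec,
    )


def _draw_trichomes(
    spec: SurfaceSpec, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Stamp trichome footprints until the requested area fraction is met."""
    h_px, w_px = shape
    mask = np.zeros(shape, dtype=bool)
    length_px = spec.trichome_length_um * 1e-3 / spec.pixel_scale_mm
    rows, cols = np.mgrid[0:h_px, 0:w_px]
    target = spec.trichome_density
    for _ in range(100_000):
        if mask.mean() >= target:
            break
        cy = rng.uniform(0, h_px)
        cx = rng.uniform(0, w_px)
        if spec.trichome_orientation == "vertical":
            # seen from above a vertical hair is a small disk
            r = max(1.5, 0.06 * length_px)
            mask |= (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
        else:
            ang = rng.uniform(0.0, np.pi)
            ux, uy = np.cos(ang), np.sin(ang)
            t = (cols - cx) * ux + (rows - cy) * uy
            d = np.abs(-(cols - cx) * uy + (rows - cy) * ux)
            half = 0.5 * length_px
            mask |= (np.abs(t) <= half) & (d <= 1.2)
    return mask


@dataclass
class FocusStack:
    """An ordered defocus series with its stage heights (mm)."""

    images: list[np.ndarray]
    stage_heights: np.ndarray

    def __post_init__(self) -> None:
        self.stage_heights = np.asarray(self.stage_heights, dtype=float)
        if len(self.images) < 2:
            raise DimensionError("a focus stack needs at least 2 images")
        if len(self.images) != len(self.stage_heights):
            raise DimensionError("one stage height per image required")
        shape = self.images[0].shape
        if any(im.shape != shape for im in self.images):
            raise DimensionError("all stack images must share one shape")
        diffs = np.diff(self.stage_heights)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise DimensionError("stage heights must be strictly monotone")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def n_images(self) -> int:
        return len(self.images)


def generate_focus_stack(
    height_mm: np.ndarray,
    texture: np.ndarray,
    stage_start_mm: float,
    stage_step_mm: float,
    n_images: int,
    blur_coefficient: float = 3000.0,
    n_blur_levels: int = 12,
    max_sigma_px: float = 12.0,
) -> tuple[FocusStack, np.ndarray]:
    """Defocus ``texture`` over a known surface at each stage height.

    Image ``i`` is the texture blurred per pixel with a Gaussian of sigma =
    ``blur_coefficient`` (px/mm) x |stage_height_i - height_mm(pixel)|,
    approximated by compositing a small bank of uniformly blurred copies.
    Returns the stack together with the ground-truth best-focus index map
    (the stage height nearest the surface at each pixel).
    """
    height_mm = np.asarray(height_mm, dtype=float)
    texture = np.asarray(texture, dtype=float)
    if height_mm.shape != texture.shape:
        raise DimensionError("height field and texture shapes differ")
    if n_images < 2:
        raise ParameterError("n_images must be at least 2")
    if stage_step_mm <= 0:
        raise ParameterError("stage_step_mm must be positive")

    heights = stage_start_mm + stage_step_mm * np.arange(n_images)
    images = []
    for z in heights:
        sigma = np.minimum(blur_coefficient * np.abs(z - height_mm), max_sigma_px)
        if blur_coefficient == 0 or sigma.max() == 0:
            images.append(texture.copy())
            continue
        levels = np.linspace(0.0, sigma.max(), n_blur_levels)
        bank = np.stack(
            [texture if s == 0 else gaussian_filter(texture, s, mode="nearest")
             for s in levels]
        )
        idx = np.argmin(np.abs(sigma[None, :, :] - levels[:, None, None]), axis=0)
        images.append(np.take_along_axis(bank, idx[None], axis=0)[0])

    truth_index = np.argmin(
        np.abs(heights[:, None, None] - height_mm[None, :, :]), axis=0
    )
    return FocusStack(images=images, stage_heights=heights), truth_index


# ---------------------------------------------------------------------------
# polarized scan sets
# ---------------------------------------------------------------------------

ORIENTATIONS_DEG = np.arange(0, 91, 5)

#: wavelengths (nm) the feature extraction depends on
RQAV_WINDOW_NM = (500.0, 900.0)
DIFF_R_NUM_NM = 765.0
DIFF_R_DEN_NM = 680.0


@dataclass(frozen=True)
class ScanSetSpec:
    """Parameters of a synthetic Brewster-angle polarizer sweep.

    The diffuse term is a parametric green-leaf curve (green bump + logistic
    red edge to an NIR plateau); the specular term is spectrally flat
    ("white") with optional thin-film ripple, modulated by sin^2 of the
    polarizer orientation relative to a tilt offset.
    """

    diffuse_base: float = 0.03
    green_peak_amplitude: float = 0.04
    green_peak_center_nm: float = 550.0
    green_peak_width_nm: float = 35.0
    red_edge_center_nm: float = 710.0
    red_edge_width_nm: float = 14.0
    nir_plateau: float = 0.42
    specular_level: float = 4e-4  # R_Q = S/2 -> 2e-4, mid printed range
    tilt_offset_deg: float = 0.0
    ripple_amplitude: float = 0.0
    ripple_period_nm: float = 60.0
    noise_sd: float = 0.0
    dark_level: float = 0.0
    transmittance_level: float = 1.0
    wavelength_grid_nm: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 1701.0, 5.0)
    )

    def validate(self) -> None:
        grid = np.asarray(self.wavelength_grid_nm, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ParameterError("wavelength grid must be strictly increasing")
        lo, hi = RQAV_WINDOW_NM
        for needed in (lo, hi, DIFF_R_DEN_NM, DIFF_R_NUM_NM):
            if not (grid[0] <= needed <= grid[-1]):
                raise ParameterError(
                    f"wavelength grid must bracket {needed:g} nm"
                )
        if self.specular_level < 0 or self.diffuse_base < 0:
            raise ParameterError("diffuse and specular levels must be >= 0")


@dataclass
class ScanTruth:
    """Diffuse/specular decomposition behind a synthetic scan set."""

    diffuse: np.ndarray  # D(lambda)
    specular: np.ndarray  # S(lambda), ripple excluded
    wavelength_nm: np.ndarray


def diffuse_leaf_curve(spec: ScanSetSpec) -> np.ndarray:
    """Parametric green-leaf diffuse reflectance on the spec's grid."""
    lam = np.asarray(spec.wavelength_grid_nm, dtype=float)
    green = spec.green_peak_amplitude * np.exp(
        -(((lam - spec.green_peak_center_nm) / spec.green_peak_width_nm) ** 2)
    )
    red_edge = spec.nir_plateau / (
        1.0 + np.exp(-(lam - spec.red_edge_center_nm) / spec.red_edge_width_nm)
    )
    return spec.diffuse_base + green + red_edge


def generate_polarized_scanset(spec: ScanSetSpec, seed: int):
    """Simulate a 19-orientation polarizer sweep with known decomposition.

    Returns ``(scanset, truth)`` where the scan set is a
    :class:`leafpol.spectral.PolarizedScanSet` (raw, i.e. dark and
    transmittance applied if nonzero) and the truth carries D and S.
    """
    from .spectral import PolarizedScanSet  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(seed)
    lam = np.asarray(spec.wavelength_grid_nm, dtype=float)
    D = diffuse_leaf_curve(spec)
    S = np.full_like(lam, float(spec.specular_level))
    ripple = spec.ripple_amplitude * np.sin(
        2.0 * np.pi * (lam - lam[0]) / spec.ripple_period_nm
        + rng.uniform(0, 2 * np.pi)
    )
    s_eff = np.clip(S + ripple, 0.0, None)

    mod = np.sin(np.deg2rad(ORIENTATIONS_DEG - spec.tilt_offset_deg)) ** 2
    refl = D[:, None] + s_eff[:, None] * mod[None, :]
    if spec.noise_sd > 0:
        refl = refl + rng.normal(0.0, spec.noise_sd, refl.shape)

    dark = np.full_like(lam, float(spec.dark_level))
    trans = np.full_like(lam, float(spec.transmittance_level))
    raw = refl * trans[:, None] + dark[:, None]

    scanset = PolarizedScanSet(
        wavelength_nm=lam,
        reflectance=raw,
        orientations_deg=ORIENTATIONS_DEG.copy(),
        dark_reference=dark,
        polarizer_transmittance=trans,
    )
    return scanset, ScanTruth(diffuse=D, specular=S, wavelength_nm=lam)


# ---------------------------------------------------------------------------
# feature clouds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassCloud:
    """Gaussian (R_Qav, DIFF_R) cloud for one phenotype, with hard bounds."""

    mean: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]
    rqav_bounds: tuple[float, float] | None = None
    diffr_bounds: tuple[float, float] | None = (0.2, None)  # type: ignore[assignment]

    def cov_array(self) -> np.ndarray:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ParameterError("covariance must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise ParameterError("covariance must be positive definite")
        return c


@dataclass(frozen=True)
class FeatureCloudSpec:
    """Class-conditional feature-cloud specification."""

    classes: dict[str, ClassCloud]
    n_per_class: int = 50

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ParameterError("n_per_class must be at least 2")
        for cloud in self.classes.values():
            cloud.cov_array()


def default_feature_spec(n_per_class: int = 50) -> FeatureCloudSpec:
    """Default phenotype clouds calibrated to the printed feature ranges.

    Glabrous R_Qav is truncated to [0.48e-4, 4.32e-4]; non-glabrous classes
    to [0.30e-4, 19.63e-4] with only glossy extending above 8e-4 and hairy
    held below ~3e-4 (predominantly under 2e-4). DIFF_R clouds are
    approximate: the exemplar tables and qualitative statements (glaucous
    and very hairy leaves share a depressed red-edge ratio) are the only
    guidance.
    """
    classes = {
        "glossy": ClassCloud(
            mean=(6.0e-4, 9.0),
            cov=((3.2e-4**2, 0.0), (0.0, 2.2**2)),
            rqav_bounds=(1.0e-4, 19.63e-4),
        ),
        "glaucous": ClassCloud(
            mean=(1.4e-4, 4.8),
            cov=((0.7e-4**2, 0.0), (0.0, 1.3**2)),
            rqav_bounds=(0.30e-4, 8.0e-4),
        ),
        "hairy": ClassCloud(
            mean=(1.1e-4, 5.6),
            cov=((0.45e-4**2, 0.0), (0.0, 1.4**2)),
            rqav_bounds=(0.30e-4, 3.0e-4),
        ),
        "glabrous": ClassCloud(
            mean=(2.0e-4, 8.3),
            cov=((0.85e-4**2, 0.0), (0.0, 2.2**2)),
            rqav_bounds=(0.48e-4, 4.32e-4),
        ),
    }
    return FeatureCloudSpec(classes=classes, n_per_class=n_per_class)


def _truncated_mvn(
    rng: np.random.Generator, cloud: ClassCloud, n: int
) -> np.ndarray:
    """Rejection-sample a bounded bivariate normal."""
    mean = np.asarray(cloud.mean, dtype=float)
    cov = cloud.cov_array()
    out = np.empty((0, 2))
    for _ in range(1000):
        draw = rng.multivariate_normal(mean, cov, size=2 * n + 16)
        keep = np.ones(len(draw), dtype=bool)
        if cloud.rqav_bounds is not None:
            lo, hi = cloud.rqav_bounds
            keep &= (draw[:, 0] >= lo) & (draw[:, 0] <= hi)
        if cloud.diffr_bounds is not None:
            lo, hi = cloud.diffr_bounds
            if lo is not None:
                keep &= draw[:, 1] >= lo
            if hi is not None:
                keep &= draw[:, 1] <= hi
        out = np.vstack([out, draw[keep]])
        if len(out) >= n:
            return out[:n]
    raise ParameterError("truncation bounds reject nearly all samples")


def generate_feature_dataset(spec: FeatureCloudSpec, seed: int) -> pd.DataFrame:
    """Draw a labeled (R_Qav, DIFF_R) table, deterministic under the seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for label in sorted(spec.classes):
        cloud = spec.classes[label]
        draw = _truncated_mvn(rng, cloud, spec.n_per_class)
        frames.append(
            pd.DataFrame(
                {"R_Qav": draw[:, 0], "DIFF_R": draw[:, 1], "label": label}
            )
        )
    return pd.concat(frames, ignore_index=True)


def study_class_counts() -> dict[str, int]:
    """Per-phenotype sample counts of the reference study dataset."""
    return {"glossy": 104, "glaucous": 110, "hairy": 39, "glabrous": 96}


def generate_study_sized_dataset(seed: int) -> pd.DataFrame:
    """Labeled feature table with the study's per-class composition."""
    counts = study_class_counts()
    base = default_feature_spec()
    frames = []
    for i, label in enumerate(sorted(counts)):
        one = FeatureCloudSpec(
            classes={label: base.classes[label]}, n_per_class=counts[label]
        )
        frames.append(generate_feature_dataset(one, seed + i))
    return pd.concat(frames, ignore_index=True)
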