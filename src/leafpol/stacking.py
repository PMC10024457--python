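"""Shape-from-focus: composite image and metric depth map from a focus stack.

Each pixel is assigned the stack slice on which its local intensity gradient
is largest; the stage height of that slice is the pixel's depth. The raw
(quantized) depth map is then smoothed with a symmetric 10x10 median filter
followed by a 15x15 Gaussian filter to suppress selection noise and recover
the shape of individual cells. The composite image is the per-pixel mosaic of
the selected slices.

Conventions for the under-determined details: the sharpness operator is the
L2 magnitude of central differences (one-sided at borders, luma for RGB); the
even 10x10 median window places its origin pixel at window index (5, 5) with
nearest-edge padding; the 15x15 Gaussian uses sigma = 2.5 px; ties in
sharpness go to the lowest stack index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter

from .errors import DimensionError, ParameterError
from .synthetic import FocusStack

__all__ = [
    "FocusStack",
    "SurfaceReconstruction",
    "PointCloud",
    "sharpness_map",
    "stack_focus",
    "reconstruct_3d",
    "DEFAULT_PIXEL_SCALE_500X_MM",
]

#: mm/pixel at 500x magnification from the calibration slide
DEFAULT_PIXEL_SCALE_500X_MM = 9.8e-5

MEDIAN_SIZE = 10
GAUSSIAN_SIZE = 15
GAUSSIAN_SIGMA = GAUSSIAN_SIZE / 6.0  # kernel spans ~ +-3 sigma


def sharpness_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel gradient magnitude of an intensity image.

    Central differences in the interior, forward/backward at borders
    (``np.gradient`` semantics); RGB images are converted to luma first.
    A constant image maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        image = image[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise DimensionError("sharpness_map needs a 2-D image of at least 3x3")
    gy, gx = np.gradient(image)
    return np.hypot(gy, gx)


@dataclass
class SurfaceReconstruction:
    """In-focus composite plus the selected-slice depth information.

    ``depth_raw_mm`` holds the unsmoothed per-pixel stage heights (every
    value is a member of the stack's stage heights); ``depth_mm`` is the
    median+Gaussian smoothed map used for 3-D metrics.
    """

    composite: np.ndarray
    focus_index: np.ndarray
    depth_raw_mm: np.ndarray
    depth_mm: np.ndarray
    stage_heights: np.ndarray
    pixel_scale_mm: float | None = None


def _smooth(depth: np.ndarray) -> np.ndarray:
    # scipy's even-size median window matches the (5,5)-origin convention
    out = median_filter(depth, size=MEDIAN_SIZE, mode="nearest")
    return gaussian_filter(
        out, sigma=GAUSSIAN_SIGMA, mode="nearest",
        truncate=(GAUSSIAN_SIZE // 2) / GAUSSIAN_SIGMA,
    )


def stack_focus(
    stack: FocusStack,
    pixel_scale_mm: float | None = None,
    smooth_composite: bool = False,
) -> SurfaceReconstruction:
    """Select the sharpest slice per pixel and build the depth map.

    Parameters
    ----------
    stack
        Validated focus stack (ordered images + stage heights).
    pixel_scale_mm
        Lateral calibration attached to the reconstruction for later 3-D
        mapping; not used in the selection itself.
    smooth_composite
        Also run the median+Gaussian pair over the composite image. The
        depth map is always smoothed.
    """
    sharp = np.stack([sharpness_map(im) for im in stack.images])
    focus_index = np.argmax(sharp, axis=0)  # first max -> lowest index on ties
    cube = np.stack([np.asarray(im, dtype=float) for im in stack.images])
    composite = np.take_along_axis(cube, focus_index[None], axis=0)[0]
    depth_raw = stack.stage_heights[focus_index]
    depth = _smooth(depth_raw)
    if smooth_composite:
        composite = _smooth(composite)
    return SurfaceReconstruction(
        composite=composite,
        focus_index=focus_index,
        depth_raw_mm=depth_raw,
        depth_mm=depth,
        stage_heights=stack.stage_heights.copy(),
        pixel_scale_mm=pixel_scale_mm,
    )


@dataclass
class PointCloud:
    """Metric (x, y, z) coordinates with per-vertex texture."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray
    texture: np.ndarray


def reconstruct_3d(
    recon: SurfaceReconstruction,
    pixel_scale_mm: float | None = None,
    use_raw_depth: bool = False,
) -> PointCloud:
    """Map every pixel to metric 3-D space.

    x = column * pixel_scale, y = row * pixel_scale, z = depth; the composite
    intensity is attached per vertex so the image can be draped over the
    surface plot.
    """
    scale = pixel_scale_mm if pixel_scale_mm is not None else recon.pixel_scale_mm
    if scale is None or scale <= 0:
        raise ParameterError("a positive pixel scale (mm/pixel) is required")
    depth = recon.depth_raw_mm if use_raw_depth else recon.depth_mm
    rows, cols = np.mgrid[0 : depth.shape[0], 0 : depth.shape[1]]
    return PointCloud(
        x_mm=cols.ravel() * scale,
        y_mm=rows.ravel() * scale,
        z_mm=depth.ravel().astype(float),
        texture=recon.composite.ravel().astype(float),
    )
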