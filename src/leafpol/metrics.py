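"""Cell-morphology and pubescence metrics from traced polygons and depth maps.

Three per-cell metrics are computed from a manually traced cell outline:

* cell size — polygon area converted to square micrometres;
* margin undulation — the ratio A1/A2 of the traced area to the area of its
  convex hull, 1 for a perfectly convex ("round") cell and decreasing as the
  margin undulates;
* cell cap aspect ratio — cell width over cell height, where height is the
  depth difference between the highest and lowest point inside the trace and
  width is twice the planar peak-to-valley distance (the run from peak to
  valley is treated as half a cell width).

Pubescence coverage is the percentage of the field covered by traced hairs;
for dense, uniform pubescence a count-times-mean-hair-area approximation is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as raster_polygon

from .errors import DimensionError, FlatCellError, GeometryError, ParameterError

__all__ = [
    "CellTrace",
    "CellMetrics",
    "SampleSurfaceSummary",
    "cell_size",
    "margin_undulation",
    "cap_aspect_ratio",
    "summarize_sample",
    "pubescence_coverage",
    "coverage_by_count",
    "rasterized_cell_size",
]


@dataclass
class CellTrace:
    """An ordered, simple polygon traced around one epidermal cell (pixels)."""

    vertices: np.ndarray  # (N, 2) as (x_px, y_px)
    magnification: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("a trace needs at least 3 (x, y) vertices")
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]) and v.shape[0] > 3:
            v = v[:-1]
        self.vertices = v
        poly = Polygon(v)
        if not poly.is_valid or poly.area == 0:
            raise GeometryError("trace is self-intersecting or degenerate")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon


@dataclass
class CellMetrics:
    """Derived morphology of one traced cell."""

    cell_size_um2: float
    margin_undulation: float
    cap_aspect_ratio: float | None  # None when the cell region is flat
    peak: tuple[float, float, float] | None = None  # (x_px, y_px, z_mm)
    valley: tuple[float, float, float] | None = None


def cell_size(trace: CellTrace, pixel_scale_mm: float) -> float:
    """Traced cell area in square micrometres.

    Continuous (shoelace) polygon area in px^2 scaled by the pixel size;
    agrees with pixel-count rasterization to within ~2% at realistic cell
    sizes (see :func:`rasterized_cell_size`).
    """
    if pixel_scale_mm <= 0:
        raise ParameterError("pixel_scale_mm must be positive")
    um_per_px = pixel_scale_mm * 1000.0
    return trace.polygon.area * um_per_px**2


def rasterized_cell_size(trace: CellTrace, pixel_scale_mm: float) -> float:
    """Pixel-count variant of :func:`cell_size` (the original procedure)."""
    if pixel_scale_mm <= 0:
        raise ParameterError("pixel_scale_mm must be positive")
    x, y = trace.vertices[:, 0], trace.vertices[:, 1]
    rr, cc = raster_polygon(y - y.min(), x - x.min())
    um_per_px = pixel_scale_mm * 1000.0
    return float(len(rr)) * um_per_px**2


def margin_undulation(trace: CellTrace) -> float:
    """Ratio of traced area to convex-hull area, in (0, 1].

    Equals 1 exactly when the trace is convex; decreases as the margin
    undulates into the hull.
    """
    hull_area = trace.polygon.convex_hull.area
    if hull_area == 0:
        raise GeometryError("convex hull has zero area")
    return trace.polygon.area / hull_area


def _interior_pixels(trace: CellTrace, shape: tuple[int, int]):
    x, y = trace.vertices[:, 0], trace.vertices[:, 1]
    rr, cc = raster_polygon(y, x, shape=shape)
    if len(rr) == 0:
        raise GeometryError("trace does not overlap the depth map")
    return rr, cc


def cap_aspect_ratio(
    trace: CellTrace, depth_mm: np.ndarray, pixel_scale_mm: float
) -> CellMetrics:
    """Cell cap aspect ratio of one traced cell over a depth map.

    Locates the highest (peak) and lowest (valley) depth within the trace;
    width = 2 * c * sqrt((x_peak - x_valley)^2 + (y_peak - y_valley)^2) in mm
    with c the pixel scale in mm/pixel, height = z_peak - z_valley in mm.
    Returns the full :class:`CellMetrics` (size and undulation included).

    Raises
    ------
    FlatCellError
        If the region is perfectly flat (height zero); such cells are
        excluded from sample averages rather than reported as infinite.
    """
    depth_mm = np.asarray(depth_mm, dtype=float)
    if depth_mm.ndim != 2:
        raise DimensionError("depth map must be 2-D")
    if pixel_scale_mm <= 0:
        raise ParameterError("pixel_scale_mm must be positive")
    rr, cc = _interior_pixels(trace, depth_mm.shape)
    z = depth_mm[rr, cc]
    i_peak = int(np.argmax(z))
    i_valley = int(np.argmin(z))
    z_peak, z_valley = float(z[i_peak]), float(z[i_valley])
    peak = (float(cc[i_peak]), float(rr[i_peak]), z_peak)
    valley = (float(cc[i_valley]), float(rr[i_valley]), z_valley)
    height = z_peak - z_valley
    if height == 0:
        raise FlatCellError("flat cell region: cap aspect ratio undefined")
    planar = np.hypot(peak[0] - valley[0], peak[1] - valley[1])
    width = 2.0 * pixel_scale_mm * planar
    return CellMetrics(
        cell_size_um2=cell_size(trace, pixel_scale_mm),
        margin_undulation=margin_undulation(trace),
        cap_aspect_ratio=width / height,
        peak=peak,
        valley=valley,
    )


@dataclass
class SampleSurfaceSummary:
    """Per-sample mean over the (typically five) cell tracings."""

    mean_cell_size_um2: float
    mean_margin_undulation: float
    mean_cap_aspect_ratio: float | None
    n_tracings: int
    n_valid_aspect: int
    pubescence_coverage_pct: float | None = None
    usable: bool = True


def summarize_sample(
    metrics: list[CellMetrics],
    pubescence_coverage_pct: float | None = None,
) -> SampleSurfaceSummary:
    """Average cell metrics over a sample's tracings.

    Cells whose cap aspect ratio was undefined (flat region) contribute to
    the size/undulation means but are excluded from the aspect-ratio mean;
    the count of valid ratios is recorded.
    """
    if not metrics:
        raise ParameterError("at least one valid tracing is required")
    sizes = [m.cell_size_um2 for m in metrics]
    undul = [m.margin_undulation for m in metrics]
    ratios = [m.cap_aspect_ratio for m in metrics if m.cap_aspect_ratio is not None]
    return SampleSurfaceSummary(
        mean_cell_size_um2=float(np.mean(sizes)),
        mean_margin_undulation=float(np.mean(undul)),
        mean_cap_aspect_ratio=float(np.mean(ratios)) if ratios else None,
        n_tracings=len(metrics),
        n_valid_aspect=len(ratios),
        pubescence_coverage_pct=pubescence_coverage_pct,
        usable=bool(ratios),
    )


def pubescence_coverage(hair_mask: np.ndarray) -> float:
    """Percent of the field covered by traced hairs."""
    mask = np.asarray(hair_mask)
    if mask.size == 0:
        raise DimensionError("hair mask is empty")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def coverage_by_count(
    hair_count: int, sample_hair_areas_px2, field_area_px2: float
) -> float:
    """Coverage approximation for dense, consistent trichomes (> ~25%).

    Percent coverage estimated as count x mean area of five sampled hairs
    over the field area.
    """
    areas = np.asarray(sample_hair_areas_px2, dtype=float)
    if areas.shape != (5,):
        raise ParameterError("exactly 5 sampled hair areas are required")
    if hair_count < 0:
        raise ParameterError("hair count must be nonnegative")
    if field_area_px2 <= 0:
        raise ParameterError("field area must be positive")
    return 100.0 * hair_count * float(areas.mean()) / field_area_px2
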