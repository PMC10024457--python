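"""On-disk formats, configuration and the end-to-end pipeline driver.

Formats
-------
* focus stacks: multi-page TIFF (or a directory of single images) plus a
  JSON stage manifest ``{"start_mm", "step_mm", "n", "files"?}``;
* scan sets: CSV with column 1 ``wavelength_nm`` and columns 2-20 labeled by
  polarizer orientation in degrees (0, 5, ..., 90); dark-reference and
  polarizer-transmittance spectra as two-column CSV (wavelength_nm, value);
* traces: CSV vertex lists (x_px, y_px per row, one file per cell);
* masks: PNG/TIFF binary images; depth maps: 32-bit float TIFF in mm;
  composites: 16-bit TIFF;
* feature tables: CSV with header ``R_Qav,DIFF_R,label``; models and
  evaluations: JSON.

CSV dialect everywhere: comma separator, '.' decimal, UTF-8, mandatory
header row. Wavelength references are linearly interpolated to the scan
grid, never extrapolated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .classify import PhenotypeQDA, monte_carlo_evaluation
from .errors import FormatError, LeafPolError, PipelineError
from .metrics import CellTrace
from .spectral import PolarizedScanSet, features_from_scanset
from .stacking import FocusStack, stack_focus

logger = logging.getLogger("leafpol")

__all__ = [
    "PipelineConfig",
    "read_focus_stack",
    "write_focus_stack",
    "read_scanset",
    "write_scanset",
    "read_reference_spectrum",
    "write_reference_spectrum",
    "read_trace",
    "write_trace",
    "read_mask",
    "write_mask",
    "write_depth_map",
    "read_depth_map",
    "write_point_cloud_ply",
    "run_pipeline",
]

EXPECTED_ORIENTATIONS = list(range(0, 91, 5))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Defaults and switches for a full pipeline invocation."""

    magnification: int = 500
    pixel_scale_mm: float = 9.8e-5
    stage_step_mm: float = 0.001  # 0.005 at 100x, 0.001 at 500x
    smooth_composite: bool = False
    per_wavelength_extrema: bool = False
    rqav_window_nm: tuple[float, float] = (500.0, 900.0)
    diffr_wavelengths_nm: tuple[float, float] = (765.0, 680.0)
    n_train: int = 150
    n_runs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnification not in (100, 500):
            raise FormatError("magnification must be 100 or 500")
        if self.pixel_scale_mm <= 0 or self.stage_step_mm <= 0:
            raise FormatError("physical scales must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["rqav_window_nm"] = tuple(payload.get("rqav_window_nm", (500, 900)))
        payload["diffr_wavelengths_nm"] = tuple(
            payload.get("diffr_wavelengths_nm", (765, 680))
        )
        return cls(**payload)


def pixel_scale_um_per_px(pixel_scale_mm: float) -> float:
    """Convert a mm/pixel calibration to micrometres per pixel."""
    if pixel_scale_mm <= 0:
        raise FormatError("pixel scale must be positive")
    return pixel_scale_mm * 1000.0


# ---------------------------------------------------------------------------
# focus stacks
# ---------------------------------------------------------------------------


def write_focus_stack(stack: FocusStack, tiff_path, manifest_path) -> None:
    """Multi-page float32 TIFF plus a JSON stage manifest."""
    tifffile.imwrite(
        tiff_path, np.stack(stack.images).astype(np.float32), photometric="minisblack"
    )
    manifest = {
        "start_mm": float(stack.stage_heights[0]),
        "step_mm": float(np.diff(stack.stage_heights).mean()),
        "n": int(stack.n_images),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _load_manifest(manifest) -> dict:
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = json.load(fh)
    for key in ("start_mm", "step_mm", "n"):
        if key not in manifest:
            raise FormatError(f"stage manifest missing key {key!r}")
    return manifest


def read_focus_stack(path, manifest) -> FocusStack:
    """Read a multi-page TIFF or image directory ordered by the manifest.

    Image intensities are normalized to float in [0, 1] (integer dtypes are
    divided by their type maximum). For a directory, an optional manifest
    ``files`` list fixes the slice order regardless of filename sort.
    """
    manifest = _load_manifest(manifest)
    path = Path(path)
    if path.is_dir():
        if "files" in manifest:
            files = [path / f for f in manifest["files"]]
        else:
            files = sorted(p for p in path.iterdir() if p.suffix.lower() in
                           (".tif", ".tiff", ".png"))
        if len(files) != manifest["n"]:
            raise FormatError(
                f"manifest n={manifest['n']} but directory has {len(files)} images"
            )
        images = [iio.imread(f) for f in files]
    else:
        cube = tifffile.imread(path)
        if cube.ndim == 2:
            cube = cube[None]
        if cube.shape[0] != manifest["n"]:
            raise FormatError(
                f"manifest n={manifest['n']} but TIFF has {cube.shape[0]} pages"
            )
        images = list(cube)
    norm = []
    for im in images:
        im = np.asarray(im)
        if im.ndim == 3:  # RGB -> luma
            im = im[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
        if np.issubdtype(im.dtype, np.integer):
            im = im.astype(float) / np.iinfo(im.dtype).max
        norm.append(np.asarray(im, dtype=float))
    if len({im.shape for im in norm}) != 1:
        raise FormatError("stack images do not share one shape")
    heights = manifest["start_mm"] + manifest["step_mm"] * np.arange(manifest["n"])
    return FocusStack(images=norm, stage_heights=heights)


def write_depth_map(depth_mm: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(depth_mm, dtype=np.float32))


def read_depth_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_composite(composite: np.ndarray, path) -> None:
    arr = np.asarray(composite, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    tifffile.imwrite(path, (scaled * 65535).astype(np.uint16))


def write_point_cloud_ply(cloud, path) -> None:
    """ASCII PLY export of a reconstructed surface point cloud."""
    n = cloud.x_mm.size
    header = "\n".join(
        [
            "ply",
            "format ascii 1.0",
            f"element vertex {n}",
            "property float x",
            "property float y",
            "property float z",
            "property float intensity",
            "end_header",
        ]
    )
    body = np.column_stack([cloud.x_mm, cloud.y_mm, cloud.z_mm, cloud.texture])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt="%.6g")


# ---------------------------------------------------------------------------
# scan sets and spectra
# ---------------------------------------------------------------------------


def write_scanset(scanset: PolarizedScanSet, path) -> None:
    cols = {"wavelength_nm": scanset.wavelength_nm}
    for j, deg in enumerate(scanset.orientations_deg.astype(int)):
        cols[str(int(deg))] = scanset.reflectance[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_reference_spectrum(wavelength_nm, values, path) -> None:
    pd.DataFrame({"wavelength_nm": wavelength_nm, "value": values}).to_csv(
        path, index=False
    )


def read_reference_spectrum(path, grid_nm: np.ndarray) -> np.ndarray:
    """Two-column reference CSV interpolated linearly onto ``grid_nm``."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "value"):
        if col not in df.columns:
            raise FormatError(f"reference spectrum missing column {col!r}")
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    val = df["value"].to_numpy(dtype=float)
    order = np.argsort(lam)
    lam, val = lam[order], val[order]
    if grid_nm[0] < lam[0] or grid_nm[-1] > lam[-1]:
        raise FormatError("reference spectrum does not cover the scan grid")
    if not np.array_equal(lam, grid_nm):
        logger.warning("reference spectrum interpolated onto the scan grid")
    return np.interp(grid_nm, lam, val)


def read_scanset(path, dark_path=None, transmittance_path=None) -> PolarizedScanSet:
    """Read a 19-orientation scan CSV, reordering shuffled columns.

    Orientation headers must parse as the degrees 0..90 in 5-degree steps;
    missing orientations are reported by name.
    """
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise FormatError("scan CSV missing 'wavelength_nm' column")
    found: dict[int, str] = {}
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        try:
            deg = int(round(float(col)))
        except ValueError:
            raise FormatError(f"orientation column {col!r} is not a number")
        found[deg] = col
    missing = [d for d in EXPECTED_ORIENTATIONS if d not in found]
    if missing:
        raise FormatError(
            f"missing orientation columns (deg): {missing}; found {sorted(found)}"
        )
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    refl = np.column_stack(
        [df[found[d]].to_numpy(dtype=float) for d in EXPECTED_ORIENTATIONS]
    )
    dark = read_reference_spectrum(dark_path, lam) if dark_path else None
    trans = (
        read_reference_spectrum(transmittance_path, lam)
        if transmittance_path
        else None
    )
    return PolarizedScanSet(
        wavelength_nm=lam,
        reflectance=refl,
        orientations_deg=np.array(EXPECTED_ORIENTATIONS, dtype=float),
        dark_reference=dark,
        polarizer_transmittance=trans,
    )


# ---------------------------------------------------------------------------
# traces and masks
# ---------------------------------------------------------------------------


def write_trace(trace: CellTrace, path) -> None:
    pd.DataFrame(trace.vertices, columns=["x_px", "y_px"]).to_csv(path, index=False)


def read_trace(path) -> CellTrace:
    df = pd.read_csv(path)
    for col in ("x_px", "y_px"):
        if col not in df.columns:
            raise FormatError(f"trace CSV missing column {col!r}")
    return CellTrace(vertices=df[["x_px", "y_px"]].to_numpy(dtype=float))


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class SpectralSample:
    """One spectral sample on disk (scan CSV + optional references/label)."""

    sample_id: str
    scan_path: str
    dark_path: str | None = None
    transmittance_path: str | None = None
    label: str | None = None


def run_pipeline(
    config: PipelineConfig,
    spectral_samples: list[SpectralSample],
    out_dir,
    stack_inputs: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Run scans -> features -> (fit + Monte-Carlo evaluation) over a batch.

    ``stack_inputs`` optionally lists (sample_id, stack_path, manifest_path)
    focus stacks; each produces a composite and depth-map TIFF. A sample
    whose stage fails is logged and skipped; if every sample fails the
    pipeline errors. Labeled feature rows (all four phenotype labels not
    required, but >=3 rows per present class) additionally produce
    ``model.json`` and ``evaluation.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    logger.info(
        "leafpol %s pipeline: %d spectral samples, seed %d",
        __version__, len(spectral_samples), config.seed,
    )

    rows = []
    failures = 0
    for sample in spectral_samples:
        try:
            scanset = read_scanset(
                sample.scan_path, sample.dark_path, sample.transmittance_path
            )
            feats = features_from_scanset(
                scanset, per_wavelength=config.per_wavelength_extrema
            )
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "R_Qav": feats.R_Qav,
                    "DIFF_R": feats.DIFF_R,
                    "min_idx_deg": feats.min_orientation_deg,
                    "max_idx_deg": feats.max_orientation_deg,
                    "label": sample.label,
                }
            )
        except LeafPolError as exc:
            failures += 1
            logger.error("sample %s failed: %s", sample.sample_id, exc)

    for sample_id, stack_path, manifest_path in stack_inputs or []:
        try:
            stack = read_focus_stack(stack_path, manifest_path)
            recon = stack_focus(
                stack,
                pixel_scale_mm=config.pixel_scale_mm,
                smooth_composite=config.smooth_composite,
            )
            write_depth_map(recon.depth_mm, out / f"{sample_id}_depth.tiff")
            write_composite(recon.composite, out / f"{sample_id}_composite.tiff")
        except LeafPolError as exc:
            failures += 1
            logger.error("stack %s failed: %s", sample_id, exc)

    if not rows and (stack_inputs or spectral_samples):
        if failures:
            raise PipelineError("every sample failed")
    features = pd.DataFrame(rows)
    features.to_csv(out / "features.csv", index=False)

    labeled = features.dropna(subset=["label"]) if "label" in features else features
    if len(labeled) and labeled["label"].nunique() >= 2:
        counts = labeled["label"].value_counts()
        if counts.min() >= 3:
            res = PhenotypeQDA.from_dataframe(labeled).fit()
            res.to_json(out / "model.json")
            if 0 < config.n_train < len(labeled):
                mc = monte_carlo_evaluation(
                    labeled,
                    n_train=config.n_train,
                    n_runs=config.n_runs,
                    seed=config.seed,
                )
                mc.to_json(out / "evaluation.json")
                mc.per_run_frame().to_csv(out / "evaluation_runs.csv", index=False)
    return features
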