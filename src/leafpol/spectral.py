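"""Polarized-reflectance feature extraction at Brewster-angle geometry.

A scan set holds 19 reflectance-factor spectra taken through a linear
polarizer rotated from 0 deg (parallel to the plane of incidence) to 90 deg
(perpendicular) in 5 deg steps. Specular reflection at the leaf cuticle is
partially polarized, so the polarizer sweep modulates the specular part while
the diffuse (internally scattered) part is unpolarized. Two features
summarise a scan set:

* ``R_Q = (R_max - R_min) / 2`` estimates the polarized (specular)
  bidirectional reflectance factor; its average over 500-900 nm is R_Qav.
* ``DIFF_R = R_min(765 nm) / R_min(680 nm)`` is the red-edge ratio of the
  diffuse (minimum) spectrum.

Because leaf surfaces are rarely aligned perfectly at the 55 deg Brewster
geometry, R_min and R_max are chosen as the lowest/highest measured scans
rather than the nominal 0/90 deg columns. The identity
``R = (R_max + R_min)/2 = R_Q + R_min`` (total reflectance = specular +
diffuse) holds pointwise by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DimensionError,
    FeatureWavelengthError,
    NormalizationError,
    ParameterError,
)

__all__ = [
    "PolarizedScanSet",
    "SpectralFeatures",
    "preprocess",
    "select_extrema",
    "compute_rq",
    "extract_features",
    "features_from_scanset",
    "brewster_angle_deg",
    "RQAV_WINDOW_NM",
    "DIFF_R_WAVELENGTHS_NM",
]

RQAV_WINDOW_NM = (500.0, 900.0)
DIFF_R_WAVELENGTHS_NM = (765.0, 680.0)  # numerator, denominator
TRANSMITTANCE_FLOOR = 1e-6
EXPECTED_ORIENTATIONS = np.arange(0, 91, 5)

#: leaf-cuticle refractive index used for the measurement geometry metadata
CUTICLE_REFRACTIVE_INDEX = 1.45


def brewster_angle_deg(refractive_index: float = CUTICLE_REFRACTIVE_INDEX) -> float:
    """Brewster's angle (degrees from nadir) for a given refractive index.

    arctan(1.45) is about 55 deg, the illumination/viewing geometry at which
    reflected light parallel to the plane of incidence vanishes and the
    polarization of the specular component is maximal. Metadata only: no
    feature computation depends on it.
    """
    if refractive_index <= 0:
        raise ParameterError("refractive index must be positive")
    return math.degrees(math.atan(refractive_index))


@dataclass
class PolarizedScanSet:
    """Reflectance-factor matrix over wavelength x polarizer orientation."""

    wavelength_nm: np.ndarray  # (W,)
    reflectance: np.ndarray  # (W, 19)
    orientations_deg: np.ndarray  # (19,) = 0, 5, ..., 90
    dark_reference: np.ndarray | None = None  # (W,)
    polarizer_transmittance: np.ndarray | None = None  # (W,)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.orientations_deg = np.asarray(self.orientations_deg, dtype=float)
        if self.wavelength_nm.ndim != 1 or np.any(np.diff(self.wavelength_nm) <= 0):
            raise DimensionError("wavelengths must be strictly increasing")
        if self.reflectance.shape != (
            self.wavelength_nm.size,
            self.orientations_deg.size,
        ):
            raise DimensionError("reflectance must be (wavelength x orientation)")
        if not np.array_equal(self.orientations_deg, EXPECTED_ORIENTATIONS):
            raise DimensionError(
                "orientations must be 0..90 deg in 5 deg steps (19 columns)"
            )
        for nm in (*RQAV_WINDOW_NM, *DIFF_R_WAVELENGTHS_NM):
            if not (self.wavelength_nm[0] <= nm <= self.wavelength_nm[-1]):
                raise FeatureWavelengthError(
                    f"wavelength grid does not bracket {nm:g} nm"
                )


@dataclass
class SpectralFeatures:
    """Per-sample spectral summary and the spectra behind it."""

    R_Q: np.ndarray
    R: np.ndarray
    R_min_spectrum: np.ndarray
    R_max_spectrum: np.ndarray
    wavelength_nm: np.ndarray
    R_Qav: float
    DIFF_R: float
    min_orientation_deg: float
    max_orientation_deg: float


def preprocess(raw: PolarizedScanSet) -> PolarizedScanSet:
    """Dark-reference removal and polarizer-transmittance normalization.

    Each orientation column becomes ``(raw - dark) / transmittance`` per
    wavelength. The transmittance (total light measured straight through the
    polarizer, source and sensor aligned) is floored at 1e-6; if it sits at
    or below the floor anywhere on the grid the scan cannot be normalized.
    Absent references are treated as dark = 0 and transmittance = 1.
    """
    dark = (
        raw.dark_reference
        if raw.dark_reference is not None
        else np.zeros_like(raw.wavelength_nm)
    )
    trans = (
        raw.polarizer_transmittance
        if raw.polarizer_transmittance is not None
        else np.ones_like(raw.wavelength_nm)
    )
    dark = np.asarray(dark, dtype=float)
    trans = np.asarray(trans, dtype=float)
    if dark.shape != raw.wavelength_nm.shape or trans.shape != raw.wavelength_nm.shape:
        raise DimensionError("reference spectra must share the wavelength grid")
    if np.any(trans <= TRANSMITTANCE_FLOOR):
        raise NormalizationError(
            "polarizer transmittance at or below the floor on the grid"
        )
    refl = (raw.reflectance - dark[:, None]) / trans[:, None]
    return PolarizedScanSet(
        wavelength_nm=raw.wavelength_nm.copy(),
        reflectance=refl,
        orientations_deg=raw.orientations_deg.copy(),
        dark_reference=None,
        polarizer_transmittance=None,
    )


def _window_mask(wavelength_nm: np.ndarray) -> np.ndarray:
    lo, hi = RQAV_WINDOW_NM
    return (wavelength_nm >= lo) & (wavelength_nm <= hi)


def select_extrema(
    scans: PolarizedScanSet, per_wavelength: bool = False
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Pick the minimum and maximum reflectance scans.

    Default (whole-scan) mode ranks the 19 columns by their mean reflectance
    over 500-900 nm and returns the lowest and highest whole columns, which
    preserves the spectral shape of the diffuse spectrum for DIFF_R. Ties go
    to the 0 deg column for the minimum and the 90 deg column for the
    maximum. ``per_wavelength=True`` instead returns the pointwise
    min/max envelopes (indices then refer to the window-mean ranking).
    """
    mask = _window_mask(scans.wavelength_nm)
    means = scans.reflectance[mask].mean(axis=0)
    # first occurrence -> ties toward 0 deg; last occurrence -> toward 90 deg
    min_idx = int(np.argmin(means))
    max_idx = int(means.size - 1 - np.argmax(means[::-1]))
    if per_wavelength:
        r_min = scans.reflectance.min(axis=1)
        r_max = scans.reflectance.max(axis=1)
    else:
        r_min = scans.reflectance[:, min_idx].copy()
        r_max = scans.reflectance[:, max_idx].copy()
    return r_max, r_min, (min_idx, max_idx)


def compute_rq(r_max: np.ndarray, r_min: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarized BRF ``R_Q = (R_max - R_min)/2`` and total ``R = R_Q + R_min``."""
    r_max = np.asarray(r_max, dtype=float)
    r_min = np.asarray(r_min, dtype=float)
    if r_max.shape != r_min.shape:
        raise DimensionError("R_max and R_min must share one grid")
    r_q = (r_max - r_min) / 2.0
    r = (r_max + r_min) / 2.0
    return r_q, r


def extract_features(
    r_q: np.ndarray,
    r_min: np.ndarray,
    wavelength_nm: np.ndarray,
    indices: tuple[int, int] | None = None,
    r_max: np.ndarray | None = None,
) -> SpectralFeatures:
    """R_Qav and DIFF_R from the R_Q and diffuse spectra.

    R_Qav is the unweighted mean of R_Q over grid points in [500, 900] nm
    inclusive (averaging cancels the thin-film interference ripple that
    cannot be removed by reference correction); DIFF_R is
    R_min(765)/R_min(680) with linear interpolation at off-grid wavelengths.
    """
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    r_q = np.asarray(r_q, dtype=float)
    r_min = np.asarray(r_min, dtype=float)
    if r_q.shape != wavelength_nm.shape or r_min.shape != wavelength_nm.shape:
        raise DimensionError("spectra must share the wavelength grid")
    mask = _window_mask(wavelength_nm)
    if not mask.any():
        raise FeatureWavelengthError("no grid points inside 500-900 nm")
    num_nm, den_nm = DIFF_R_WAVELENGTHS_NM
    for nm in (num_nm, den_nm):
        if not (wavelength_nm[0] <= nm <= wavelength_nm[-1]):
            raise FeatureWavelengthError(f"grid does not bracket {nm:g} nm")
    r765 = float(np.interp(num_nm, wavelength_nm, r_min))
    r680 = float(np.interp(den_nm, wavelength_nm, r_min))
    if r680 <= 0:
        raise ParameterError("diffuse reflectance at 680 nm is not positive")
    if r_max is None:
        r_max = r_min + 2.0 * r_q
    min_idx, max_idx = indices if indices is not None else (-1, -1)
    orient = np.arange(0, 91, 5)
    return SpectralFeatures(
        R_Q=r_q,
        R=r_q + r_min,
        R_min_spectrum=r_min,
        R_max_spectrum=np.asarray(r_max, dtype=float),
        wavelength_nm=wavelength_nm,
        R_Qav=float(r_q[mask].mean()),
        DIFF_R=r765 / r680,
        min_orientation_deg=float(orient[min_idx]) if min_idx >= 0 else float("nan"),
        max_orientation_deg=float(orient[max_idx]) if max_idx >= 0 else float("nan"),
    )


def features_from_scanset(
    raw: PolarizedScanSet, per_wavelength: bool = False
) -> SpectralFeatures:
    """Full chain: preprocess, pick extrema, Eq.-style decomposition, features."""
    scans = preprocess(raw)
    r_max, r_min, (min_idx, max_idx) = select_extrema(scans, per_wavelength)
    r_q, _ = compute_rq(r_max, r_min)
    return extract_features(
        r_q, r_min, scans.wavelength_nm, indices=(min_idx, max_idx), r_max=r_max
    )
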