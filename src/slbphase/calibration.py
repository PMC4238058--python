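"""Fluorescence-to-density calibration for membrane-attached protein.

Absolute surface densities (molecules/µm²) are obtained from fluorescence
in three steps:

1. Linear standard curves of intensity vs concentration are measured for
   the labeled protein and for a reference fluorescent lipid in solution;
   the ratio of their slopes, F = I_labeled_protein / I_labeled_SUV, is the
   relative per-molecule brightness of protein vs lipid on the instrument.
2. Bilayers doped with known mole fractions of the reference lipid set an
   intensity-vs-density standard curve. Mole fraction converts to density
   through the lipid headgroup area (default 69 Å²) counting both leaflets:
   density = fraction * 2 * (1e8 Å²/µm² / 69 Å²).
3. A measured protein intensity is divided by F, inverted through the
   bilayer standard curve, and divided by the labeled fraction to report
   total (labeled + unlabeled) molecules per µm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "DensityCalibration",
    "fit_standard",
    "correction_factor",
    "molpercent_to_density",
    "intensity_to_density",
    "HEADGROUP_AREA_A2",
]

#: Default lipid headgroup area in square Ångströms.
HEADGROUP_AREA_A2 = 69.0

_A2_PER_UM2 = 1e8  # Å² per µm²


@dataclass(frozen=True)
class StandardCurve:
    """An ordinary-least-squares line: intensity = slope * x + intercept."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    x_max: float  # largest standard; guards extrapolation
    slope_se: float = np.nan

    def invert(self, intensity: float) -> float:
        """x at a given intensity (line inversion)."""
        return (intensity - self.intercept) / self.slope


@dataclass(frozen=True)
class DensityCalibration:
    """Everything needed to turn protein intensity into molecules/µm²."""

    F: float
    bilayer_curve: StandardCurve  # intensity vs molecules/µm²
    lipid_headgroup_area: float = HEADGROUP_AREA_A2
    labeled_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError("correction factor F must be positive")
        if not self.lipid_headgroup_area > 0:
            raise ValueError("headgroup area must be positive")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must lie in (0, 1]")
        if self.labeled_fraction > 0.6:
            warnings.warn(
                "labeled fraction above 0.6: fluorescence is no longer linear "
                "in density at high labeling",
                stacklevel=2,
            )


def fit_standard(points: np.ndarray) -> StandardCurve:
    """OLS line through (x, intensity) standards.

    ``points`` is an (n, 2) array. Two points give r² = 1 by construction;
    a warning flags the absent degrees of freedom.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) array of (x, intensity) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all x values identical; no line can be fit")
    if pts.shape[0] == 2:
        warnings.warn("two-point standard: r² = 1 by construction", stacklevel=2)
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=int(pts.shape[0]),
        x_max=float(x.max()),
        slope_se=float(res.stderr),
    )


def correction_factor(protein_curve: StandardCurve, dye_curve: StandardCurve) -> float:
    """F = protein slope / dye slope (relative per-molecule brightness)."""
    if protein_curve.slope <= 0 or dye_curve.slope <= 0:
        raise ValueError("standard-curve slopes must be positive")
    return protein_curve.slope / dye_curve.slope


def molpercent_to_density(
    fraction: float,
    headgroup_area: float = HEADGROUP_AREA_A2,
    leaflets: int = 2,
) -> float:
    """Convert a lipid mole fraction to molecules/µm².

    ``fraction`` is the mole fraction (0.004 for 0.4 mol%). Both bilayer
    leaflets carry the dye by default.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if headgroup_area <= 0:
        raise ValueError("headgroup area must be positive")
    return fraction * leaflets * (_A2_PER_UM2 / headgroup_area)


def intensity_to_density(intensity: float, cal: DensityCalibration) -> float:
    """Total protein density (molecules/µm²) from a measured intensity.

    The intensity is divided by F, inverted through the bilayer standard
    curve, and scaled up by 1/labeled_fraction. Raises if the inversion
    lands below zero (background mis-subtraction) or beyond 1.5x the
    largest calibration standard (extrapolation outside the linear range).
    """
    labeled = cal.bilayer_curve.invert(intensity / cal.F)
    if labeled < 0:
        raise ValueError(
            "negative density after curve inversion: check background subtraction"
        )
    if labeled > 1.5 * cal.bilayer_curve.x_max:
        raise ValueError(
            "intensity implies a density beyond 1.5x the largest standard; "
            "refusing to extrapolate outside the calibrated linear range"
        )
    return labeled / cal.labeled_fraction
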