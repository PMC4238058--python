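"""Synthetic TIRF-like data generators.

Every downstream analysis in this package is exercised on synthetic data
with the statistical structure of supported-lipid-bilayer experiments:

* homogeneous fluid bilayers with smooth vignetting, a camera offset and
  additive Gaussian read noise;
* two cluster morphologies — *nucleated* (discrete puncta whose areas follow
  an exponential law and whose centers form a homogeneous Poisson process;
  the low-density regime) and *spinodal* (a labyrinthine pattern from a
  thresholded smoothed Gaussian random field; the high-density regime);
  clusters are brighter than the surrounding bilayer by a configurable
  enrichment factor (default 4x);
* titration series with a sharp clustering onset at a critical
  concentration (default 200 nM);
* FRAP recoveries (mono- or bi-exponential, with bleach depth, mobile
  fraction and optional mono-exponential acquisition bleaching);
* linear fluorescence standards for density calibration; and
* per-cluster actin assembly time courses with stochastic lag times.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .imgproc import RasterImage
from .kinetics import KineticTrace

__all__ = [
    "SceneParams",
    "TitrationParams",
    "FrapGenParams",
    "CalibrationDataset",
    "gen_bilayer_image",
    "gen_titration",
    "titration_area_fraction",
    "gen_frap_trace",
    "gen_calibration",
    "gen_actin_timecourse",
    "sample_cluster_areas",
]

# Defaults emulate 512x512 EM-CCD frames at 0.16 um/px, so a ~56 um field
# spans ~350 px, with clusters four times brighter than the bilayer.
DEFAULT_WIDTH = 512
DEFAULT_PIXEL_SIZE = 0.16
DEFAULT_ENRICHMENT = 4.0


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic bilayer image.

    ``morphology`` is 'none' (homogeneous), 'nucleated' (discrete puncta,
    exponential area law, Poisson-placed) or 'spinodal' (labyrinthine).
    ``enrichment`` is the cluster/background intensity (density) ratio;
    ``vignette_strength`` in [0, 1) scales a radial quadratic falloff.
    """

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_WIDTH
    pixel_size: float = DEFAULT_PIXEL_SIZE  # um/px
    mean_intensity: float = 1000.0  # counts, background bilayer level
    camera_offset: float = 100.0  # counts
    noise_sd: float = 20.0  # counts
    vignette_strength: float = 0.0
    morphology: str = "none"
    enrichment: float = DEFAULT_ENRICHMENT
    cluster_density: float = 0.05  # clusters per um^2 (nucleated)
    mean_cluster_area: float = 1.0  # um^2, exponential-law mean (nucleated)
    irregularity: float = 0.5  # disk-jitter scale, 0 = round puncta
    correlation_length: float = 1.0  # um (spinodal)
    clustered_fraction: float = 0.3  # area fraction (spinodal)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if not self.mean_intensity > 0:
            raise ValueError("mean_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must lie in [0, 1)")
        if not 0 <= self.clustered_fraction <= 1:
            raise ValueError("clustered_fraction must lie in [0, 1]")
        if self.morphology not in ("none", "nucleated", "spinodal"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.morphology == "spinodal" and self.clustered_fraction >= 1:
            raise ValueError("spinodal clustered_fraction must be < 1")


@dataclass(frozen=True)
class TitrationParams:
    """A concentration series with a sharp clustering onset.

    Above the critical concentration c*, the clustered area fraction rises
    as ``max_clustered_fraction * (1 - exp(-(c - c*)/rise_width))``; below
    c* it is exactly zero.
    """

    concentrations: tuple[float, ...]  # nM, strictly increasing
    critical_concentration: float = 200.0  # nM
    rise_width: float = 150.0  # nM
    max_clustered_fraction: float = 0.25
    scene: SceneParams = field(default_factory=SceneParams)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0:
            raise ValueError("empty concentration list")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not self.critical_concentration > 0:
            raise ValueError("critical_concentration must be positive")
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))


@dataclass(frozen=True)
class FrapGenParams:
    """Parameters of a synthetic FRAP recovery trace.

    The noiseless normalized recovery is

        f(t) = (1 - bleach_depth)
               + bleach_depth * mobile_fraction * sum_i f_i (1 - exp(-t/tau_i))

    for t >= 0 after the bleach, multiplied by the acquisition-bleaching
    factor exp(-elapsed/acq_bleach_tau) (elapsed time since the start of
    acquisition, so the first recorded frame has reference value 1).
    """

    tau_values: tuple[float, ...]  # seconds, 1 or 2 components
    fractions: tuple[float, ...] = (1.0,)
    bleach_depth: float = 0.8
    mobile_fraction: float = 1.0
    frame_interval: float = 1.0  # s
    duration: float = 300.0  # s of post-bleach recording
    n_prebleach: int = 5
    acq_bleach_tau: float = math.inf  # s; inf disables acquisition bleaching
    noise_sd: float = 0.01  # normalized units
    seed: int = 0

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.tau_values)
        fracs = tuple(float(f) for f in self.fractions)
        if len(taus) not in (1, 2) or len(fracs) != len(taus):
            raise ValueError("need 1 or 2 components with matching fractions")
        if any(t <= 0 for t in taus):
            raise ValueError("time constants must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0 <= self.bleach_depth <= 1 or not 0 <= self.mobile_fraction <= 1:
            raise ValueError("bleach_depth and mobile_fraction must lie in [0, 1]")
        if self.duration <= self.frame_interval:
            raise ValueError("duration must exceed the frame interval")
        object.__setattr__(self, "tau_values", taus)
        object.__setattr__(self, "fractions", fracs)


@dataclass(frozen=True)
class CalibrationDataset:
    """Three linear standards plus the true generating parameters."""

    dye_solution: np.ndarray  # (n, 2): concentration, intensity
    protein_solution: np.ndarray
    bilayer: np.ndarray  # (n, 2): molecules/um^2, intensity
    true_dye_slope: float
    true_protein_slope: float
    true_bilayer_slope: float

    @property
    def true_F(self) -> float:
        return self.true_protein_slope / self.true_dye_slope


# ---------------------------------------------------------------------------
# bilayer images


def _vignette(height: int, width: int, strength: float) -> np.ndarray:
    if strength == 0:
        return np.ones((height, width))
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2, (width - 1) / 2
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - strength * r2


_STAR_MODES = np.array([2, 3, 4, 5])


def _rasterize_star(
    mask: np.ndarray, cy: float, cx: float, area_px: float, irr: float, rng: np.random.Generator
) -> None:
    """Stamp one irregular punctum of (continuum) area ``area_px`` onto mask.

    The boundary is r(theta) = r0 * g(theta) with g a low-order Fourier
    perturbation normalized so that mean(g^2) = 1, which keeps the enclosed
    area (1/2) * integral r^2 dtheta equal to pi * r0^2 = area_px exactly in
    the continuum, independent of the irregularity draw.
    """
    coef = rng.normal(0.0, 1.0, (2, _STAR_MODES.size)) / _STAR_MODES
    r0 = math.sqrt(area_px / math.pi)

    def g(theta: np.ndarray) -> np.ndarray:
        modes = _STAR_MODES[None, :] * theta[:, None]
        out = 1.0 + irr * (
            coef[0][None, :] * np.cos(modes) + coef[1][None, :] * np.sin(modes)
        ).sum(axis=1)
        return np.clip(out, 0.15, None)

    theta_grid = np.linspace(0, 2 * math.pi, 128, endpoint=False)
    gv = g(theta_grid)
    norm = math.sqrt(float(np.mean(gv**2)))
    r_max = r0 * gv.max() / norm

    h, w = mask.shape
    y0, y1 = max(0, int(cy - r_max) - 1), min(h, int(cy + r_max) + 2)
    x0, x1 = max(0, int(cx - r_max) - 1), min(w, int(cx + r_max) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx).ravel()
    inside = (rr.ravel() <= r0 * g(theta) / norm).reshape(rr.shape)
    if not inside.any():
        # every punctum occupies at least its seed pixel
        iy, ix = int(round(cy)), int(round(cx))
        if 0 <= iy < h and 0 <= ix < w:
            mask[iy, ix] = True
        return
    mask[y0:y1, x0:x1] |= inside


def _nucleated_mask(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = p.height, p.width
    area_um2 = h * w * p.pixel_size**2
    n = rng.poisson(p.cluster_density * area_um2)
    mask = np.zeros((h, w), dtype=bool)
    centers = np.column_stack([rng.uniform(0, h, n), rng.uniform(0, w, n)])
    areas_px = rng.exponential(p.mean_cluster_area, n) / p.pixel_size**2
    for (cy, cx), a in zip(centers, areas_px):
        _rasterize_star(mask, cy, cx, a, p.irregularity, rng)
    return mask


def _spinodal_mask(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    from scipy import ndimage

    sigma_px = max(p.correlation_length / p.pixel_size, 1.0)
    noise = rng.standard_normal((p.height, p.width))
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    cut = np.quantile(smooth, 1.0 - p.clustered_fraction)
    return smooth > cut


def gen_bilayer_image(params: SceneParams) -> tuple[RasterImage, np.ndarray]:
    """Render one synthetic bilayer image and its ground-truth cluster mask.

    The noiseless model is
    ``vignette * background * (1 + (enrichment - 1) * mask) + offset``,
    to which Gaussian read noise of sd ``noise_sd`` is added.
    """
    rng = np.random.default_rng(params.seed)
    if params.morphology == "none":
        mask = np.zeros((params.height, params.width), dtype=bool)
    elif params.morphology == "nucleated":
        mask = _nucleated_mask(params, rng)
    else:
        mask = _spinodal_mask(params, rng)
    vign = _vignette(params.height, params.width, params.vignette_strength)
    signal = params.mean_intensity * (1.0 + (params.enrichment - 1.0) * mask)
    img = vign * signal + params.camera_offset
    if params.noise_sd > 0:
        img = img + rng.normal(0, params.noise_sd, img.shape)
    return RasterImage(values=img, pixel_size=params.pixel_size), mask


# ---------------------------------------------------------------------------
# titrations


def titration_area_fraction(c: float, params: TitrationParams) -> float:
    """Ground-truth clustered area fraction at solution concentration c (nM)."""
    cstar = params.critical_concentration
    if c <= cstar:
        return 0.0
    return params.max_clustered_fraction * (1.0 - math.exp(-(c - cstar) / params.rise_width))


def gen_titration(params: TitrationParams) -> list[tuple[float, RasterImage]]:
    """Generate one image per concentration with a sharp clustering onset.

    Below the critical concentration images are homogeneous; above it the
    scene morphology is used with its parameters scaled so the expected
    clustered area fraction follows the ground-truth onset law.
    """
    out: list[tuple[float, RasterImage]] = []
    base = params.scene
    morph = base.morphology if base.morphology != "none" else "nucleated"
    for i, c in enumerate(params.concentrations):
        phi = titration_area_fraction(c, params)
        if phi <= 0:
            scene = replace(base, morphology="none", seed=base.seed + i)
        elif morph == "nucleated":
            dens = phi / base.mean_cluster_area
            scene = replace(
                base, morphology="nucleated", cluster_density=dens, seed=base.seed + i
            )
        else:
            scene = replace(
                base, morphology="spinodal", clustered_fraction=phi, seed=base.seed + i
            )
        img, _ = gen_bilayer_image(scene)
        out.append((c, img))
    return out


# ---------------------------------------------------------------------------
# FRAP traces


def gen_frap_trace(params: FrapGenParams) -> tuple[KineticTrace, np.ndarray]:
    """Simulate a FRAP recovery; returns (trace, noiseless reference).

    The trace has ``n_prebleach`` frames at negative times, the bleach at
    t = 0, and post-bleach frames every ``frame_interval`` up to
    ``duration``. The returned reference is the noiseless acquisition-
    bleaching factor sampled at the same frames.
    """
    p = params
    t_pre = -p.frame_interval * np.arange(p.n_prebleach, 0, -1)
    t_post = np.arange(0.0, p.duration + 0.5 * p.frame_interval, p.frame_interval)
    times = np.concatenate([t_pre, t_post])
    elapsed = times - times[0]
    acq = (
        np.exp(-elapsed / p.acq_bleach_tau) if np.isfinite(p.acq_bleach_tau) else np.ones_like(times)
    )
    taus = np.asarray(p.tau_values)
    fracs = np.asarray(p.fractions)
    recovery = (1.0 - p.bleach_depth) + p.bleach_depth * p.mobile_fraction * (
        fracs[None, :] * (1.0 - np.exp(-t_post[:, None] / taus[None, :]))
    ).sum(axis=1)
    clean = np.concatenate([np.ones(p.n_prebleach), recovery]) * acq
    rng = np.random.default_rng(p.seed)
    noisy = clean + (rng.normal(0, p.noise_sd, clean.shape) if p.noise_sd > 0 else 0.0)
    trace = KineticTrace(
        times=times,
        values=noisy,
        n_prebleach=p.n_prebleach,
        reference=acq if np.isfinite(p.acq_bleach_tau) else None,
    )
    return trace, acq


# ---------------------------------------------------------------------------
# calibration standards


def gen_calibration(
    dye_slope: float,
    protein_slope: float,
    bilayer_slope: float,
    noise_sd: float = 0.0,
    n_points: int = 8,
    seed: int = 0,
    x_max: float = 1.0,
) -> CalibrationDataset:
    """Three linear standards with proportional Gaussian scatter.

    Each intensity is perturbed as ``y * (1 + eps)`` with
    ``eps ~ N(0, noise_sd)``, so 0.01 means 1% scatter per point.
    """
    if min(dye_slope, protein_slope, bilayer_slope) <= 0:
        raise ValueError("slopes must be positive")
    if n_points < 2:
        raise ValueError("need at least 2 points per standard")
    rng = np.random.default_rng(seed)
    x = np.linspace(x_max / n_points, x_max, n_points)

    def line(slope: float) -> np.ndarray:
        y = slope * x
        if noise_sd > 0:
            y = y * (1.0 + rng.normal(0, noise_sd, y.shape))
        return np.column_stack([x, y])

    return CalibrationDataset(
        dye_solution=line(dye_slope),
        protein_solution=line(protein_slope),
        bilayer=line(bilayer_slope),
        true_dye_slope=float(dye_slope),
        true_protein_slope=float(protein_slope),
        true_bilayer_slope=float(bilayer_slope),
    )


# ---------------------------------------------------------------------------
# actin assembly traces


def gen_actin_timecourse(
    n_clusters: int = 20,
    lag_range_min: tuple[float, float] = (6.0, 15.0),
    rise_tau: float = 3.0,
    frame_interval_min: float = 3.0,
    duration_min: float = 60.0,
    baseline: float = 0.05,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[KineticTrace]:
    """Per-cluster actin intensity traces with stochastic assembly lags.

    Each trace is a small uniform baseline until a lag drawn uniformly from
    ``lag_range_min`` (minutes), then a saturating rise
    ``amplitude * (1 - exp(-(t - lag)/rise_tau))``. Timestamps are
    0, frame_interval, 2*frame_interval, ... minutes.
    """
    lo, hi = lag_range_min
    if not 0 <= lo <= hi <= duration_min:
        raise ValueError("lag range must lie within [0, duration]")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 0.5 * frame_interval_min, frame_interval_min)
    traces = []
    for _ in range(n_clusters):
        lag = rng.uniform(lo, hi)
        rise = np.where(times > lag, amplitude * (1.0 - np.exp(-(times - lag) / rise_tau)), 0.0)
        y = baseline + rise
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, y.shape)
        traces.append(KineticTrace(times=times, values=y))
    return traces


# ---------------------------------------------------------------------------
# cluster-area sampling (size-law ground truth for distribution tests)


def sample_cluster_areas(
    n: int,
    law: str = "exponential",
    mean_area: float = 1.0,
    exponent: float = 2.0,
    min_area: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Draw cluster areas (µm²) from an exponential or power-law size law.

    ``exponential`` draws from Exp(mean_area); ``power_law`` from a Pareto
    density p(s) ~ s^(-exponent) for s >= min_area (exponent > 1). The two
    laws are the nucleation- and coalescence-dominated regimes seen at low
    and high receptor density, respectively.
    """
    rng = np.random.default_rng(seed)
    if law == "exponential":
        return rng.exponential(mean_area, n)
    if law == "power_law":
        if exponent <= 1:
            raise ValueError("power-law exponent must exceed 1")
        u = rng.uniform(size=n)
        return min_area * (1.0 - u) ** (-1.0 / (exponent - 1.0))
    raise ValueError(f"unknown size law {law!r}")
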