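"""Phase-transition order parameters and clustering-concentration detection.

Two order parameters track the two-dimensional phase transition as the
solution concentration of the crosslinking partner rises:

* **fractional intensity** — the fraction of total membrane fluorescence
  residing in thresholded cluster regions;
* **signal variance** — the population variance of pixel intensities across
  the (flat-field-corrected) bilayer image, which rises when bright regions
  form. The dimensionless CV² = var/mean² is reported alongside, since raw
  variance units depend on camera gain.

The clustering (critical) concentration is the point where both order
parameters begin increasing. Two estimators operationalize "begin
increasing": a segmented *hockey-stick* regression (flat baseline joined to
a rising line, breakpoint scanned over the interior grid points, accepted
only if the rise is significant by both a slope t-test and a nested-model
F-test at alpha = 0.05), and a simpler *baseline + 3 sd* exceedance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imgproc import RasterImage
from .segment import LabeledClusters, compute_threshold, segment_clusters

__all__ = [
    "TitrationPoint",
    "TitrationCurve",
    "BreakpointEstimate",
    "fractional_intensity",
    "signal_variance",
    "enrichment_ratio",
    "line_scan",
    "titration_statistics",
    "clustering_concentration",
]


@dataclass(frozen=True)
class TitrationPoint:
    concentration: float  # nM
    fractional_intensity: float
    variance: float
    cv2: float
    n_clusters: int


@dataclass(frozen=True)
class TitrationCurve:
    """Order parameters vs concentration, sorted ascending."""

    points: tuple[TitrationPoint, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.concentrations
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration for p in self.points])

    def statistic(self, name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in self.points])


@dataclass(frozen=True)
class BreakpointEstimate:
    """Estimated clustering concentration (if a rise was detected)."""

    detected: bool
    concentration: float | None
    baseline_level: float
    post_slope: float
    sse: float
    method: str
    p_slope: float | None = None
    p_ftest: float | None = None


def fractional_intensity(image: RasterImage, clusters: LabeledClusters) -> float:
    """Fraction of total image intensity inside cluster pixels, in [0, 1]."""
    if clusters.label_map.shape != image.shape:
        raise ValueError("label map and image shapes differ")
    total = float(image.values.sum())
    if total == 0:
        raise ValueError("image has zero total intensity")
    return float(image.values[clusters.mask].sum() / total)


def signal_variance(image: RasterImage) -> float:
    """Population variance of pixel intensities (counts²)."""
    return float(image.values.var())


def enrichment_ratio(
    image: RasterImage, clusters: LabeledClusters
) -> tuple[float, np.ndarray]:
    """Mean cluster intensity over mean background intensity (fold).

    Returns the global ratio and the per-cluster ratios (each cluster's
    mean over the common background mean).
    """
    mask = clusters.mask
    if not mask.any():
        raise ValueError("no cluster pixels")
    if mask.all():
        raise ValueError("no background pixels")
    bg_mean = float(image.values[~mask].mean())
    if bg_mean == 0:
        raise ValueError("zero background mean")
    global_ratio = float(image.values[mask].mean() / bg_mean)
    per_cluster = np.array([c.mean_intensity / bg_mean for c in clusters.clusters])
    return global_ratio, per_cluster


def line_scan(
    image: RasterImage, start: tuple[float, float], end: tuple[float, float], n: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile along a segment, bilinear interpolation.

    ``start``/``end`` are (row, col) pixel coordinates; returns (distance
    along the segment in µm, intensity).
    """
    from scipy import ndimage

    rows = np.linspace(start[0], end[0], n)
    cols = np.linspace(start[1], end[1], n)
    prof = ndimage.map_coordinates(image.values, [rows, cols], order=1, mode="nearest")
    dist = np.hypot(rows - rows[0], cols - cols[0]) * image.pixel_size
    return dist, prof


def titration_statistics(
    images: list[tuple[float, RasterImage | list[RasterImage]]],
    method: str = "triangle",
    min_area_px: int = 4,
    bins: int = 256,
    metadata: dict | None = None,
) -> TitrationCurve:
    """Order parameters for each concentration of a titration series.

    Each entry is (concentration_nM, image) or (concentration_nM, list of
    replicate tile images); replicate statistics are averaged. Images that
    are constant or contain no clusters contribute fractional intensity 0.
    """
    if len(images) < 4:
        raise ValueError("need at least 4 concentrations")
    conc = np.array([c for c, _ in images], dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    points = []
    for c, imgs in images:
        tiles = imgs if isinstance(imgs, (list, tuple)) else [imgs]
        fi, var, cv2, ncl = [], [], [], []
        for img in tiles:
            v = signal_variance(img)
            mean = float(img.values.mean())
            var.append(v)
            cv2.append(v / mean**2 if mean != 0 else np.nan)
            try:
                thr = compute_threshold(img, method=method, bins=bins)
                labeled = segment_clusters(img, thr, min_area_px=min_area_px)
                # clusters are the minority bright phase and must stand out
                # from the membrane: a mask covering most of the image, or
                # one whose mean is within 3 background sd of the membrane
                # mean, is a cluster-free image thresholded inside its own
                # noise peak
                mask = labeled.mask
                degenerate = labeled.n_clusters == 0 or mask.mean() > 0.5
                if not degenerate:
                    bg_vals = img.values[~mask]
                    degenerate = (
                        img.values[mask].mean() - bg_vals.mean() < 3 * bg_vals.std()
                    )
                if degenerate:
                    fi.append(0.0)
                    ncl.append(0)
                else:
                    fi.append(fractional_intensity(img, labeled))
                    ncl.append(labeled.n_clusters)
            except ValueError:
                fi.append(0.0)  # degenerate (constant) image: no clusters
                ncl.append(0)
        points.append(
            TitrationPoint(
                concentration=float(c),
                fractional_intensity=float(np.mean(fi)),
                variance=float(np.mean(var)),
                cv2=float(np.mean(cv2)),
                n_clusters=int(round(np.mean(ncl))),
            )
        )
    return TitrationCurve(points=tuple(points), metadata=metadata or {})


def _hockey_stick_sse(
    c: np.ndarray, y: np.ndarray, kb: int
) -> tuple[float, float, float]:
    """Least-squares flat-then-rising fit with breakpoint at grid index kb.

    Model: y = b for c <= c[kb]; y = b + m*(c - c[kb]) beyond. Linear in
    (b, m), solved in closed form. Returns (sse, baseline, slope).
    """
    x = np.clip(c - c[kb], 0.0, None)
    X = np.column_stack([np.ones_like(c), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(res[0]) if res.size else float(np.sum((X @ beta - y) ** 2))
    return sse, float(beta[0]), float(beta[1])


def clustering_concentration(
    curve: TitrationCurve,
    statistic: str = "fractional_intensity",
    method: str = "hockey_stick",
    alpha: float = 0.05,
    k_baseline: int = 3,
) -> BreakpointEstimate:
    """Estimate the concentration at which an order parameter begins rising.

    ``hockey_stick`` scans every interior grid concentration as the
    breakpoint of a flat-baseline + rising-line model, keeps the breakpoint
    with the lowest SSE, and reports a detection only when the post-break
    slope is significantly positive (t-test) *and* the two-segment model
    beats the flat model by the nested F-test, both at ``alpha``.
    ``baseline_3sd`` returns the first concentration whose statistic
    exceeds mean + 3 sd of the first ``k_baseline`` points.
    """
    c = curve.concentrations
    y = curve.statistic(statistic)
    n = c.size
    if n < 4:
        raise ValueError("need at least 4 titration points")

    if method == "baseline_3sd":
        base = y[:k_baseline]
        cut = base.mean() + 3 * base.std(ddof=1)
        idx = np.nonzero(y > cut)[0]
        idx = idx[idx >= k_baseline]
        if idx.size == 0:
            return BreakpointEstimate(False, None, float(base.mean()), 0.0, float(np.sum((y - y.mean()) ** 2)), method)
        k = int(idx[0])
        return BreakpointEstimate(True, float(c[k]), float(base.mean()), 0.0, 0.0, method)

    if method != "hockey_stick":
        raise ValueError(f"unknown breakpoint method {method!r}")

    # The rising segment is linear only near the onset; titration curves
    # saturate, so points beyond half-saturation are dropped before the
    # breakpoint scan (they carry no information about where the rise
    # begins and would otherwise dominate the least squares).
    base_level = float(np.median(y[:k_baseline]))
    half = base_level + 0.5 * (y.max() - base_level)
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] + 1 >= 4:
        c, y = c[: above[0] + 1], y[: above[0] + 1]
        n = c.size

    best = None
    for kb in range(1, n - 1):  # interior grid points
        sse, b, m = _hockey_stick_sse(c, y, kb)
        if best is None or sse < best[0]:
            best = (sse, b, m, kb)
    sse, b, m, kb = best
    sse_flat = float(np.sum((y - y.mean()) ** 2))

    # one-sided t-test on the rising-segment slope within the fitted model
    n_t = c.size
    p_slope = 1.0
    if n_t > 2 and m > 0:
        x = np.clip(c - c[kb], 0.0, None)
        s2 = sse / (n_t - 2)
        denom = n_t * np.sum(x**2) - np.sum(x) ** 2
        if denom > 0 and s2 > 0:
            se_m = np.sqrt(s2 * n_t / denom)
            p_slope = float(stats.t.sf(m / se_m, n_t - 2))
        elif s2 == 0:
            p_slope = 0.0  # exact fit with a positive slope

    # nested F-test: flat (1 param) vs segmented (3 params: b, m, breakpoint)
    df_flat, df_seg = n - 1, n - 3
    p_f = 1.0
    if df_seg > 0 and sse > 0:
        F = ((sse_flat - sse) / (df_flat - df_seg)) / (sse / df_seg)
        p_f = float(stats.f.sf(max(F, 0.0), df_flat - df_seg, df_seg))
    elif sse == 0 and sse_flat > 0:
        p_f = 0.0

    detected = bool(m > 0 and (p_slope < alpha or np.isnan(p_slope)) and p_f < alpha)
    return BreakpointEstimate(
        detected=detected,
        concentration=float(c[kb]) if detected else None,
        baseline_level=b,
        post_slope=m,
        sse=sse,
        method=method,
        p_slope=None if np.isnan(p_slope) else p_slope,
        p_ftest=p_f,
    )
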