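"""Cluster size-distribution and spatial-randomness statistics.

Size analysis bins the areas of clusters not touching the image border and
asks whether counts fall off exponentially with size, N(s) ~ exp(-s/s_bar)
(the signature of independent stochastic nucleation and growth), or as a
power law N(s) ~ s^(-k) (the coalescence-dominated regime at high receptor
density). Discrimination follows the regression procedure used in the
field: fit lines to (s, ln N) and to (ln s, ln N) over occupied bins and
prefer the law with the higher r², requiring a margin of 0.02 to call a
winner. The regressions are count-weighted (the log of a small Poisson
count is mostly sampling noise), and a direct nonlinear fit of the
exponential law supplies the reported mean cluster size.

Spatial analysis divides the image into a grid of boxes (default 5 x 5 =
25) and counts clusters per box twice — excluding and including clusters
that cross box boundaries. A cluster spanning k boxes is counted once in
each of the k boxes of the "including" count; the mean per-box excess
(including - excluding) estimates the average number of boundary clusters,
and half of it is subtracted from each "including" count to remove the
overcounting. The corrected counts of a spatially random (Poisson) pattern
follow a Gaussian frequency histogram, which is fit by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .segment import LabeledClusters

__all__ = [
    "SizeDistribution",
    "SizeModelComparison",
    "BoxCountResult",
    "size_distribution",
    "fit_size_model",
    "box_counts",
    "fit_gaussian_counts",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Linear-binned histogram of non-edge cluster areas (µm²)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_excluded_edge_clusters: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_clusters(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SizeModelComparison:
    """Exponential vs power-law size-law comparison by log-space regression."""

    exp_rate: float  # 1/µm² from the (s, ln N) line; N(s) ~ exp(-exp_rate*s)
    exp_r2: float
    power_exponent: float  # N(s) ~ s^(-power_exponent)
    power_r2: float
    preferred: str  # 'exponential', 'power_law' or 'indeterminate'
    mean_size: float  # s_bar in µm², from the direct nonlinear fit
    direct_exp_rate: float  # 1/s_bar from the nonlinear N0*exp(-s/s_bar) fit


@dataclass(frozen=True)
class BoxCountResult:
    """Quadrat counts with the boundary-cluster overcounting correction."""

    grid: tuple[int, int]
    counts_including_edges: np.ndarray
    counts_excluding_edges: np.ndarray
    avg_edge_clusters: float
    corrected_counts: np.ndarray


def _freedman_diaconis_width(areas: np.ndarray, floor: float) -> float:
    iqr = float(np.subtract(*np.percentile(areas, [75, 25])))
    width = 2.0 * iqr / areas.size ** (1 / 3)
    return max(width, floor)


def size_distribution(
    clusters: "LabeledClusters | np.ndarray",
    bin_width: float | None = None,
    pixel_size: float = 0.16,
    origin: float | None = None,
) -> SizeDistribution:
    """Bin non-edge cluster areas linearly.

    Accepts either a :class:`LabeledClusters` (edge-touching clusters are
    excluded, per the measurement protocol) or a raw array of areas in µm²
    (nothing excluded). ``bin_width`` defaults to the Freedman-Diaconis
    rule, floored at one pixel area. ``origin`` sets the left edge of the
    binning grid; by default it is the largest multiple of ``bin_width``
    at or below the smallest area, so the first bin is fully populated.
    """
    if isinstance(clusters, LabeledClusters):
        areas = clusters.areas_um2(include_edge=False)
        n_excluded = clusters.n_clusters - areas.size
        floor = clusters.pixel_size**2
    else:
        areas = np.asarray(clusters, dtype=float)
        n_excluded = 0
        floor = pixel_size**2
    if areas.size < 1:
        raise ValueError("no non-edge clusters to bin")
    if bin_width is None:
        bin_width = _freedman_diaconis_width(areas, floor)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if origin is None:
        lo = np.floor(areas.min() / bin_width) * bin_width
    else:
        if origin > areas.min():
            raise ValueError("origin must not exceed the smallest area")
        lo = float(origin)
    n_bins = max(int(np.ceil((areas.max() - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = np.nextafter(max(edges[-1], areas.max()), np.inf)
    counts, _ = np.histogram(areas, bins=edges)
    return SizeDistribution(
        bin_edges=edges, counts=counts, n_excluded_edge_clusters=int(n_excluded)
    )


def _r2(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares slope and r² of y on x.

    For y = ln N with Poisson-distributed bin counts N, Var(ln N) ~ 1/N,
    so weights proportional to the counts make the tail bins (whose logs
    are dominated by sampling noise) count for what they are worth.
    """
    sw = w.sum()
    xm, ym = (w * x).sum() / sw, (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    resid = y - ym - slope * (x - xm)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def fit_size_model(dist: SizeDistribution) -> SizeModelComparison:
    """Discriminate exponential vs power-law size laws on occupied bins.

    Zero-count bins are excluded (their log is undefined). Requires at
    least 4 occupied bins.
    """
    occupied = dist.counts > 0
    if occupied.sum() < 4:
        raise ValueError("need at least 4 occupied bins")
    s = dist.bin_centers[occupied]
    n = dist.counts[occupied].astype(float)
    ln_n = np.log(n)

    exp_slope, exp_r2 = _r2(s, ln_n, n)  # ln N = a - s/s_bar
    pow_slope, pow_r2 = _r2(np.log(s), ln_n, n)  # ln N = a - k ln s
    exp_rate = -exp_slope
    if exp_r2 > pow_r2 + 0.02:
        preferred = "exponential"
    elif pow_r2 > exp_r2 + 0.02:
        preferred = "power_law"
    else:
        preferred = "indeterminate"

    # Direct nonlinear fit of N(s) = N0 * exp(-s/s_bar). This is the
    # primary estimate of the mean cluster size: unlike the log-space line
    # it weights bins by their counts, so sparse tail bins do not bias
    # s_bar upward.
    sbar0 = 1.0 / exp_rate if exp_rate > 0 else max(float(s.mean()), 1e-6)
    try:
        with np.errstate(over="ignore"):  # transient overflow while searching
            popt, _ = optimize.curve_fit(
                lambda ss, n0, sbar: n0 * np.exp(-ss / sbar),
                s,
                n,
                p0=[n.max(), abs(sbar0)],
                maxfev=10000,
            )
        direct_rate = 1.0 / popt[1]
    except (RuntimeError, ValueError):
        direct_rate = np.nan

    mean_size = 1.0 / direct_rate if np.isfinite(direct_rate) and direct_rate > 0 else (
        1.0 / exp_rate if exp_rate > 0 else np.nan
    )
    return SizeModelComparison(
        exp_rate=float(exp_rate),
        exp_r2=exp_r2,
        power_exponent=float(-pow_slope),
        power_r2=pow_r2,
        preferred=preferred,
        mean_size=float(mean_size),
        direct_exp_rate=float(direct_rate),
    )


def box_counts(clusters: LabeledClusters, grid: tuple[int, int] = (5, 5)) -> BoxCountResult:
    """Quadrat counts over a grid of boxes with edge-cluster correction.

    Remainder pixels (when the image does not divide evenly) go to the last
    row/column of boxes. Per box, "including" counts every cluster with at
    least one pixel in the box, "excluding" only clusters entirely inside
    it; ``corrected = including - avg_edge_clusters / 2`` where
    ``avg_edge_clusters`` is the mean per-box excess.
    """
    rows, cols = grid
    h, w = clusters.label_map.shape
    if rows > h or cols > w:
        raise ValueError("grid is finer than the image")
    row_idx = np.minimum(np.arange(h) // (h // rows), rows - 1)
    col_idx = np.minimum(np.arange(w) // (w // cols), cols - 1)
    box_of_pixel = row_idx[:, None] * cols + col_idx[None, :]

    n_boxes = rows * cols
    including = np.zeros(n_boxes)
    excluding = np.zeros(n_boxes)
    labels = clusters.label_map
    for c in clusters.clusters:
        boxes = np.unique(box_of_pixel[labels == c.id])
        including[boxes] += 1
        if boxes.size == 1:
            excluding[boxes[0]] += 1
    avg_edge = float(np.mean(including - excluding))
    return BoxCountResult(
        grid=(rows, cols),
        counts_including_edges=including,
        counts_excluding_edges=excluding,
        avg_edge_clusters=avg_edge,
        corrected_counts=including - avg_edge / 2.0,
    )


def fit_gaussian_counts(
    results: "list[BoxCountResult] | np.ndarray", bins: int | None = None
) -> dict:
    """Least-squares Gaussian fit to the frequency histogram of box counts.

    Pools corrected counts from all results (>= 20 boxes required), builds
    a relative-frequency histogram at unit (integer) bin width by default,
    and fits A*exp(-(x - mu)^2 / (2 sigma^2)). A Shapiro-Wilk normality
    p-value is reported as a cross-check.
    """
    if isinstance(results, np.ndarray):
        counts = results.astype(float)
    else:
        counts = np.concatenate([r.corrected_counts for r in results])
    if counts.size < 20:
        raise ValueError("need at least 20 boxes in total")
    if counts.std() == 0:
        raise ValueError("zero-variance counts: Gaussian fit is degenerate")

    if bins is None:
        lo, hi = np.floor(counts.min()), np.ceil(counts.max())
        edges = np.arange(lo - 0.5, hi + 1.5)
    else:
        edges = np.histogram_bin_edges(counts, bins=bins)
    hist, edges = np.histogram(counts, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    freq = hist / counts.size  # relative frequencies

    mu0, sd0 = counts.mean(), counts.std()
    popt, _ = optimize.curve_fit(
        lambda x, a, mu, sd: a * np.exp(-((x - mu) ** 2) / (2 * sd**2)),
        centers,
        freq,
        p0=[freq.max(), mu0, sd0],
        maxfev=20000,
    )
    a, mu, sd = popt
    pred = a * np.exp(-((centers - mu) ** 2) / (2 * sd**2))
    ss_res = float(np.sum((freq - pred) ** 2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    n_shapiro = min(counts.size, 4999)  # Shapiro-Wilk upper sample limit
    p_norm = float(stats.shapiro(counts[:n_shapiro]).pvalue)
    return {
        "mean": float(mu),
        "sd": float(abs(sd)),
        "amplitude": float(a),
        "r2": r2,
        "p_normality": p_norm,
    }
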