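"""Kinetic trace analysis: FRAP, membrane dissociation, actin assembly.

FRAP recovery curves are background-corrected, divided by an acquisition-
bleaching reference trace, normalized to the pre-bleach mean, and fit to

    f(t) = plateau - sum_i A_i * exp(-t / tau_i),        i = 1 or 2,

measured from the bleach instant. The single- vs double-exponential choice
is made by the classical nested-model F-test

    F = [(SS1 - SS2) / (df1 - df2)] / (SS2 / df2),

with p from the F(df1-df2, df2) distribution. Membrane dissociation decays
are fit to A*exp(-t/tau) + C. Actin assembly traces yield per-cluster
half-times t_1/2 (time at which intensity first reaches half its maximum,
baseline-subtracted, linear interpolation between bracketing frames) and
Spearman rank correlations of t_1/2 against cluster area and receptor
intensity.

Bi-exponential least squares is initialization-sensitive, so fits use a
multistart grid over {t_total/100, t_total/10, t_total/3} time constants
crossed with amplitude splits {0.25, 0.5, 0.75}; the lowest-SS solution is
kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "ExpFit",
    "ModelChoice",
    "normalize_frap",
    "detect_bleach_frame",
    "fit_recovery",
    "select_model",
    "fit_decay",
    "actin_halftime",
    "actin_halftimes",
]


@dataclass(frozen=True)
class KineticTrace:
    """A (time, intensity) series, optionally with pre-bleach frames.

    Parameters
    ----------
    times : ndarray
        Strictly increasing time stamps (seconds unless noted).
    values : ndarray
        Intensities, raw or normalized.
    n_prebleach : int
        Number of leading frames acquired before the perturbation
        (0 if the trace starts at the perturbation).
    reference : ndarray, optional
        Acquisition-bleaching reference trace sampled at the same times
        (imaging-only control, no bleach pulse).
    background : float or ndarray
        Camera/dark background to subtract, scalar or per-frame.
    """

    times: np.ndarray
    values: np.ndarray
    n_prebleach: int = 0
    reference: np.ndarray | None = None
    background: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.reference is not None:
            r = np.asarray(self.reference, dtype=float)
            if r.shape != t.shape:
                raise ValueError("reference must match times in shape")
            object.__setattr__(self, "reference", r)

    @property
    def prebleach_values(self) -> np.ndarray:
        return self.values[: self.n_prebleach]

    def postbleach(self) -> tuple[np.ndarray, np.ndarray]:
        """Times (rebased to the bleach instant) and values after it."""
        i = self.n_prebleach
        return self.times[i:] - self.times[i], self.values[i:]


@dataclass(frozen=True)
class ExpFit:
    """Result of a 1- or 2-component exponential fit.

    ``taus`` are sorted ascending; ``amplitudes`` are fractions of the total
    recovering (or decaying) amplitude and sum to 1. ``plateau`` is the
    t -> inf asymptote and ``bleach_floor`` the fitted value at t = 0.
    ``ci95`` holds asymptotic 95% confidence half-widths per parameter in
    the order (tau_1[, tau_2], A_1[, A_2], plateau), with A_i the absolute
    recovering amplitudes, matching the sorted taus.
    """

    n_components: int
    taus: tuple[float, ...]
    amplitudes: tuple[float, ...]
    plateau: float
    bleach_floor: float
    ss_residual: float
    df: int
    n_points: int
    ci95: tuple[float, ...] = ()
    ci95_fractions: tuple[float, ...] = ()
    at_bounds: bool = False

    @property
    def n_params(self) -> int:
        return self.n_points - self.df

    @property
    def total_amplitude(self) -> float:
        return self.plateau - self.bleach_floor


@dataclass(frozen=True)
class ModelChoice:
    """Nested-model F-test outcome for single vs double exponential."""

    F_stat: float
    df_num: int
    df_den: int
    p_value: float
    preferred: str  # 'single' or 'double'


def detect_bleach_frame(trace: KineticTrace, n_baseline: int = 5) -> int:
    """Index of the first frame dropping > 3 sd below the pre-bleach mean.

    Used when a trace does not carry an explicit ``n_prebleach``.
    """
    base = trace.values[:n_baseline]
    mu, sd = base.mean(), base.std(ddof=1)
    sd = max(sd, 1e-12 * abs(mu) if mu != 0 else 1e-12)
    below = np.nonzero(trace.values < mu - 3 * sd)[0]
    if below.size == 0:
        raise ValueError("no bleach event found in trace")
    return int(below[0])


def normalize_frap(trace: KineticTrace) -> KineticTrace:
    """Normalize a raw FRAP trace to pre-bleach intensity 1.

    Each frame is background-subtracted, divided by the (background-
    subtracted) acquisition-bleaching reference at the same frame, and the
    quotient is divided by its pre-bleach mean. Without a reference trace
    the reference quotient is 1 (acquisition bleaching assumed negligible).
    """
    if trace.n_prebleach < 2:
        raise ValueError("need at least 2 pre-bleach points to normalize")
    bg = np.asarray(trace.background, dtype=float)
    signal = trace.values - bg
    if trace.reference is not None:
        ref = trace.reference - bg
        if np.any(ref <= 0):
            raise ValueError("reference trace is at or below background")
        q = signal / ref
    else:
        q = signal
    pre = q[: trace.n_prebleach].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach mean after correction")
    return replace(trace, values=q / pre, reference=None, background=0.0)


def _exp_model(t: np.ndarray, taus: np.ndarray, amps: np.ndarray, plateau: float) -> np.ndarray:
    return plateau - (amps[:, None] * np.exp(-t[None, :] / taus[:, None])).sum(axis=0)


def _fit_exp_ls(
    t: np.ndarray, y: np.ndarray, n_components: int
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Multistart trust-region least squares; returns (params, ss, jac).

    Parameter vector: (tau_1..tau_k, A_1..A_k, plateau).
    """
    t_total = t[-1] - t[0] if t[-1] > t[0] else 1.0
    amp_total = max(y.max() - y.min(), 1e-12)
    tau_grid = [t_total / 100, t_total / 10, t_total / 3]

    def residuals(p: np.ndarray) -> np.ndarray:
        taus, amps, plateau = p[:n_components], p[n_components:-1], p[-1]
        return _exp_model(t, taus, amps, plateau) - y

    lb = [t_total * 1e-5] * n_components + [0.0] * n_components + [-np.inf]
    ub = [t_total * 1e3] * n_components + [np.inf] * n_components + [np.inf]
    starts = []
    if n_components == 1:
        for tau in tau_grid:
            starts.append([tau, amp_total, y.max()])
    else:
        for tau_f in tau_grid:
            for tau_s in tau_grid:
                if tau_s <= tau_f:
                    continue
                for frac in (0.25, 0.5, 0.75):
                    starts.append(
                        [tau_f, tau_s, frac * amp_total, (1 - frac) * amp_total, y.max()]
                    )
    best = None
    for p0 in starts:
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lb, ub), method="trf")
        except Exception:  # noqa: BLE001 - a failed start is simply skipped
            continue
        ss = float(2 * sol.cost)
        if best is None or ss < best[1]:
            best = (sol.x, ss, sol.jac)
    if best is None:
        raise RuntimeError("exponential fit failed to converge from all starts")
    return best


def _cov_from_jac(jac: np.ndarray, ss: float, df: int) -> np.ndarray | None:
    if df <= 0:
        return None
    try:
        return np.linalg.inv(jac.T @ jac) * (ss / df)
    except np.linalg.LinAlgError:
        return None


def fit_recovery(trace: KineticTrace, n_components: int = 2) -> ExpFit:
    """Fit a normalized FRAP recovery to a 1- or 2-exponential model.

    The fit uses only post-bleach frames, with time rebased to the bleach
    instant. Raises if the recovering amplitude is degenerate (flat trace)
    or if no start converges; time constants pinned at the search bounds
    are flagged via ``at_bounds``.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t, y = trace.postbleach()
    n_params = 2 * n_components + 1
    if t.size < 3 * n_params:
        raise ValueError(f"need at least {3 * n_params} post-bleach points")
    if np.ptp(y) <= 1e-12 * max(1.0, abs(y).max()):
        raise ValueError("flat trace: recovering amplitude is zero")

    params, ss, jac = _fit_exp_ls(t, y, n_components)
    taus = params[:n_components]
    amps = params[n_components:-1]
    plateau = float(params[-1])
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    total = amps.sum()
    if total <= 0:
        raise ValueError("fitted recovering amplitude is zero")
    df = t.size - n_params
    t_total = t[-1] - t[0]
    at_bounds = bool(np.any(taus <= t_total * 1.1e-5) or np.any(taus >= t_total * 0.9e3))
    if at_bounds:
        warnings.warn("fitted time constant at search bound", stacklevel=2)
    ci: tuple[float, ...] = ()
    ci_frac: tuple[float, ...] = ()
    cov = _cov_from_jac(jac, ss, df) if jac is not None else None
    if cov is not None:
        tcrit = float(stats.t.ppf(0.975, df))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        # align CI entries with the sorted (taus..., amps..., plateau)
        se[:n_components] = se[:n_components][order]
        se[n_components:-1] = se[n_components:-1][order]
        ci = tuple(float(tcrit * x) for x in se)
        if n_components == 2:
            # delta-method CI for the fast fraction f = A1/(A1+A2);
            # the slow fraction CI is identical by symmetry
            i1, i2 = n_components + order[0], n_components + order[1]
            a1, a2 = params[i1], params[i2]
            g = np.zeros(cov.shape[0])
            g[i1], g[i2] = a2 / total**2, -a1 / total**2
            se_f = float(np.sqrt(max(g @ cov @ g, 0.0)))
            ci_frac = (tcrit * se_f, tcrit * se_f)
    return ExpFit(
        n_components=n_components,
        taus=tuple(float(x) for x in taus),
        amplitudes=tuple(float(a / total) for a in amps),
        plateau=plateau,
        bleach_floor=float(plateau - total),
        ss_residual=ss,
        df=df,
        n_points=int(t.size),
        ci95=ci,
        ci95_fractions=ci_frac,
        at_bounds=at_bounds,
    )


def select_model(fit1: ExpFit, fit2: ExpFit, alpha: float = 0.05) -> ModelChoice:
    """F-test between a single- (fit1) and double-exponential (fit2) fit.

    fit1 must be nested in fit2 (fewer parameters, same data length).
    A perfect double-exponential fit (SS2 = 0) prefers 'double' with p = 0.
    """
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits compare different data")
    df1, df2 = fit1.df, fit2.df
    if df1 <= df2:
        raise ValueError("fit1 must have more residual degrees of freedom than fit2")
    if fit2.ss_residual == 0.0:
        return ModelChoice(np.inf, df1 - df2, df2, 0.0, "double")
    F = ((fit1.ss_residual - fit2.ss_residual) / (df1 - df2)) / (fit2.ss_residual / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1 - df2, df2))
    return ModelChoice(float(F), df1 - df2, df2, p, "double" if p < alpha else "single")


def fit_decay(trace: KineticTrace) -> ExpFit:
    """Fit a dissociation decay I(t) = A*exp(-t/tau) + C.

    Used for membrane-dissociation time courses; the trace has no
    pre-bleach segment (``n_prebleach`` ignored).
    """
    t = trace.times - trace.times[0]
    y = trace.values
    if t.size < 5:
        raise ValueError("need at least 5 points")
    amp = y[0] - y[-1]
    if abs(amp) <= 1e-12 * max(1.0, abs(y).max()):
        raise ValueError("flat trace: decay amplitude unidentifiable")
    t_total = t[-1]

    def model(tt: np.ndarray, A: float, tau: float, C: float) -> np.ndarray:
        return A * np.exp(-tt / tau) + C

    best = None
    for tau0 in (t_total / 10, t_total / 3, t_total):
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=[amp, tau0, y[-1]],
                bounds=([-np.inf, t_total * 1e-5, -np.inf], [np.inf, t_total * 1e4, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise RuntimeError("decay fit failed to converge")
    (A, tau, C), pcov, ss = best
    df = t.size - 3
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ci = tuple(float(stats.t.ppf(0.975, df)) * se) if df > 0 else ()
    return ExpFit(
        n_components=1,
        taus=(float(tau),),
        amplitudes=(1.0,),
        plateau=float(C),
        bleach_floor=float(C + A),  # value at t = 0
        ss_residual=ss,
        df=df,
        n_points=int(t.size),
        ci95=ci,
    )


def actin_halftime(
    trace: KineticTrace,
    window: float = 27.0,
    n_baseline: int = 2,
) -> float:
    """Half-rise time of one actin assembly trace, in trace time units.

    Intensity is baseline-subtracted (mean of the first ``n_baseline``
    frames); t_1/2 is where the trace first reaches half its maximum within
    the analysis window, located by linear interpolation between the
    bracketing frames. Raises if the trace never exceeds twice its baseline
    (no detectable assembly).
    """
    in_win = trace.times <= window
    t, y = trace.times[in_win], trace.values[in_win]
    if t.size < 3:
        raise ValueError("too few frames inside the analysis window")
    baseline = y[:n_baseline].mean()
    if y.max() <= 2 * max(baseline, 1e-12):
        raise ValueError("no assembly detected: trace never exceeds 2x baseline")
    z = y - baseline
    half = z.max() / 2.0
    above = np.nonzero(z >= half)[0]
    k = above[0]
    if k == 0 or z[k - 1] <= 0:
        # assembly jumps from baseline straight past half-max: the crossing
        # time is the frame where signal first appears (interpolating into
        # the pre-assembly lag would be meaningless)
        return float(t[k])
    frac = (half - z[k - 1]) / (z[k] - z[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def actin_halftimes(
    traces: list[KineticTrace],
    cluster_features: "np.ndarray | list[dict] | None" = None,
    window: float = 27.0,
) -> dict:
    """Half-times for a set of per-cluster actin traces, with correlations.

    ``cluster_features`` is an optional per-trace list of dicts with keys
    ``area`` and ``receptor_intensity``. Returns the half-times, flags for
    traces with no detectable assembly, and Spearman rank correlations
    (rho, p) of t_1/2 against each supplied feature.
    """
    t_half = np.full(len(traces), np.nan)
    for i, tr in enumerate(traces):
        try:
            t_half[i] = actin_halftime(tr, window=window)
        except ValueError:
            pass  # left NaN and reported via `undefined`
    out: dict = {
        "t_half": t_half,
        "undefined": np.isnan(t_half),
        "window": window,
    }
    if cluster_features is not None:
        ok = ~np.isnan(t_half)
        for key in ("area", "receptor_intensity"):
            feat = np.array([f.get(key, np.nan) for f in cluster_features], dtype=float)
            use = ok & ~np.isnan(feat)
            if use.sum() >= 3:
                rho, p = stats.spearmanr(t_half[use], feat[use])
                out[f"spearman_{key}"] = (float(rho), float(p))
    return out
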