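"""Enzyme-assay analysis: initial velocities, salt regressions, ratios.

The in vitro readout is absorbance at 280 nm versus time for samples that
are either native (intact compartments; product formation limited by both
shell permeation and enzyme turnover) or broken (sonicated; turnover only),
across a range of NaCl concentrations.  The pipeline estimates the initial
velocity V0 of each series by ordinary least squares on an early-time
window, regresses V0 against [NaCl] over a stated range (100–500 mM by
default), compares the two states' slopes with a t test, and forms the
broken/native V0 ratio with first-order error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError


@dataclass
class AssaySeries:
    """One absorbance time course (time s, A280, condition, state, replicate)."""

    times_s: np.ndarray
    a280: np.ndarray
    nacl_mM: float
    state: str  # "native" | "broken"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.a280 = np.asarray(self.a280, dtype=float)
        if len(self.times_s) != len(self.a280):
            raise InputError("times and absorbances must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise InputError("times must be strictly increasing")


@dataclass
class VelocityEstimate:
    """Fitted initial velocity (absorbance/s) with standard error."""

    v0: float
    se: float
    window: tuple[int, int]  # [start, stop) indices of the fitted window
    r2: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InputError("standard error must be non-negative")


@dataclass
class LinearFit:
    """OLS fit of V0 against [NaCl]."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n: int
    r2: float
    range_mM: tuple[float, float] | None = None


@dataclass
class SlopeComparison:
    """t test for a difference between two independently fitted slopes."""

    slope_a: float
    se_a: float
    slope_b: float
    se_b: float
    difference: float
    t: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError("p-value must lie in [0, 1]")


@dataclass
class RatioPoint:
    """Broken/native V0 ratio at one salt level, with compounded SE."""

    nacl_mM: float
    ratio: float
    se: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Slope, intercept, their SEs, and R² — with exact-fit edge cases.

    A perfectly fitted line (including a constant series) gets SE 0 and
    R² 1, so noiseless fixtures behave deterministically.
    """
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise InputError("degenerate abscissa: all x identical")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    scale = max(ss_tot, 1.0)
    if ss_res <= 1e-24 * scale:
        return slope, intercept, 0.0, 0.0, 1.0
    if n <= 2:
        raise InputError("need more than two points for standard errors")
    sigma2 = ss_res / (n - 2)
    slope_se = float(np.sqrt(sigma2 / sxx))
    intercept_se = float(np.sqrt(sigma2 * (1.0 / n + xm**2 / sxx)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, slope_se, intercept_se, r2


def _poly2_initial_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Quadratic fit in (t - t0); returns (dy/dt at t0, its SE, R², resid RMS)."""
    x = t - t[0]
    X = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(t)
    scale = max(ss_tot, 1.0)
    if ss_res <= 1e-24 * scale:
        return float(coef[1]), 0.0, 1.0, 0.0
    dof = n - 3
    sigma2 = ss_res / dof if dof > 0 else np.inf
    cov = sigma2 * np.linalg.inv(X.T @ X)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return (
        float(coef[1]),
        float(np.sqrt(cov[1, 1])),
        r2,
        float(np.sqrt(ss_res / n)),
    )


def _noise_sd_estimate(y: np.ndarray) -> float:
    """Noise SD from second differences (smooth trends cancel; Var(d²y) = 6σ²)."""
    d2 = np.diff(y, n=2)
    if d2.size == 0:
        return 0.0
    return float(np.sqrt(max(np.mean(d2**2) / 6.0, 0.0)))


def _exponential_velocity(t: np.ndarray, y: np.ndarray) -> VelocityEstimate:
    """V0 from a saturating progress-curve fit, c + V0·τ·(1 − e^(−t/τ)).

    Uses every point, so the V0 variance is far below any early-window
    estimator when the curve really is exponential; falls back to the
    quadratic initial slope if the nonlinear fit fails.  Exactly polynomial
    series short-circuit to the exact OLS answer (SE 0).
    """
    from scipy.optimize import curve_fit

    n = len(t)
    slope, _, se_line, _, r2_line = _ols_line(t, y)
    if se_line == 0.0:
        return VelocityEstimate(v0=slope, se=0.0, window=(0, n), r2=r2_line)
    x = t - t[0]

    def model(tt, c, v0, tau):
        return c + v0 * tau * (1.0 - np.exp(-tt / tau))

    b1, _, _, _ = _poly2_initial_slope(t, y)
    X = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    tau0 = -coef[1] / (2.0 * coef[2]) if coef[2] < 0 else x[-1] * 10.0
    if not np.isfinite(tau0) or tau0 <= 0:
        tau0 = x[-1] * 10.0
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[y[0], b1 if b1 != 0 else slope, tau0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = y - model(x, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return VelocityEstimate(
            v0=float(popt[1]), se=float(np.sqrt(pcov[1, 1])), window=(0, n), r2=r2
        )
    except (RuntimeError, ValueError):
        v0, se, r2, _ = _poly2_initial_slope(t, y)
        return VelocityEstimate(v0=v0, se=se, window=(0, n), r2=r2)


def initial_velocity(
    series: AssaySeries,
    method: str = "quadratic",
    min_points: int = 5,
    r2_threshold: float = 0.99,
    noise_factor: float = 1.2,
    fixed_window: tuple[int, int] | None = None,
) -> VelocityEstimate:
    """Initial slope of a product-formation curve over an early-time window.

    Default method ("quadratic"): estimate the noise SD from second
    differences, take the longest initial prefix whose quadratic fit has
    residual RMS within ``noise_factor`` x noise (so the window grows until
    real curvature beyond quadratic emerges above the noise), and report the
    fitted curve's derivative at the first time point.  The quadratic
    derivative is unbiased for saturating progress curves where a plain
    line fit systematically underestimates V0.

    Method "linear": ordinary least-squares slope over the longest initial
    prefix with line-fit R² ≥ ``r2_threshold`` (minimal prefix if none
    qualifies).  ``fixed_window`` overrides either policy with explicit
    [start, stop) indices.
    """
    t, y = series.times_s, series.a280
    if len(t) < 4:
        raise InputError("need at least four points to fit an initial velocity")
    if fixed_window is not None:
        lo, hi = fixed_window
        if not (0 <= lo < hi <= len(t)) or hi - lo < 2:
            raise InputError("fixed window out of series bounds")
        if method == "quadratic" and hi - lo >= 4:
            v0, se, r2, _ = _poly2_initial_slope(t[lo:hi], y[lo:hi])
        else:
            v0, _, se, _, r2 = _ols_line(t[lo:hi], y[lo:hi])
        return VelocityEstimate(v0=v0, se=se, window=(lo, hi), r2=r2)

    min_points = max(min_points, 4 if method == "quadratic" else 3)
    if method == "quadratic":
        sigma = _noise_sd_estimate(y)
        thresh = max(noise_factor * sigma, 1e-12 * max(np.max(np.abs(y)), 1.0))
        best = None
        for hi in range(min(min_points, len(t)), len(t) + 1):
            v0, se, r2, rms = _poly2_initial_slope(t[:hi], y[:hi])
            if rms <= thresh:
                best = VelocityEstimate(v0=v0, se=se, window=(0, hi), r2=r2)
            elif best is not None:
                break
        if best is None:
            hi = min(min_points, len(t))
            v0, se, r2, _ = _poly2_initial_slope(t[:hi], y[:hi])
            best = VelocityEstimate(v0=v0, se=se, window=(0, hi), r2=r2)
        return best
    if method == "exponential":
        return _exponential_velocity(t, y)
    if method != "linear":
        raise InputError(f"unknown initial-velocity method {method!r}")
    best = None
    for hi in range(min(min_points, len(t)), len(t) + 1):
        slope, _, se, _, r2 = _ols_line(t[:hi], y[:hi])
        if r2 >= r2_threshold:
            best = VelocityEstimate(v0=slope, se=se, window=(0, hi), r2=r2)
        elif best is not None:
            # prefix R² is not monotone, but stop at the first failure past a
            # success to keep the window genuinely "initial"
            break
    if best is None:
        hi = min(min_points, len(t))
        slope, _, se, _, r2 = _ols_line(t[:hi], y[:hi])
        best = VelocityEstimate(v0=slope, se=se, window=(0, hi), r2=r2)
    return best


def regress_v0_vs_salt(
    points: list[tuple[float, float, float]],
    range_mM: tuple[float, float] = (100.0, 500.0),
) -> LinearFit:
    """OLS of V0 against [NaCl] over the stated inclusive range.

    ``points`` is a list of (salt mM, V0, V0 SE); only points with
    ``lo ≤ salt ≤ hi`` enter the fit (the SEs are carried for bookkeeping,
    the fit itself is unweighted OLS).
    """
    lo, hi = range_mM
    sel = [(s, v) for s, v, _ in points if lo <= s <= hi]
    if len(sel) < 3:
        raise InputError(
            f"need at least 3 points inside [{lo}, {hi}] mM, got {len(sel)}"
        )
    x = np.array([s for s, _ in sel])
    y = np.array([v for _, v in sel])
    slope, intercept, slope_se, intercept_se, r2 = _ols_line(x, y)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        intercept_se=intercept_se,
        n=len(sel),
        r2=r2,
        range_mM=(lo, hi),
    )


def compare_slopes(fit_a: LinearFit, fit_b: LinearFit) -> SlopeComparison:
    """Two-sided t test for unequal slopes of two independent OLS fits.

    ``t = (slope_a − slope_b) / √(SE_a² + SE_b²)`` with
    ``df = n_a + n_b − 4``.  A zero pooled SE with equal slopes yields
    p = 1 by convention (identical noiseless fits are not evidence of a
    difference); with unequal slopes it yields p = 0.
    """
    if fit_a.n < 3 or fit_b.n < 3:
        raise InputError("both fits must use at least 3 points")
    diff = fit_a.slope - fit_b.slope
    pooled = float(np.hypot(fit_a.slope_se, fit_b.slope_se))
    df = fit_a.n + fit_b.n - 4
    if pooled == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / pooled
        p = float(2.0 * stats.t.sf(abs(t), df))
    return SlopeComparison(
        slope_a=fit_a.slope,
        se_a=fit_a.slope_se,
        slope_b=fit_b.slope,
        se_b=fit_b.slope_se,
        difference=diff,
        t=float(t),
        df=df,
        p_value=p,
    )


def v0_ratio(broken: VelocityEstimate, native: VelocityEstimate, nacl_mM: float = 0.0) -> RatioPoint:
    """Broken/native V0 ratio with first-order compounded standard error.

    ``SE = ratio · √((SE_b/b)² + (SE_n/n)²)`` — exact to first order in the
    coefficients of variation.
    """
    if native.v0 == 0:
        raise InputError("native V0 is zero: ratio undefined")
    ratio = broken.v0 / native.v0
    # first-order: var = (se_b/n)^2 + (b*se_n/n^2)^2, valid also at b = 0
    se = float(
        np.hypot(broken.se / native.v0, broken.v0 * native.se / native.v0**2)
    )
    return RatioPoint(nacl_mM=nacl_mM, ratio=ratio, se=se)


def dilution_final_concentration(
    stock_mM: float, added_uL: float, total_uL: float
) -> float:
    """Final concentration after diluting ``added`` µL of stock to ``total`` µL.

    Example: 10 µL of 2 M (2000 mM) substrate into 100 µL total → 200 mM.
    """
    if added_uL <= 0 or total_uL <= 0:
        raise InputError("volumes must be positive")
    if added_uL > total_uL:
        raise InputError("added volume cannot exceed total volume")
    return stock_mM * added_uL / total_uL


def average_replicates(
    estimates: list[VelocityEstimate],
) -> tuple[float, float]:
    """Replicate V0s → (mean, SE = sample SD / √n)."""
    if not estimates:
        raise InputError("no velocity estimates to average")
    v = np.array([e.v0 for e in estimates])
    n = len(v)
    se = 0.0 if n == 1 else float(v.std(ddof=1) / np.sqrt(n))
    return float(v.mean()), se


def analyze_assays(
    series: list[AssaySeries],
    range_mM: tuple[float, float] = (100.0, 500.0),
    **velocity_kwargs,
):
    """Full assay analysis: V0 per condition, per-state fits, slope test, ratios.

    Replicates are averaged to one V0 ± SE per (state, salt) before the
    regression.  Returns a dict with keys ``v0`` (per-condition table),
    ``fits`` (state → LinearFit), ``comparison`` (SlopeComparison, broken −
    native) and ``ratios`` (list of RatioPoint by salt).
    """
    grouped: dict[tuple[str, float], list[VelocityEstimate]] = {}
    for s in series:
        grouped.setdefault((s.state, s.nacl_mM), []).append(
            initial_velocity(s, **velocity_kwargs)
        )
    v0: dict[tuple[str, float], tuple[float, float]] = {
        key: average_replicates(ests) for key, ests in grouped.items()
    }
    fits = {}
    for state in ("native", "broken"):
        pts = [
            (salt, mean, se)
            for (st, salt), (mean, se) in sorted(v0.items())
            if st == state
        ]
        if pts:
            fits[state] = regress_v0_vs_salt(pts, range_mM=range_mM)
    comparison = None
    if "native" in fits and "broken" in fits:
        comparison = compare_slopes(fits["broken"], fits["native"])
    salts = sorted({salt for (_, salt) in v0})
    ratios = []
    for salt in salts:
        if ("broken", salt) in v0 and ("native", salt) in v0:
            b_mean, b_se = v0[("broken", salt)]
            n_mean, n_se = v0[("native", salt)]
            ratios.append(
                v0_ratio(
                    VelocityEstimate(v0=b_mean, se=b_se, window=(0, 0), r2=1.0),
                    VelocityEstimate(v0=n_mean, se=n_se, window=(0, 0), r2=1.0),
                    nacl_mM=salt,
                )
            )
    return {"v0": v0, "fits": fits, "comparison": comparison, "ratios": ratios}
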