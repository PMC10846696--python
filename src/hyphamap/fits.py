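"""Growth-law fits: doubling law, linear area growth, exponential counts.

Three laws describe the growing network:

* apexes, nodes and total length follow the doubling law
  ``X(t) = X0 * 2**((t + t0) / tau)`` after the lag phase, with ``tau`` the
  characteristic doubling time and ``t0`` a user-supplied temporal offset
  (manually adjusted so the onset values X0 land near their expected
  values -- about 3 apexes, 1 node, 10-20 hypha diameters of length);
* the total intra-thallus area S(t) grows linearly after its lag, fitted by
  ordinary least squares on a user-chosen window, quality reported as
  R^2 = 1 - SS_res / SS_tot;
* the number of intra-thallus areas grows exponentially,
  ``count(t) = beta * exp(alpha * t)``, fitted log-linearly with
  Poisson-motivated weights on counts within a window (5 to 336 by
  default, the usable range before extraction saturates).

All fits weight points by their supplied uncertainties (1/sigma^2) and
report 1-sd parameter uncertainties from the fit covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoublingFit", "LinearFit", "ExponentialCountFit",
           "fit_doubling", "fit_linear_area", "fit_exponential_counts",
           "adjust_t0"]


class FitError(ValueError):
    """The requested fit is not identifiable on the given data."""


@dataclass
class DoublingFit:
    """X(t) = X0 * 2**((t + t0) / tau)."""

    X0: float
    X0_sd: float
    tau: float
    tau_sd: float
    t0: float
    t0_sd: float | None
    chi2_reduced: float
    window: tuple[float, float]
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.X0 * 2.0 ** ((np.asarray(t) + self.t0) / self.tau)


@dataclass
class LinearFit:
    """S(t) = a * t + b on [t_min, t_max]."""

    slope: float
    slope_sd: float
    intercept: float
    r_squared: float
    t_min: float
    t_max: float
    n_points: int


@dataclass
class ExponentialCountFit:
    """count(t) = beta * exp(alpha * t) for counts inside the window."""

    alpha: float
    alpha_sd: float
    beta: float
    count_window: tuple[float, float]
    r_squared: float
    n_points: int


def fit_doubling(times, X, sigmas, t0: float = 0.0,
                 window: tuple[float, float] | None = None,
                 free_t0: bool = False, reweight: int = 3) -> DoublingFit:
    """Weighted nonlinear least squares of the doubling law.

    ``t0`` is a fixed input by default, mirroring the manual adjustment of
    the temporal offset; pass ``free_t0=True`` to fit it, but note that on
    a single series X0 and t0 are degenerate (only X0 * 2**(t0/tau) is
    identifiable), so their individual uncertainties blow up -- prefer
    :func:`adjust_t0`, which pins t0 with onset-value expectations.
    ``window`` is a
    ``(t_low, t_high)`` interval of times to include; points outside are
    ignored.  Uncertainties are 1 sd from the covariance with
    ``absolute_sigma=True``; the reduced chi-square is reported so the
    error model can be judged.

    Count-type uncertainties evaluated at the *observed* values (e.g.
    sigma = sqrt(X)) correlate the weights with the noise and bias the
    fit low: a point that fluctuates down also gets a smaller sigma and
    therefore more weight.  ``reweight`` iterations rescale each supplied
    sigma by ``sqrt(model / observed)`` -- evaluating the same error law
    at the fitted model instead -- which removes that bias for any
    variance proportional to X.  Set ``reweight=0`` to treat the supplied
    sigmas as fixed.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(X, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if window is None:
        window = (float(t.min()), float(t.max()))
    keep = (t >= window[0] - 1e-12) & (t <= window[1] + 1e-12)
    t, x, s = t[keep], x[keep], s[keep]
    if len(t) < 3:
        raise FitError(f"need >= 3 in-window points, have {len(t)}")
    if np.any(s <= 0):
        raise FitError("sigmas must be positive")
    if np.any(x <= 0) or np.allclose(x, x[0]):
        raise FitError("doubling fit needs positive, non-constant X")

    # log2 regression for starting values
    slope, icpt = np.polyfit(t, np.log2(x), 1)
    if slope <= 0:
        raise FitError("X does not grow over the fit window")
    tau0 = 1.0 / slope

    if free_t0:
        def model(tt, x0, tau, tt0):
            return x0 * 2.0 ** ((tt + tt0) / tau)
        p0 = [x[0] / 2.0 ** ((t[0] + t0) / tau0), tau0, t0]
    else:
        def model(tt, x0, tau):
            return x0 * 2.0 ** ((tt + t0) / tau)
        p0 = [x[0] / 2.0 ** ((t[0] + t0) / tau0), tau0]

    s_fit = s
    popt, pcov = curve_fit(model, t, x, p0=p0, sigma=s_fit,
                           absolute_sigma=True, maxfev=20000)
    for _ in range(max(0, int(reweight))):
        pred = np.clip(model(t, *popt), 1e-12, None)
        s_fit = s * np.sqrt(pred / x)
        popt, pcov = curve_fit(model, t, x, p0=popt, sigma=s_fit,
                               absolute_sigma=True, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    resid = (x - model(t, *popt)) / s_fit
    dof = max(len(t) - len(popt), 1)
    chi2_red = float((resid ** 2).sum() / dof)
    if free_t0:
        x0v, tauv, t0v = popt
        return DoublingFit(X0=float(x0v), X0_sd=float(perr[0]),
                           tau=float(tauv), tau_sd=float(perr[1]),
                           t0=float(t0v), t0_sd=float(perr[2]),
                           chi2_reduced=chi2_red, window=window,
                           n_points=len(t))
    x0v, tauv = popt
    return DoublingFit(X0=float(x0v), X0_sd=float(perr[0]),
                       tau=float(tauv), tau_sd=float(perr[1]),
                       t0=t0, t0_sd=None, chi2_reduced=chi2_red,
                       window=window, n_points=len(t))


def adjust_t0(series: dict, expected_X0: dict, t0_grid,
              window: tuple[float, float] | None = None,
              ) -> tuple[float, dict]:
    """Grid-search the shared temporal offset t0 across A/N/L series.

    For a single series the doubling-law residual chi-square is invariant
    under t0 (X0 absorbs any shift), so t0 is chosen by the onset values
    instead: for each candidate t0 the doubling law is fitted to every
    series and scored by how far the fitted onset values X0 land from
    their expected values, sum over series of
    ``((X0 - center) / halfwidth)**2`` with ``expected_X0`` giving
    ``(low, high)`` per series (center = midpoint, halfwidth = half the
    range).  This automates the manual adjustment of t0 until the X0 fall
    "in the range of the respective expected values".

    ``series`` maps a name (e.g. "A", "N", "L") to ``(times, X, sigmas)``;
    ``expected_X0`` maps the same names to ``(low, high)``.  Returns the
    best t0 and the fits obtained with it.
    """
    t0_grid = np.asarray(t0_grid, dtype=float)
    if t0_grid.size == 0:
        raise ValueError("empty t0 grid")
    missing = set(series) - set(expected_X0)
    if missing:
        raise ValueError(f"expected_X0 missing for {sorted(missing)}")
    best = None
    for t0 in t0_grid:
        score = 0.0
        fits = {}
        try:
            for name, (t, x, s) in series.items():
                f = fit_doubling(t, x, s, t0=float(t0), window=window)
                lo, hi = expected_X0[name]
                center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
                score += ((f.X0 - center) / half) ** 2
                fits[name] = f
        except FitError:
            continue
        if best is None or score < best[0]:
            best = (score, float(t0), fits)
    if best is None:
        raise FitError("no t0 candidate produced a valid fit")
    return best[1], best[2]


def fit_linear_area(times, S, t_min: float, t_max: float) -> LinearFit:
    """OLS linear fit of the total intra-thallus area on [t_min, t_max].

    The slope uncertainty comes from the residual variance; with exactly
    two points the fit is perfect and the slope uncertainty is NaN.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(S, dtype=float)
    keep = (t >= t_min - 1e-12) & (t <= t_max + 1e-12)
    t, s = t[keep], s[keep]
    if len(t) < 2:
        raise FitError("linear fit needs >= 2 in-window points")
    tbar = t.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0:
        raise FitError("all points at the same time")
    slope = float(((t - tbar) * (s - s.mean())).sum() / sxx)
    intercept = float(s.mean() - slope * tbar)
    resid = s - (slope * t + intercept)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((s - s.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if len(t) > 2:
        slope_sd = math.sqrt(ss_res / (len(t) - 2) / sxx)
    else:
        slope_sd = float("nan")
    return LinearFit(slope=slope, slope_sd=slope_sd, intercept=intercept,
                     r_squared=r2, t_min=t_min, t_max=t_max, n_points=len(t))


def fit_exponential_counts(times, counts,
                           count_window: tuple[float, float] = (5, 336),
                           method: str = "loglinear") -> ExponentialCountFit:
    """Fit count(t) = beta * exp(alpha * t) using counts within the window.

    Only points whose *count* lies inside ``count_window`` (inclusive)
    enter the fit.  The default method regresses ln(count) on time with
    weights equal to the counts (the Poisson delta-method variance of
    ln(count) is 1/count); ``method="nls"`` runs the direct nonlinear fit
    instead, which agrees with the log-linear route on noiseless data.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(counts, dtype=float)
    keep = (c >= count_window[0]) & (c <= count_window[1])
    t, c = t[keep], c[keep]
    if len(t) < 3:
        raise FitError(f"need >= 3 points with counts in {count_window}, "
                       f"have {len(t)}")
    if method == "nls":
        a0, b0 = _loglinear(t, c)[:2]
        popt, pcov = curve_fit(lambda tt, b, a: b * np.exp(a * tt), t, c,
                               p0=[b0, a0], sigma=np.sqrt(c),
                               absolute_sigma=True, maxfev=20000)
        beta, alpha = float(popt[0]), float(popt[1])
        alpha_sd = float(np.sqrt(pcov[1, 1]))
    elif method == "loglinear":
        alpha, beta, alpha_sd = _loglinear(t, c)
    else:
        raise ValueError(f"unknown method {method!r}")
    # R^2 in log space, where the model is linear
    pred = math.log(beta) + alpha * t
    y = np.log(c)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExponentialCountFit(alpha=alpha, alpha_sd=alpha_sd, beta=beta,
                               count_window=count_window, r_squared=r2,
                               n_points=len(t))


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Weighted regression of ln(c) on t with Poisson weights w = c."""
    y = np.log(c)
    w = c
    W = w.sum()
    tbar = (w * t).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (t - tbar) ** 2).sum()
    alpha = float((w * (t - tbar) * (y - ybar)).sum() / sxx)
    icpt = float(ybar - alpha * tbar)
    resid = y - (alpha * t + icpt)
    dof = max(len(t) - 2, 1)
    scale = float((w * resid ** 2).sum() / dof)
    alpha_sd = math.sqrt(scale / sxx)
    return alpha, math.exp(icpt), alpha_sd
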