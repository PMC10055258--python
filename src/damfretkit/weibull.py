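"""Saturation-concentration (C50) estimation by Weibull curve fitting.

The average DAmFRET curve of a seeded protein — mean AmFRET per expression
bin, using bins holding at least 100 cells — rises like a stretched
exponential and is fit to

    AmFRET(c) = Amp * (1 - exp(-ln2 * (c / C50)**a))

where ``Amp`` is the asymptotic AmFRET, ``C50`` the concentration at which
the curve reaches half its asymptote (exactly: AmFRET(C50) = Amp/2 for any
steepness ``a``), and ``a`` the stretch/steepness exponent, constrained to
[0.1, 10].  Initial values come from a Gaussian-smoothed curve; Amp and C50
are box-constrained to within 2-fold of those guesses.  Parameter errors are
estimated by Monte-Carlo refits under residual-scale perturbations.
Supersaturability is the fold change between null-seeded ("stochastic") and
self-seeded C50s, computed within an experimental batch only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .profiles import BinnedProfile

__all__ = [
    "MeanCurve",
    "WeibullFit",
    "weibull_eval",
    "mean_curve",
    "select_fit_window",
    "fit_weibull",
    "mc_errors",
    "supersaturability",
    "FitWindowError",
]

A_BOUNDS = (0.1, 10.0)


class FitWindowError(Exception):
    """No usable rising segment: the fit abstains."""


def weibull_eval(c, amp: float, c50: float, a: float):
    """Stretched-exponential assembly curve; AmFRET(C50) = Amp/2 exactly."""
    if c50 <= 0 or a <= 0:
        raise ValueError("weibull_eval requires C50 > 0 and a > 0")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    out = amp * (1.0 - np.exp(-np.log(2.0) * (c / c50) ** a))
    return out if out.ndim else float(out)


@dataclass
class MeanCurve:
    """Mean AmFRET per expression bin, restricted to well-populated bins."""

    bin_centers: np.ndarray  # expression, p.d.u.
    mean_amfret: np.ndarray
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.bin_centers)


def mean_curve(profile: BinnedProfile, min_count: int = 100) -> MeanCurve:
    """Average DAmFRET curve from a binned profile (bins with >= 100 cells)."""
    keep = profile.counts >= min_count
    return MeanCurve(
        bin_centers=profile.bin_centers[keep],
        mean_amfret=profile.mean_amfret[keep],
        counts=profile.counts[keep],
    )


def select_fit_window(
    curve: MeanCurve,
    slope_fraction: float = 0.05,
    sustain: int = 2,
    smooth_sigma: float = 2.0,
    override: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Deterministic surrogate for choosing fit limits by visual inspection.

    On the Gaussian-smoothed curve, the window starts at the first bin whose
    log-concentration slope exceeds ``slope_fraction`` of the maximum slope
    for ``sustain`` consecutive bins, and ends at the first later bin where
    the slope falls back below that threshold (or the last bin).  An explicit
    ``override`` window always wins.
    """
    if override is not None:
        return override
    if len(curve) < 6:
        raise FitWindowError(f"only {len(curve)} usable bins (need >= 6)")
    y = gaussian_filter1d(curve.mean_amfret.astype(float), smooth_sigma)
    logx = np.log10(curve.bin_centers)
    slope = np.gradient(y, logx)
    smax = slope.max()
    if smax <= 0:
        raise FitWindowError("curve never increases")
    above = slope >= slope_fraction * smax
    start = None
    for i in range(len(above) - sustain + 1):
        if above[i : i + sustain].all():
            start = i
            break
    if start is None:
        raise FitWindowError("no sustained rising segment")
    peak = start + int(np.argmax(slope[start:]))
    end = len(curve) - 1
    for j in range(peak, len(above)):
        if not above[j]:
            end = j
            break
    if end - start + 1 < 4:
        end = min(len(curve) - 1, start + 3)
    return start, end


@dataclass
class WeibullFit:
    amp: float
    c50: float  # p.d.u.
    a: float
    amp_sd: float
    c50_sd: float
    a_sd: float
    window: tuple[int, int]
    converged: bool
    residual_sd: float


def fit_weibull(
    curve: MeanCurve,
    window: tuple[int, int] | None = None,
    rng_seed: int = 0,
    n_mc: int = 0,
) -> WeibullFit:
    """Bounded least-squares Weibull fit of a mean DAmFRET curve.

    Initial Amp is the maximum of the Gaussian-smoothed curve, initial C50
    the concentration where the smoothed curve first reaches half that
    maximum, initial a = 2.  Amp and C50 are constrained to [guess/2,
    guess*2]; a to [0.1, 10].  A fit whose optimizer fails, or that lands on
    a box boundary, reports ``converged=False`` with best-effort parameters.
    With ``n_mc`` > 0, Monte-Carlo parameter errors are attached.
    """
    if window is None:
        window = select_fit_window(curve)
    i0, i1 = window
    x = curve.bin_centers[i0 : i1 + 1].astype(float)
    y = curve.mean_amfret[i0 : i1 + 1].astype(float)
    if len(x) < 4:
        raise ValueError("fit window must contain at least 4 points")

    ysm = gaussian_filter1d(y, 2.0)
    amp0 = float(max(ysm.max(), 1e-6))
    half = np.flatnonzero(ysm >= amp0 / 2)
    c50_0 = float(x[half[0]] if len(half) else x[len(x) // 2])
    p0 = np.array([amp0, c50_0, 2.0])
    lo = np.array([amp0 / 2, c50_0 / 2, A_BOUNDS[0]])
    hi = np.array([amp0 * 2, c50_0 * 2, A_BOUNDS[1]])

    def resid(p):
        return weibull_eval(x, p[0], p[1], p[2]) - y

    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-8, ftol=1e-8, gtol=1e-8)
    amp, c50, a = sol.x
    at_bound = bool(
        np.any(np.isclose(sol.x[:2], lo[:2], rtol=1e-6))
        or np.any(np.isclose(sol.x[:2], hi[:2], rtol=1e-6))
    )
    converged = bool(sol.success) and not at_bound
    res_sd = float(np.std(sol.fun, ddof=min(3, len(x) - 1)))
    fit = WeibullFit(
        amp=float(amp),
        c50=float(c50),
        a=float(a),
        amp_sd=np.nan,
        c50_sd=np.nan,
        a_sd=np.nan,
        window=window,
        converged=converged,
        residual_sd=res_sd,
    )
    if n_mc > 0:
        fit = mc_errors(fit, curve, n_mc=n_mc, rng_seed=rng_seed)
    return fit


def mc_errors(
    fit: WeibullFit, curve: MeanCurve, n_mc: int = 100, rng_seed: int = 0
) -> WeibullFit:
    """Monte-Carlo parameter errors by residual-scale perturbation.

    Refits ``n_mc`` curves perturbed by Gaussian noise with the fitted
    residual standard deviation and reports the SD of each parameter across
    refits (zero residuals give zero errors).
    """
    i0, i1 = fit.window
    x = curve.bin_centers[i0 : i1 + 1].astype(float)
    y0 = weibull_eval(x, fit.amp, fit.c50, fit.a)
    rng = np.random.default_rng(rng_seed)
    lo = np.array([fit.amp / 2, fit.c50 / 2, A_BOUNDS[0]])
    hi = np.array([fit.amp * 2, fit.c50 * 2, A_BOUNDS[1]])
    p0 = np.array([fit.amp, fit.c50, fit.a])
    draws = np.empty((n_mc, 3))
    for k in range(n_mc):
        yk = y0 + rng.normal(0.0, fit.residual_sd, size=len(x))
        sol = least_squares(
            lambda p: weibull_eval(x, p[0], p[1], p[2]) - yk,
            p0,
            bounds=(np.minimum(lo, p0), np.maximum(hi, p0)),
            xtol=1e-8,
            ftol=1e-8,
        )
        draws[k] = sol.x
    sds = draws.std(axis=0, ddof=1) if n_mc > 1 else np.zeros(3)
    return WeibullFit(
        amp=fit.amp,
        c50=fit.c50,
        a=fit.a,
        amp_sd=float(sds[0]),
        c50_sd=float(sds[1]),
        a_sd=float(sds[2]),
        window=fit.window,
        converged=fit.converged,
        residual_sd=fit.residual_sd,
    )


@dataclass(frozen=True)
class Supersaturability:
    """Fold change between stochastic (null-seeded) and seeded C50.

    ``fold_reduction`` = C50_stochastic / C50_seeded (>= 1 when seeding
    lowers the saturation concentration); ``ratio_seeded_to_stochastic`` is
    the reciprocal orientation, carried explicitly.
    """

    fold_reduction: float
    ratio_seeded_to_stochastic: float
    batch: str


def supersaturability(
    c50_stochastic: float,
    c50_seeded: float,
    batch_stochastic: str = "",
    batch_seeded: str = "",
) -> Supersaturability:
    """Supersaturability of a protein from same-batch C50 pairs only."""
    if batch_stochastic != batch_seeded:
        raise ValueError(
            f"C50 ratio requires same-batch measurements "
            f"({batch_stochastic!r} vs {batch_seeded!r})"
        )
    if c50_stochastic <= 0 or c50_seeded <= 0:
        raise ValueError("C50 values must be positive")
    return Supersaturability(
        fold_reduction=c50_stochastic / c50_seeded,
        ratio_seeded_to_stochastic=c50_seeded / c50_stochastic,
        batch=batch_stochastic,
    )
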