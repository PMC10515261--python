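"""Sub-asymptotic parametric tail fit and return-level extrapolation.

Above a cut-on level λ0 the exceedance function is modelled by the
four-parameter form

    p(λ) ≈ q · exp{ −a (λ − b)^c },   q ∈ (0, 1], a > 0, b < λ0, c ∈ [0.1, 10]

which contains the Gumbel-type exponential tail at c = 1 while letting c
absorb sub-asymptotic curvature, so the fit can use moderate levels where
counts are still plentiful instead of only the far tail. Parameters are
chosen to minimise the weighted sum of squared log-residuals

    Σ_j w_j ( ln p̂(λ_j) − ln q + a (λ_j − b)^c )²,
    w_j = ( ln ci_hi(λ_j) − ln ci_lo(λ_j) )^{-2}

so grid points with tight count-based confidence bands dominate. For fixed
(b, c) the model is linear in (ln q, a) and is solved by weighted linear
least squares; the outer search over (b, c) runs Nelder–Mead from the best
point of a coarse grid, making the whole fit deterministic for given data.
Individual parameters can trade off against each other — the fitted
*function*, not the tuple, is the contract.

The extrapolated 95% band is obtained by fitting the same parametric form to
the empirical ci_lo and ci_hi curves and inverting those fits, which keeps
the band monotone in the target probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import DomainError, InsufficientTailError, InversionError
from .exceedance import ExceedanceFunction

_C_BOUNDS = (0.1, 10.0)
_MIN_POINTS = 4


def tail_model(lam, q, a, b, c):
    """Evaluate p(λ) = q·exp{−a(λ−b)^c} (λ must exceed b)."""
    lam = np.asarray(lam, dtype=float)
    return q * np.exp(-a * np.power(lam - b, c))


@dataclass
class TailFitResult:
    """Fitted tail parameters plus separate fits to the CI curves."""

    q: float
    a: float
    b: float
    c: float
    cut_on: float
    objective: float
    band_params: dict  # {"lo": (q,a,b,c) | None, "hi": (q,a,b,c) | None}
    n_points: int

    @property
    def params(self):
        return (self.q, self.a, self.b, self.c)

    def __call__(self, lam):
        return tail_model(lam, *self.params)


@dataclass
class ReturnForecast:
    """Return level at a target exceedance probability, with 95% CI."""

    return_period: float | None
    events_per_year: float | None
    target_prob: float
    level: float
    ci: tuple


def return_period_to_prob(return_period: float, events_per_year: float) -> float:
    """Per-event exceedance probability of the T-year level: 1/(T·m)."""
    if return_period <= 0 or events_per_year <= 0:
        raise DomainError("return_period and events_per_year must be positive")
    return 1.0 / (return_period * events_per_year)


def _wls_inner(y, x, w):
    """Min over (lnq ≤ 0, a > 0) of Σ w (y − lnq + a·x)²; returns (obj, lnq, a)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    sxy = (w * (x - mx) * (y - my)).sum()
    if sxx <= 0:
        return np.inf, 0.0, np.nan
    a = -sxy / sxx  # slope of y on x is −a
    lnq = my + a * mx
    if lnq > 0.0:  # enforce q ≤ 1 by refitting on the boundary
        lnq = 0.0
        sxx0 = (w * x * x).sum()
        a = -(w * x * y).sum() / sxx0 if sxx0 > 0 else np.nan
    if not np.isfinite(a) or a <= 0:
        return np.inf, lnq, a
    resid = y - (lnq - a * x)
    return float((w * resid**2).sum()), lnq, a


def _fit_curve(lam, p, w, cut_on):
    """Fit q·exp{−a(λ−b)^c} to (lam, p) by WLS in log space.

    Returns (params, objective). ``lam`` strictly above b is guaranteed by
    parameterising b = cut_on − exp(u) < cut_on ≤ min(lam).
    """
    y = np.log(p)
    span = max(lam.max() - cut_on, 1e-12)

    def eval_bc(b, c):
        x = np.power(lam - b, c)
        return _wls_inner(y, x, w)

    def objective(theta):
        u, v = theta
        b = cut_on - np.exp(u)
        c = np.clip(np.exp(v), *_C_BOUNDS)
        return eval_bc(b, c)[0]

    # coarse deterministic start grid over (b, c)
    best = (np.inf, None)
    for delta in np.geomspace(0.01 * span, 10.0 * span, 6):
        for c in np.geomspace(0.25, 4.0, 7):
            theta = (np.log(delta), np.log(c))
            obj = objective(theta)
            if obj < best[0]:
                best = (obj, theta)
    if best[1] is None or not np.isfinite(best[0]):
        return None, np.inf
    res = minimize(
        objective,
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 600},
    )
    theta = res.x if res.fun <= best[0] else np.asarray(best[1])
    obj = min(float(res.fun), best[0])
    b = cut_on - np.exp(theta[0])
    c = float(np.clip(np.exp(theta[1]), *_C_BOUNDS))
    _, lnq, a = eval_bc(b, c)
    if not np.isfinite(a):
        return None, np.inf
    return (float(np.exp(lnq)), float(a), float(b), c), obj


def _log_band_width(func: ExceedanceFunction, mask):
    """ln(ci_hi/ci_lo) per point, with a symmetric-in-log fallback where the
    lower band was clipped to zero, floored to keep weights finite."""
    est = func.estimate[mask]
    hi = func.ci_hi[mask]
    lo = func.ci_lo[mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        width = np.where(lo > 0, np.log(hi) - np.log(lo), 2.0 * (np.log(hi) - np.log(est)))
    width = np.where(np.isfinite(width), width, np.nan)
    fallback = np.nanmax(width) if np.isfinite(width).any() else 1.0
    width = np.where(np.isfinite(width), width, fallback)
    return np.maximum(width, 1e-6)


def _first_of_each_step(func: ExceedanceFunction, mask: np.ndarray) -> np.ndarray:
    """Keep one grid point per step of the empirical function.

    The empirical p̂ is a step function of λ; an equally spaced grid samples
    long flat steps (e.g. the stretch between the two largest events) many
    times, and every duplicate carries the *same* exceedance counts. Left in,
    those duplicates multiply the weight of a single observation, so only the
    first grid point of each (numer, denom) run enters the fit.
    """
    out = mask.copy()
    idx = np.flatnonzero(mask)
    for prev, cur in zip(idx[:-1], idx[1:]):
        if func.numer[cur] == func.numer[prev] and func.denom[cur] == func.denom[prev]:
            out[cur] = False
    return out


def fit_tail(func: ExceedanceFunction, cut_on: float) -> TailFitResult:
    """Fit the parametric tail to p̂ above ``cut_on``, and to its CI curves."""
    grid = func.grid
    usable = (grid >= cut_on) & (func.numer > 0) & np.isfinite(func.estimate)
    usable &= func.estimate > 0
    usable = _first_of_each_step(func, usable)
    n_use = int(np.count_nonzero(usable))
    if n_use < _MIN_POINTS:
        raise InsufficientTailError(
            f"only {n_use} usable grid points above cut-on {cut_on}; need >= {_MIN_POINTS}"
        )
    lam = grid[usable]
    w = _log_band_width(func, usable) ** -2

    params, obj = _fit_curve(lam, func.estimate[usable], w, cut_on)
    if params is None:
        raise InsufficientTailError("tail fit did not converge to admissible parameters")

    band_params = {}
    for name, curve in (("lo", func.ci_lo), ("hi", func.ci_hi)):
        cmask = usable & np.isfinite(curve) & (curve > 0)
        if np.count_nonzero(cmask) >= _MIN_POINTS:
            wb = _log_band_width(func, cmask) ** -2
            p_band, _ = _fit_curve(grid[cmask], curve[cmask], wb, cut_on)
            band_params[name] = p_band
        else:
            band_params[name] = None

    return TailFitResult(
        q=params[0],
        a=params[1],
        b=params[2],
        c=params[3],
        cut_on=cut_on,
        objective=obj,
        band_params=band_params,
        n_points=n_use,
    )


def _invert(params, target_prob):
    q, a, b, c = params
    if not (0.0 < target_prob < q):
        raise InversionError(
            f"target probability {target_prob} outside invertible range (0, {q})"
        )
    return float(b + (np.log(q / target_prob) / a) ** (1.0 / c))


def predict_level(
    fit: TailFitResult,
    target_prob: float,
    return_period: float | None = None,
    events_per_year: float | None = None,
) -> ReturnForecast:
    """Invert the fitted tail at ``target_prob``; CI from the band fits."""
    level = _invert(fit.params, target_prob)
    lo = hi = np.nan
    if fit.band_params.get("lo") is not None:
        try:
            lo = _invert(fit.band_params["lo"], target_prob)
        except InversionError:
            lo = np.nan
    if fit.band_params.get("hi") is not None:
        try:
            hi = _invert(fit.band_params["hi"], target_prob)
        except InversionError:
            hi = np.nan
    return ReturnForecast(
        return_period=return_period,
        events_per_year=events_per_year,
        target_prob=target_prob,
        level=level,
        ci=(lo, hi),
    )
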