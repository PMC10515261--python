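"""Conditional exceedance (ACER-style) estimation on the merged series.

For a level λ and conditioning number k, the estimator counts windows of k
consecutive merged events whose first k−1 values stay at or below λ and asks
how often the k-th value exceeds λ:

    p̂_k(λ) = a_k(λ) / b_k(λ)

with a_k the number of such windows ending in an exceedance and b_k the
number of qualifying windows. k=1 reduces to the empirical survival function
of R; larger k absorbs serial clustering, and the working k is the smallest
at which p̂_k stabilises (``check_k_convergence``). Ties R_j = λ count as
non-exceedance throughout (strict >).

Pointwise 95% bands use the normal approximation for rare-event counts,
p̂·(1 ± z/√a_k), clipped to [0, 1] and undefined where a_k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, WindowError
from .transform import MergedSeries

Z95 = 1.959963984540054


@dataclass
class ExceedanceFunction:
    """Empirical p̂_k on a level grid with counts and pointwise 95% bands."""

    k: int
    grid: np.ndarray
    numer: np.ndarray  # a_k(λ): conditional exceedance counts
    denom: np.ndarray  # b_k(λ): qualifying window counts
    estimate: np.ndarray  # a_k/b_k; NaN where b_k = 0
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.grid,
                "numer": self.numer,
                "denom": self.denom,
                "estimate": self.estimate,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int, n_events: int) -> "ExceedanceFunction":
        return cls(
            k=k,
            grid=df["lambda"].to_numpy(float),
            numer=df["numer"].to_numpy(float),
            denom=df["denom"].to_numpy(float),
            estimate=df["estimate"].to_numpy(float),
            ci_lo=df["ci_lo"].to_numpy(float),
            ci_hi=df["ci_hi"].to_numpy(float),
            n_events=n_events,
        )


def default_grid(merged: MergedSeries, cut_on: float, size: int = 100) -> np.ndarray:
    """Equally spaced levels from the cut-on up to the sample maximum."""
    if len(merged) == 0:
        raise EmptyInputError("merged series is empty")
    top = float(np.max(merged.values))
    if top <= cut_on:
        raise ValueError(f"cut-on {cut_on} is at or above the sample maximum {top}")
    return np.linspace(cut_on, top, size)


def _acer_counts(R: np.ndarray, k: int, grid: np.ndarray):
    """Vectorized window counting; O(N) per grid level."""
    N = len(R)
    numer = np.empty(len(grid))
    denom = np.empty(len(grid))
    for i, lam in enumerate(grid):
        exceed = R > lam
        if k == 1:
            numer[i] = np.count_nonzero(exceed)
            denom[i] = N
            continue
        below = ~exceed
        cs = np.concatenate(([0], np.cumsum(below)))
        j = np.arange(k - 1, N)  # candidate window ends (0-based)
        window_ok = (cs[j] - cs[j - (k - 1)]) == (k - 1)
        denom[i] = np.count_nonzero(window_ok)
        numer[i] = np.count_nonzero(window_ok & exceed[j])
    return numer, denom


def estimate_acer(merged: MergedSeries, k: int, grid: np.ndarray) -> ExceedanceFunction:
    """Estimate p̂_k over ``grid`` with pointwise 95% confidence bands."""
    if len(merged) == 0:
        raise EmptyInputError("merged series is empty")
    if k < 1:
        raise WindowError(f"conditioning number k must be >= 1, got {k}")
    N = len(merged)
    if k > N:
        raise WindowError(f"k={k} exceeds the number of merged events N={N}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or (len(grid) > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("grid must be a non-empty strictly increasing 1-D array")

    numer, denom = _acer_counts(np.asarray(merged.values, dtype=float), k, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        estimate = np.where(denom > 0, numer / np.maximum(denom, 1), np.nan)
        rel = Z95 / np.sqrt(np.maximum(numer, 1))
        ci_lo = np.where(numer > 0, np.clip(estimate * (1 - rel), 0.0, 1.0), np.nan)
        ci_hi = np.where(numer > 0, np.clip(estimate * (1 + rel), 0.0, 1.0), np.nan)
    return ExceedanceFunction(
        k=k,
        grid=grid,
        numer=numer,
        denom=denom,
        estimate=estimate,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        n_events=N,
    )


@dataclass
class KConvergenceResult:
    """Outcome of the k-convergence diagnostic.

    ``converged_k`` is the smallest k whose successor changes p̂ by at most
    ``tol`` (relative, worst grid point); None when no k ≤ k_max−1 converges.
    ``discrepancies`` maps k to that worst relative change between p̂_k and
    p̂_{k+1}.
    """

    converged_k: int | None
    discrepancies: dict
    tol: float
    k_max: int

    @property
    def converged(self) -> bool:
        return self.converged_k is not None


def _max_rel_discrepancy(f1: ExceedanceFunction, f2: ExceedanceFunction) -> float:
    valid = (f1.denom > 0) & (f2.denom > 0)
    if not valid.any():
        return np.nan
    p1 = f1.estimate[valid]
    p2 = f2.estimate[valid]
    diff = np.abs(p2 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(diff == 0, 0.0, diff / p1)  # inf when p1=0 but p2>0
    return float(np.max(rel))


def check_k_convergence(
    merged: MergedSeries, k_max: int, grid: np.ndarray, tol: float = 0.1
) -> KConvergenceResult:
    """Find the smallest k at which successive p̂_k agree within ``tol``."""
    if k_max < 2:
        raise WindowError(f"k_max must be >= 2, got {k_max}")
    if k_max > len(merged):
        raise WindowError(f"k_max={k_max} exceeds the number of merged events N={len(merged)}")
    funcs = {k: estimate_acer(merged, k, grid) for k in range(1, k_max + 1)}
    discrepancies = {
        k: _max_rel_discrepancy(funcs[k], funcs[k + 1]) for k in range(1, k_max)
    }
    converged_k = None
    for k in range(1, k_max):
        d = discrepancies[k]
        if np.isfinite(d) and d <= tol:
            converged_k = k
            break
    return KConvergenceResult(
        converged_k=converged_k, discrepancies=discrepancies, tol=tol, k_max=k_max
    )
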