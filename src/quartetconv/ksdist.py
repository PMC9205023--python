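"""Ks-distribution dating: fixed-bandwidth KDE plus minimal Gaussian-mixture
curve fitting to locate polyploidy peaks.

Following standard practice for dating whole-genome duplications from
synonymous-distance distributions, the Ks values of block anchors are
smoothed with a Gaussian kernel of absolute bandwidth 0.05, and the density
*curve* (not the sample) is fit by nonlinear least squares with an
increasing number of Gaussian components until the coefficient of
determination against the KDE curve reaches the threshold (default 0.95).
Each evolutionary event is then represented by its component, youngest
first.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .models import KsMixtureFit

#: Ks values at/above this are treated as saturated and excluded from fitting
KS_SATURATION = 3.0

GRID_POINTS = 512


def kde_ks(
    values: Sequence[float],
    bandwidth: float = 0.05,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of Ks values on a uniform grid.

    The grid spans [0, max(ks) + 3*bandwidth] with 512 points unless given
    explicitly.  Values at or beyond the saturation cutoff are excluded.
    """
    vals = np.asarray([v for v in values if np.isfinite(v) and 0 <= v < KS_SATURATION])
    if vals.size < 2:
        raise ValueError("need at least two finite Ks values below saturation")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(0.0, float(vals.max()) + 3.0 * bandwidth, GRID_POINTS)
    # reflect at 0 so the density of the non-negative Ks support integrates to 1
    z = (grid[:, None] - vals[None, :]) / bandwidth
    zr = (grid[:, None] + vals[None, :]) / bandwidth
    dens = (np.exp(-0.5 * z * z) + np.exp(-0.5 * zr * zr)).sum(axis=1)
    dens /= vals.size * bandwidth * math.sqrt(2 * math.pi)
    return grid, dens


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x)
    for k in range(0, len(params), 3):
        w, mu, sd = params[k : k + 3]
        out = out + w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    return out


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def _initial_means(grid: np.ndarray, density: np.ndarray, k: int) -> list[float]:
    peaks, props = find_peaks(density, height=0.0)
    if peaks.size:
        order = np.argsort(props["peak_heights"])[::-1]
        means = [float(grid[peaks[i]]) for i in order[:k]]
    else:
        means = []
    q = 1
    while len(means) < k:
        means.append(float(np.quantile(grid, q / (k + 1))))
        q += 1
    return means[:k]


def _fit_k(
    grid: np.ndarray, density: np.ndarray, k: int, p0_list: list[list[float]]
) -> Optional[tuple[np.ndarray, float]]:
    span = float(grid[-1] - grid[0]) or 1.0
    lower = [1e-8, float(grid[0]), 1e-4] * k
    upper = [np.inf, float(grid[-1]), span] * k
    best = None
    for p0 in p0_list:
        p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, lower, upper)]
        try:
            popt, _ = curve_fit(
                _gaussian_sum, grid, density, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        r2 = _r_squared(density, _gaussian_sum(grid, *popt))
        if best is None or r2 > best[1]:
            best = (popt, r2)
    return best


def fit_min_gaussians(
    grid: np.ndarray,
    density: np.ndarray,
    r2_threshold: float = 0.95,
    max_components: int = 5,
    bandwidth: float = 0.05,
) -> KsMixtureFit:
    """Smallest number of Gaussian components whose least-squares fit to the
    density curve reaches the R^2 threshold.

    Initialization is multi-start: means at the k largest curve maxima, and
    (for k > 1) the best (k-1)-component solution extended by one component
    at the largest-residual grid point — which also makes R^2 non-decreasing
    in k.
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    if grid.size != density.size or grid.size < 4:
        raise ValueError("grid and density must be equal-length (>= 4 points)")
    if not np.any(density > 0):
        raise ValueError("density curve is identically zero")

    prev: Optional[np.ndarray] = None
    best_overall: Optional[tuple[np.ndarray, float, int]] = None
    for k in range(1, max_components + 1):
        means = _initial_means(grid, density, k)
        w0 = float(np.trapezoid(density, grid)) / k
        p0_peaks = []
        for mu in means:
            p0_peaks.extend([w0, mu, max(2.0 * bandwidth, 1e-3)])
        starts = [p0_peaks]
        if prev is not None:
            resid = density - _gaussian_sum(grid, *prev)
            mu_extra = float(grid[int(np.argmax(resid))])
            starts.append(list(prev) + [max(w0 * 0.1, 1e-6), mu_extra,
                                        max(2.0 * bandwidth, 1e-3)])
        fit = _fit_k(grid, density, k, starts)
        if fit is None:
            continue
        popt, r2 = fit
        if prev is not None and best_overall is not None and r2 < best_overall[1]:
            # keep monotone: reuse the padded previous solution if better
            padded = list(prev) + [1e-8, float(grid[len(grid) // 2]), bandwidth]
            r2_padded = _r_squared(density, _gaussian_sum(grid, *padded))
            if r2_padded > r2:
                popt, r2 = np.asarray(padded), r2_padded
        prev = popt
        if best_overall is None or r2 > best_overall[1]:
            best_overall = (popt, r2, k)
        if r2 >= r2_threshold:
            comps = sorted(
                [(float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
                 for i in range(0, len(popt), 3)],
                key=lambda c: c[1],
            )
            return KsMixtureFit(
                bandwidth=bandwidth, grid=list(grid), density=list(density),
                components=comps, r_squared=r2, n_components=k, converged=True,
            )
    popt, r2, k = best_overall
    comps = sorted(
        [(float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
         for i in range(0, len(popt), 3)],
        key=lambda c: c[1],
    )
    return KsMixtureFit(
        bandwidth=bandwidth, grid=list(grid), density=list(density),
        components=comps, r_squared=r2, n_components=k, converged=False,
    )


def peaks_to_event_windows(
    fit: KsMixtureFit, events: Sequence[str], n_sigma: float = 2.0
) -> dict[str, tuple[float, float]]:
    """Map mixture components to event windows [mean - 2 sd, mean + 2 sd].

    Components are sorted by mean; events must be given youngest first (e.g.
    ['SCT', 'ECH'] within a genome, or ['ORTHOLOG'] between genomes).
    Overlapping adjacent windows are truncated at the midpoint between the
    component means so the windows stay disjoint.
    """
    if fit.n_components < len(events):
        raise ValueError(
            f"{len(events)} events requested but only {fit.n_components} components fitted"
        )
    comps = sorted(fit.components, key=lambda c: c[1])[: len(events)]
    # assign the youngest events to the lowest-mean components, in order
    windows: dict[str, tuple[float, float]] = {}
    bounds = []
    for (w, mu, sd) in comps:
        bounds.append([max(0.0, mu - n_sigma * sd), mu + n_sigma * sd, mu])
    for i in range(len(bounds) - 1):
        if bounds[i][1] > bounds[i + 1][0]:
            mid = 0.5 * (bounds[i][2] + bounds[i + 1][2])
            bounds[i][1] = min(bounds[i][1], mid)
            bounds[i + 1][0] = max(bounds[i + 1][0], math.nextafter(mid, math.inf))
    for event, b in zip(events, bounds):
        windows[event] = (b[0], b[1])
    return windows
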