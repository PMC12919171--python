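"""Evans-Blue leakage quantification and its temporal decay model.

Extravasated dye is quantified on greyscale intensity rasters: pixels
with intensity strictly greater than 100 (the calibrated extravasation
threshold) count toward the leakage area, and the integrated density is
the plain intensity sum over the region of interest.  Both statistics are
exactly additive over disjoint ROIs.

The time course of leakage is modeled by a two-phase exponential decay

    y(t) = P + A_fast * exp(-k_fast t) + A_slow * exp(-k_slow t)

with k_fast > k_slow > 0 enforced by the smooth parameterization
k_slow = exp(theta_1), k_fast = k_slow + exp(theta_2), which removes
label switching between the phases.  For fixed rates the model is linear
in (P, A_fast, A_slow), so those are solved by bounded linear least
squares (amplitudes constrained non-negative: this is a decay model)
inside a multistart search over a data-driven rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares, lsq_linear

EXTRAVASATION_THRESHOLD = 100.0


class LeakageError(ValueError):
    pass


@dataclass
class IntensityImage:
    """Non-negative greyscale raster with an optional boolean ROI mask.

    Row-major, origin top-left, 0-based coordinates; ROI membership is
    full-pixel (no partial-area weighting).
    """

    pixels: np.ndarray
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise LeakageError("pixels must be a 2-D grid")
        if not np.isfinite(self.pixels).all():
            raise LeakageError("pixel intensities must be finite")
        if self.roi is None:
            self.roi = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != self.pixels.shape:
                raise LeakageError("ROI mask shape must match the image")

    @classmethod
    def from_file(cls, path: str | Path, roi: np.ndarray | None = None) -> "IntensityImage":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # collapse RGB(A) to luminance-free mean
            arr = arr[..., :3].mean(axis=-1)
        return cls(arr, roi)


def extravasation_area(
    image: IntensityImage, threshold: float = EXTRAVASATION_THRESHOLD
) -> tuple[int, float]:
    """(pixel count, ROI-area fraction) of pixels strictly above threshold."""
    roi_size = int(image.roi.sum())
    if roi_size == 0:
        raise LeakageError("empty ROI")
    count = int(np.count_nonzero(image.pixels[image.roi] > threshold))
    return count, count / roi_size


def integrated_density(image: IntensityImage) -> float:
    """Sum of intensities over the ROI."""
    if int(image.roi.sum()) == 0:
        raise LeakageError("empty ROI")
    return float(image.pixels[image.roi].sum())


# ----------------------------------------------------------------------
@dataclass
class DecayFit:
    plateau: float
    a_fast: float
    k_fast: float
    a_slow: float
    k_slow: float
    rss: float
    converged: bool
    at_boundary: bool  # an amplitude pinned at the zero bound
    single_phase: "SinglePhaseFit | None" = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.plateau
            + self.a_fast * np.exp(-self.k_fast * t)
            + self.a_slow * np.exp(-self.k_slow * t)
        )


@dataclass
class SinglePhaseFit:
    plateau: float
    amplitude: float
    rate: float
    rss: float


def _linear_amplitudes(t: np.ndarray, y: np.ndarray, rates: np.ndarray):
    """Solve (P, A_1..A_r) >= 0 amplitudes for fixed decay rates."""
    cols = [np.ones_like(t)] + [np.exp(-k * t) for k in rates]
    A = np.column_stack(cols)
    lb = np.r_[-np.inf, np.zeros(len(rates))]
    res = lsq_linear(A, y, bounds=(lb, np.full(len(rates) + 1, np.inf)))
    resid = A @ res.x - y
    return res.x, float(resid @ resid)


_THETA_CAP = 30.0  # |log rate| bound keeping exp() finite during search


def _fit_with_rates(t: np.ndarray, y: np.ndarray, theta0: np.ndarray):
    """Optimize theta = (log k_slow, log(k_fast - k_slow)) by nonlinear
    least squares with amplitudes profiled out at each step."""

    def residuals(theta):
        theta = np.clip(theta, -_THETA_CAP, _THETA_CAP)
        k_slow = np.exp(theta[0])
        k_fast = k_slow + np.exp(theta[1])
        coef, _ = _linear_amplitudes(t, y, np.array([k_fast, k_slow]))
        pred = coef[0] + coef[1] * np.exp(-k_fast * t) + coef[2] * np.exp(-k_slow * t)
        return pred - y

    sol = least_squares(residuals, theta0, method="lm", max_nfev=400)
    theta = np.clip(sol.x, -_THETA_CAP, _THETA_CAP)
    k_slow = float(np.exp(theta[0]))
    k_fast = k_slow + float(np.exp(theta[1]))
    coef, rss = _linear_amplitudes(t, y, np.array([k_fast, k_slow]))
    return k_fast, k_slow, coef, rss, bool(sol.success)


def fit_two_phase_decay(times, values) -> DecayFit:
    """Fit the two-phase decay by multistart profiled least squares.

    Needs at least five distinct timepoints (five parameters).  Initial
    rate pairs span 1/max(t) .. 1/min(t) geometrically.  The nested
    single-phase fit is returned for comparison; by nesting its RSS can
    never beat the two-phase RSS.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise LeakageError("times and values must be 1-D and equal length")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise LeakageError("times and values must be finite")
    if len(np.unique(t)) < 5:
        raise LeakageError("need >= 5 distinct timepoints for 5 parameters")
    if np.any(t <= 0):
        raise LeakageError("times must be positive hours")

    k_lo, k_hi = 1.0 / t.max(), 1.0 / t.min()
    grid = np.geomspace(k_lo / 4, k_hi * 4, 6)
    best = None
    for i, ks in enumerate(grid):
        for kf in grid[i + 1:]:
            theta0 = np.array([np.log(ks), np.log(max(kf - ks, 1e-8))])
            try:
                k_fast, k_slow, coef, rss, ok = _fit_with_rates(t, y, theta0)
            except Exception:
                continue
            if best is None or rss < best[3] - 1e-12:
                best = (k_fast, k_slow, coef, rss, ok)
    if best is None:
        raise LeakageError("decay optimization failed from every start")
    k_fast, k_slow, coef, rss, ok = best
    plateau, a_fast, a_slow = float(coef[0]), float(coef[1]), float(coef[2])
    scale = max(float(np.abs(y).max()), 1e-12)
    at_boundary = a_fast <= 1e-10 * scale or a_slow <= 1e-10 * scale

    sp = _fit_single_phase(t, y)
    # guard the nesting guarantee: a single-phase solution is also a
    # two-phase solution with one amplitude at the zero bound
    if sp.rss < rss:
        k_slow = sp.rate
        k_fast = sp.rate * 100.0
        plateau, a_fast, a_slow = sp.plateau, 0.0, sp.amplitude
        rss = sp.rss
        at_boundary = True
    return DecayFit(
        plateau=plateau, a_fast=a_fast, k_fast=k_fast,
        a_slow=a_slow, k_slow=k_slow, rss=rss,
        converged=ok and not at_boundary, at_boundary=at_boundary,
        single_phase=sp,
    )


def _fit_single_phase(t: np.ndarray, y: np.ndarray) -> SinglePhaseFit:
    k_lo, k_hi = 1.0 / t.max(), 1.0 / t.min()
    best = None
    for k0 in np.geomspace(k_lo / 4, k_hi * 4, 10):

        def residuals(theta):
            k = np.exp(np.clip(theta[0], -_THETA_CAP, _THETA_CAP))
            coef, _ = _linear_amplitudes(t, y, np.array([k]))
            return coef[0] + coef[1] * np.exp(-k * t) - y

        try:
            sol = least_squares(residuals, np.array([np.log(k0)]),
                                method="lm", max_nfev=200)
        except Exception:
            continue
        k = float(np.exp(np.clip(sol.x[0], -_THETA_CAP, _THETA_CAP)))
        coef, rss = _linear_amplitudes(t, y, np.array([k]))
        if best is None or rss < best.rss:
            best = SinglePhaseFit(float(coef[0]), float(coef[1]), k, rss)
    if best is None:
        raise LeakageError("single-phase optimization failed")
    return best
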