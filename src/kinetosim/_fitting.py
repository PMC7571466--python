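"""Shared nonlinear Gaussian peak fitting on 1D profiles."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths


class SinglePeakError(ValueError):
    """Profile contains fewer discernible maxima than the requested model."""


class MultiPeakError(ValueError):
    """Profile contains more discernible maxima than the requested model."""


def gaussian(x, amplitude, center, sigma):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _model(x, *params):
    n = (len(params) - 1) // 3
    y = np.full_like(x, params[-1], dtype=float)
    for i in range(n):
        a, c, s = params[3 * i : 3 * i + 3]
        y = y + gaussian(x, a, c, s)
    return y


def detect_peaks(x: np.ndarray, y: np.ndarray, smooth: float = 1.5, min_prominence: float = 0.05):
    """Initial peak guesses: (center, amplitude, sigma) triples sorted by prominence."""
    ys = gaussian_filter1d(y.astype(float), smooth)
    span = float(np.ptp(ys))
    if span <= 0:
        return []
    idx, props = find_peaks(ys, prominence=min_prominence * span)
    if len(idx) == 0:
        return []
    widths = peak_widths(ys, idx, rel_height=0.5)[0]
    step = float(np.median(np.diff(x)))
    baseline = float(np.min(ys))
    order = np.argsort(props["prominences"])[::-1]
    out = []
    for k in order:
        sigma = max(widths[k] * step / 2.35482, step / 2)
        out.append((float(x[idx[k]]), float(ys[idx[k]] - baseline), sigma))
    return out


def fit_gaussian_peaks(x: np.ndarray, y: np.ndarray, n_peaks: int, p0=None):
    """Least-squares fit of ``n_peaks`` Gaussians plus a shared constant baseline.

    Returns ``(peaks, baseline, relative_error, converged)`` where ``peaks``
    is a list of (amplitude, center, sigma) sorted by center and
    ``relative_error`` is the RMS residual divided by the mean fitted
    amplitude.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 * n_peaks + 1:
        raise ValueError("profile too short for the requested number of peaks")
    if p0 is None:
        guesses = detect_peaks(x, y)
        if len(guesses) < n_peaks:
            raise SinglePeakError(
                f"found {len(guesses)} discernible peak(s), expected {n_peaks}"
            )
        guesses = sorted(guesses[:n_peaks], key=lambda g: g[0])
        p0 = []
        for c, a, s in guesses:
            p0.extend([a, c, s])
        p0.append(float(np.min(y)))
    span = float(np.ptp(y)) or 1.0
    step = float(np.median(np.diff(x)))
    lo, hi = float(x.min()), float(x.max())
    lower = ([0.0, lo, step / 4] * n_peaks) + [min(float(np.min(y)), 0.0) - span]
    upper = ([10 * span, hi, (hi - lo)] * n_peaks) + [float(np.max(y)) + span]
    p0 = np.clip(p0, lower, upper)
    converged = True
    try:
        popt, _ = curve_fit(
            _model, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError:
        popt = np.asarray(p0, float)
        converged = False
    resid = y - _model(x, *popt)
    peaks = sorted(
        [tuple(popt[3 * i : 3 * i + 3]) for i in range(n_peaks)], key=lambda p: p[1]
    )
    mean_amp = float(np.mean([abs(p[0]) for p in peaks])) or 1.0
    rel_err = float(np.sqrt(np.mean(resid**2)) / mean_amp)
    return peaks, float(popt[-1]), rel_err, converged


def gaussian_2d(coords, amplitude, x0, y0, sx, sy, baseline):
    x, y = coords
    return (
        amplitude
        * np.exp(-0.5 * (((x - x0) / sx) ** 2 + ((y - y0) / sy) ** 2))
        + baseline
    ).ravel()


def fit_gaussian_2d(x, y, z, p0=None):
    """2D elliptical Gaussian fit (axis-aligned) on a grid of intensities.

    ``x``/``y`` are 1D coordinate arrays for the columns/rows of ``z``.
    Returns ``(params, relative_error, converged)`` with params
    (amplitude, x0, y0, sx, sy, baseline).
    """
    xx, yy = np.meshgrid(x, y)
    zf = np.asarray(z, float)
    if p0 is None:
        base = float(zf.min())
        w = np.clip(zf - base, 0, None)
        tot = w.sum() or 1.0
        x0 = float((w.sum(axis=0) * x).sum() / tot)
        y0 = float((w.sum(axis=1) * y).sum() / tot)
        sx = np.sqrt(max((w.sum(axis=0) * (x - x0) ** 2).sum() / tot, (x[1] - x[0]) ** 2 / 12))
        sy = np.sqrt(max((w.sum(axis=1) * (y - y0) ** 2).sum() / tot, (y[1] - y[0]) ** 2 / 12))
        p0 = [float(zf.max() - base), x0, y0, float(sx), float(sy), base]
    span = float(np.ptp(zf)) or 1.0
    lower = [0.0, x.min(), y.min(), (x[1] - x[0]) / 4, (y[1] - y[0]) / 4, zf.min() - span]
    upper = [
        10 * span,
        x.max(),
        y.max(),
        (x.max() - x.min()),
        (y.max() - y.min()),
        zf.max() + span,
    ]
    p0 = np.clip(p0, lower, upper)
    converged = True
    try:
        popt, _ = curve_fit(
            gaussian_2d, (xx, yy), zf.ravel(), p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError:
        popt = np.asarray(p0, float)
        converged = False
    resid = zf.ravel() - gaussian_2d((xx, yy), *popt)
    rel_err = float(np.sqrt(np.mean(resid**2)) / (abs(popt[0]) or 1.0))
    return tuple(float(v) for v in popt), rel_err, converged
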