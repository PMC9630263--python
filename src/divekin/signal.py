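"""Low-pass filtering, residual-analysis cutoff selection, differentiation.

The default filter is a 4th-order Butterworth applied forward and backward
(zero lag).  Because the dual pass squares the magnitude response, the
per-pass cutoff is widened so that the -3 dB point of the *combined*
response sits at the requested cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import UniformSeries

__all__ = [
    "butterworth_lowpass",
    "dual_pass_gain",
    "residual_analysis_cutoff",
    "differentiate",
    "ResidualAnalysisWarning",
]


class ResidualAnalysisWarning(UserWarning):
    """Raised when the residual curve is degenerate (e.g. noise-free input)."""


def _dual_pass_correction(order: int) -> float:
    # Per-pass cutoff divisor so the combined dual-pass response is -3 dB
    # at the nominal cutoff: (2**(1/n_passes) - 1) ** (1 / (2 * order)).
    return (2.0 ** 0.5 - 1.0) ** (1.0 / (2.0 * order))


def dual_pass_gain(f: np.ndarray, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Analytic magnitude response of the corrected dual-pass Butterworth.

    For an order-``n`` Butterworth run forward and backward with per-pass
    cutoff ``fa``, the magnitude is ``1 / (1 + (f / fa)**(2 n))``.
    """
    fa = cutoff_hz / _dual_pass_correction(order)
    return 1.0 / (1.0 + (np.asarray(f, dtype=float) / fa) ** (2 * order))


def butterworth_lowpass(
    x: UniformSeries,
    cutoff_hz: float,
    order: int = 4,
    zero_lag: bool = True,
) -> UniformSeries:
    """Zero-phase Butterworth low-pass on a uniformly sampled series.

    Parameters
    ----------
    x : UniformSeries
        Input signal (1-D or N x 3); filtered column-wise.
    cutoff_hz : float
        Effective cutoff of the combined forward-backward response
        (the per-pass design cutoff is widened accordingly).
    order : int
        Per-pass Butterworth order.
    zero_lag : bool
        If False, a single causal pass at the nominal cutoff is used
        (phase lag is then uncorrected; not the default pipeline setting).
    """
    nyq = x.rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz) "
            f"for rate {x.rate} Hz"
        )
    if len(x) < 3 * order:
        raise ValueError(
            f"series of length {len(x)} too short for order-{order} filtering "
            f"(need >= {3 * order})"
        )
    if zero_lag:
        fc = cutoff_hz / _dual_pass_correction(order)
        if fc >= nyq:
            # Corrected per-pass cutoff would exceed Nyquist; clamp just below.
            fc = 0.999 * nyq
        sos = sps.butter(order, fc, btype="low", fs=x.rate, output="sos")
        y = sps.sosfiltfilt(sos, x.values, axis=0)
    else:
        sos = sps.butter(order, cutoff_hz, btype="low", fs=x.rate, output="sos")
        y = sps.sosfilt(sos, x.values, axis=0)
    return x.with_values(y)


def _residual_curve(x: UniformSeries, grid_hz: np.ndarray, order: int) -> np.ndarray:
    vals = x.values if x.values.ndim == 2 else x.values[:, None]
    out = np.empty(len(grid_hz))
    for i, fc in enumerate(grid_hz):
        f = butterworth_lowpass(x, float(fc), order=order)
        fv = f.values if f.values.ndim == 2 else f.values[:, None]
        out[i] = np.sqrt(np.mean((vals - fv) ** 2))
    return out


def residual_analysis_cutoff(
    x: UniformSeries,
    grid_hz: np.ndarray,
    order: int = 4,
    noise_fraction: float = 0.5,
) -> float:
    """Select a low-pass cutoff by residual analysis.

    For each candidate cutoff the RMS residual between raw and filtered
    signal is computed.  A straight line is fitted to the residual curve
    over its high-frequency, noise-dominated tail (the upper
    ``noise_fraction`` of the grid); the selected cutoff is the lowest
    candidate whose residual has fallen to the line's zero-frequency
    intercept.

    Returns the grid minimum with a :class:`ResidualAnalysisWarning` when
    the construction is degenerate (flat residual curve, noise-free input).
    """
    grid = np.asarray(grid_hz, dtype=float)
    if grid.ndim != 1 or len(grid) < 3:
        raise ValueError("grid must be a 1-D vector of at least 3 cutoffs")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    nyq = x.rate / 2.0
    if grid[0] <= 0 or grid[-1] >= nyq:
        raise ValueError(f"grid must lie within (0, Nyquist={nyq} Hz)")

    resid = _residual_curve(x, grid, order)
    scale = resid.max()
    if scale <= 0 or scale < 1e-12 * max(1.0, float(np.abs(x.values).max())):
        warnings.warn(
            "flat residual curve; returning grid minimum",
            ResidualAnalysisWarning,
            stacklevel=2,
        )
        return float(grid[0])

    n_noise = max(2, int(np.ceil(noise_fraction * len(grid))))
    slope, intercept = np.polyfit(grid[-n_noise:], resid[-n_noise:], 1)
    if intercept < 1e-3 * scale:
        # no appreciable noise floor: residuals in the noise region are
        # negligible against the signal-distortion residuals at low cutoffs
        warnings.warn(
            "noise-free or degenerate residual curve; returning grid minimum",
            ResidualAnalysisWarning,
            stacklevel=2,
        )
        return float(grid[0])
    if intercept <= 0:
        warnings.warn(
            "non-positive residual-line intercept; returning grid minimum",
            ResidualAnalysisWarning,
            stacklevel=2,
        )
        return float(grid[0])

    below = np.nonzero(resid <= intercept)[0]
    if len(below) == 0:
        warnings.warn(
            "residual curve never reaches the noise-line intercept; "
            "returning grid maximum",
            ResidualAnalysisWarning,
            stacklevel=2,
        )
        return float(grid[-1])
    return float(grid[below[0]])


def differentiate(x: UniformSeries) -> UniformSeries:
    """First time derivative: central differences, one-sided at the ends."""
    if len(x) < 3:
        raise ValueError(f"need at least 3 samples to differentiate, got {len(x)}")
    d = np.gradient(x.values, x.dt, axis=0)
    return x.with_values(d)
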