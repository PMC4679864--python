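"""Canonical double-gamma hemodynamic response function and event regressors.

The same single-trial response kernel is used by the forward simulator and by
the nuisance/stimulus design matrix, so that a noise-free simulated run is
exactly spanned by its own design.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

# Canonical double-gamma parameters: response peak at 6 s, undershoot peak at
# 16 s, unit dispersions, undershoot one sixth of the positive lobe.
PEAK_DELAY_S = 6.0
UNDERSHOOT_DELAY_S = 16.0
PEAK_DISPERSION = 1.0
UNDERSHOOT_DISPERSION = 1.0
UNDERSHOOT_RATIO = 1.0 / 6.0


def hrf_shape(t: np.ndarray) -> np.ndarray:
    """Unnormalized double-gamma HRF evaluated at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    pos = stats.gamma.pdf(t, PEAK_DELAY_S / PEAK_DISPERSION, scale=PEAK_DISPERSION)
    neg = stats.gamma.pdf(
        t, UNDERSHOOT_DELAY_S / UNDERSHOOT_DISPERSION, scale=UNDERSHOOT_DISPERSION
    )
    return pos - UNDERSHOOT_RATIO * neg


def double_gamma_hrf(tr_s: float, length_s: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on the TR grid, peak-normalized.

    Parameters
    ----------
    tr_s:
        Sampling interval (repetition time) in seconds; must be positive.
    length_s:
        Kernel support in seconds (at least 20 s so the undershoot is covered).

    Returns
    -------
    1-D kernel of ``round(length_s / tr_s)`` samples with maximum 1.
    """
    if tr_s <= 0:
        raise InvalidArgumentError(f"tr_s must be positive, got {tr_s}")
    if length_s < 20:
        raise InvalidArgumentError(f"length_s must be >= 20 s, got {length_s}")
    t = np.arange(int(round(length_s / tr_s))) * tr_s
    h = hrf_shape(t)
    return h / h.max()


def trial_response_kernel(
    duration_s: float, length_s: float = 32.0, dt: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar-convolved HRF for a single stimulus, on a fine time grid.

    Returns ``(t, r)`` with ``r`` normalized to peak 1, so that a planted
    amplitude equals the peak BOLD excursion of one isolated trial.
    """
    if duration_s <= 0:
        raise InvalidArgumentError(f"duration_s must be positive, got {duration_s}")
    t = np.arange(0.0, length_s + duration_s, dt)
    h = hrf_shape(t)
    box = (t < duration_s).astype(float)
    r = np.convolve(box, h)[: t.size] * dt
    return t, r / r.max()


def stimulus_regressor(
    onsets_s: np.ndarray,
    duration_s: float,
    n_vols: int,
    tr_s: float,
    t0_s: float = 0.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Sum of single-trial responses sampled at volume acquisition times."""
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    tk, rk = trial_response_kernel(duration_s, length_s=length_s)
    vol_times = t0_s + np.arange(n_vols) * tr_s
    reg = np.zeros(n_vols)
    for onset in onsets_s:
        rel = vol_times - onset
        reg += np.interp(rel, tk, rk, left=0.0, right=0.0)
    return reg
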