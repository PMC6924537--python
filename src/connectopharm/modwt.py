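"""Maximal-overlap discrete wavelet transform (MODWT).

The MODWT is the shift-invariant, non-decimated variant of the discrete
wavelet transform used to decompose BOLD time series into frequency bands
before computing wavelet correlations.  Scale ``j`` detail coefficients
capture fluctuations in the band ``[1/2^(j+1), 1/2^j]`` cycles per sample,
i.e. roughly 0.031-0.0625 Hz for scale 3 at a 2-s sampling interval.

Coefficients are computed with circular (periodic) filtering via the FFT;
the leading ``L_j - 1`` coefficients of each level, which mix the two ends
of the series, can be discarded to avoid wrap-around bias
(``boundary_width``).
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["modwt_detail", "boundary_width", "min_length"]

_SQRT2 = np.sqrt(2.0)


def _filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Rescaled MODWT wavelet/scaling filters (h/sqrt2, g/sqrt2)."""
    w = pywt.Wavelet(wavelet_name)
    g = np.asarray(w.dec_lo, dtype=float)[::-1] / _SQRT2
    h = np.asarray(w.dec_hi, dtype=float)[::-1] / _SQRT2
    return h, g


def boundary_width(wavelet_name: str, level: int) -> int:
    """Number of leading level-``level`` coefficients affected by circularity.

    Equals ``L_j - 1`` with ``L_j = (2^j - 1)(L - 1) + 1`` for a length-``L``
    base filter.
    """
    L = pywt.Wavelet(wavelet_name).dec_len
    return (2**level - 1) * (L - 1)


def min_length(wavelet_name: str, level: int, n_usable: int = 8) -> int:
    """Shortest series length leaving ``n_usable`` boundary-free coefficients."""
    return boundary_width(wavelet_name, level) + n_usable


def _circular_filter(v: np.ndarray, filt: np.ndarray, step: int) -> np.ndarray:
    """Circularly convolve rows of ``v`` with ``filt`` upsampled by ``step``.

    Computes ``out[t] = sum_l filt[l] * v[(t - step*l) mod N]`` for each row.
    """
    n = v.shape[-1]
    kernel = np.zeros(n)
    idx = (np.arange(filt.size) * step) % n
    np.add.at(kernel, idx, filt)
    return np.fft.irfft(np.fft.rfft(v, axis=-1) * np.fft.rfft(kernel), n=n, axis=-1)


def modwt_detail(
    x: np.ndarray,
    level: int,
    wavelet_name: str = "db4",
    discard_boundary: bool = True,
) -> np.ndarray:
    """MODWT detail (wavelet) coefficients at ``level`` for each row of ``x``.

    Parameters
    ----------
    x : array, shape (n_series, n_time) or (n_time,)
        Input series, one per row.
    level : int
        Decomposition level (scale index), ``>= 1``.
    wavelet_name : str
        Any orthogonal wavelet known to PyWavelets (default Daubechies-4).
    discard_boundary : bool
        Drop the leading circularity-affected coefficients (default).

    Returns
    -------
    array, shape (n_series, n_coeff)
        Detail coefficients; ``n_coeff = n_time - boundary_width`` when
        boundaries are discarded.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    need = min_length(wavelet_name, level) if discard_boundary else boundary_width(
        wavelet_name, level
    ) + 1
    if n < need:
        raise ValueError(
            f"series of length {n} too short for scale {level} with "
            f"'{wavelet_name}': need at least {need} samples"
        )
    h, g = _filters(wavelet_name)
    v = x
    w = None
    for j in range(1, level + 1):
        step = 2 ** (j - 1)
        w = _circular_filter(v, h, step)
        v = _circular_filter(v, g, step)
    assert w is not None
    if discard_boundary:
        w = w[:, boundary_width(wavelet_name, level):]
    return w
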