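"""Zero-phase FIR filtering primitives shared by the ASSR and ERP chains.

Filters are linear-phase (symmetric) FIR kernels designed with
``scipy.signal.firwin``; the group delay is compensated by centering the
convolution, so a single pass is zero-phase. Edges are reflection-padded
by one kernel length to suppress boundary transients.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve, firwin


def design_fir(order: int, fs: float, low_hz: float | None,
               high_hz: float | None) -> np.ndarray:
    """Design a linear-phase FIR kernel with ``order + 1`` taps (order even).

    ``low_hz``/``high_hz`` of None mean no edge on that side: (low, None)
    is a high-pass, (None, high) a low-pass, (low, high) a band-pass.
    A high edge at or above Nyquist degrades to a high-pass (a low-pass at
    Nyquist is a no-op).
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # type I (odd-length symmetric) for integer delay
    nyq = fs / 2
    if high_hz is not None and high_hz >= nyq:
        high_hz = None
    if low_hz is not None and low_hz <= 0:
        low_hz = None
    if low_hz is None and high_hz is None:
        raise ValueError("at least one finite band edge inside (0, fs/2) required")
    if low_hz is not None and high_hz is not None:
        return firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs)
    if low_hz is not None:
        return firwin(numtaps, low_hz, pass_zero=False, fs=fs)
    return firwin(numtaps, high_hz, pass_zero=True, fs=fs)


def filt_zero_phase(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel with zero net phase, length preserved.

    Works on the last axis. Reflection padding by the kernel length keeps
    boundary transients local.
    """
    x = np.asarray(x, dtype=float)
    L = len(kernel)
    pad = min(L, x.shape[-1] - 1)
    left = x[..., 1:pad + 1][..., ::-1]
    right = x[..., -pad - 1:-1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    y = fftconvolve(xp, kernel[(None,) * (x.ndim - 1) + (slice(None),)], mode="same",
                    axes=-1)
    return y[..., pad:pad + x.shape[-1]]


def moving_average_kernel(order: int) -> np.ndarray:
    """Boxcar kernel with ``order + 1`` taps, unit DC gain."""
    if order < 0:
        raise ValueError("order must be >= 0")
    n = order + 1
    return np.full(n, 1.0 / n)
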