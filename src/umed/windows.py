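"""Sliding windows and AR(2) feature extraction.

A window of length ``L_w`` samples slides along the recording in steps of
``d`` samples; every fully contained placement is one window, so a signal of
T samples yields ``IN = floor((T - L_w) / d) + 1`` windows. For each window
and each channel the first two autoregressive coefficients of

    W(r) = a_1 W(r-1) + a_2 W(r-2) + e(r)

are estimated by Burg's method (forward+backward prediction error minimized
through reflection coefficients). The per-channel (a_1, a_2) pairs are
concatenated channel-major into one feature vector per window, giving the
IN x (Q * order) feature matrix that downstream clustering consumes.

AR coefficients are scale-invariant by construction and location-invariant
because each window is demeaned before the Burg recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal import MultichannelSignal


class DegenerateWindowError(ValueError):
    """A window with (numerically) zero variance cannot yield AR features."""

    def __init__(self, message: str, window: int | None = None,
                 channel: int | None = None):
        super().__init__(message)
        self.window = window
        self.channel = channel


@dataclass(frozen=True)
class WindowSet:
    """The IN sliding windows defined by (L_w, d) over a T-sample signal.

    ``starts`` are 0-based sample indices; window ``i`` (1-based, W_1..W_IN)
    covers samples ``starts[i-1] .. starts[i-1] + L_w - 1``. A trailing
    partial window is discarded.
    """

    L_w: int
    d: int
    n_samples: int
    starts: np.ndarray

    @property
    def IN(self) -> int:
        """Number of windows."""
        return len(self.starts)


@dataclass(frozen=True)
class FeatureMatrix:
    """IN x S matrix of concatenated per-channel AR coefficients.

    Row i holds window W_{i+1}'s features in channel-major layout:
    ``[ch1:a1, ch1:a2, ch2:a1, ch2:a2, ...]``.
    """

    values: np.ndarray
    window_set: WindowSet
    n_channels: int
    order: int = 2

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def make_windows(signal: MultichannelSignal | int, L_w: int, d: int) -> WindowSet:
    """Build the sliding-window set for window length L_w and slide d.

    ``signal`` may be a :class:`MultichannelSignal` or a plain sample count.
    """
    T = signal if isinstance(signal, (int, np.integer)) else signal.n_samples
    L_w, d = int(L_w), int(d)
    if L_w < 4:
        raise ValueError(f"window length must be >= 4 samples, got {L_w}")
    if L_w > T:
        raise ValueError(f"window exceeds signal: L_w={L_w} > T={T}")
    if d < 1:
        raise ValueError(f"slide width must be >= 1 sample, got {d}")
    n = (T - L_w) // d + 1
    starts = np.arange(n, dtype=np.int64) * d
    return WindowSet(L_w=L_w, d=d, n_samples=T, starts=starts)


def _burg_batch(x: np.ndarray, order: int = 2) -> np.ndarray:
    """Burg AR coefficients for a batch of demeaned series.

    Parameters
    ----------
    x : ndarray, shape (..., n)
        Series along the last axis; each is demeaned internally.
    order : int
        AR order p.

    Returns
    -------
    ndarray, shape (..., order)
        Coefficients in the regression sign convention
        ``x[t] = a_1 x[t-1] + ... + a_p x[t-p] + e[t]``.

    Notes
    -----
    Classic Burg recursion: at stage m the reflection coefficient minimizing
    the summed forward+backward prediction error is
    ``k_m = -2 sum(f b) / (sum f^2 + sum b^2)``, and the prediction-error
    filter is updated by the Levinson step. Degenerate (zero-error) batches
    raise :class:`DegenerateWindowError` naming the first offending series.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    lead = x.shape[:-1]
    # c holds the prediction-error filter tail: 1 + c_1 z^-1 + ... ; a = -c.
    c = np.zeros(lead + (order,))
    f = x[..., 1:]
    b = x[..., :-1]
    for m in range(1, order + 1):
        den = np.sum(f * f, axis=-1) + np.sum(b * b, axis=-1)
        bad = den <= 0
        if np.any(bad):
            idx = np.argwhere(bad)[0] if lead else ()
            raise DegenerateWindowError(
                f"degenerate window (zero prediction error) at index "
                f"{tuple(int(i) for i in idx)}",
            )
        k = -2.0 * np.sum(f * b, axis=-1) / den
        c_prev = c[..., : m - 1]
        c = np.concatenate(
            [c_prev + k[..., None] * c_prev[..., ::-1], k[..., None],
             np.zeros(lead + (order - m,))],
            axis=-1,
        )
        f_new = f + k[..., None] * b
        b_new = b + k[..., None] * f
        f = f_new[..., 1:]
        b = b_new[..., :-1]
    return -c


def burg_ar2(window_samples: np.ndarray) -> tuple[float, float]:
    """Order-2 Burg AR coefficients of one window.

    Returns ``(a_1, a_2)`` in the convention
    ``W(r) = a_1 W(r-1) + a_2 W(r-2) + e(r)``. The window is demeaned first.

    Raises
    ------
    DegenerateWindowError
        If the window is constant (zero variance).
    """
    x = np.asarray(window_samples, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError(f"window too short for AR(2): {len(x)} samples")
    if np.ptp(x) == 0:
        raise DegenerateWindowError("degenerate window: constant samples")
    a = _burg_batch(x, order=2)
    return float(a[0]), float(a[1])


def feature_matrix(signal: MultichannelSignal, windows: WindowSet,
                   order: int = 2) -> FeatureMatrix:
    """AR feature matrix FV over all (window, channel) pairs.

    Every cell equals :func:`burg_ar2` (or its order-p generalization)
    applied to that window's slice of that channel. A degenerate window in
    any channel aborts with the 1-based window number and channel label.
    """
    if windows.n_samples != signal.n_samples:
        raise ValueError(
            f"window set built for T={windows.n_samples}, "
            f"signal has T={signal.n_samples}"
        )
    if order < 1:
        raise ValueError(f"AR order must be >= 1, got {order}")
    q = signal.n_channels
    out = np.empty((windows.IN, q * order))
    for ch in range(q):
        # (IN, L_w) strided view: all windows of this channel at once.
        view = sliding_window_view(signal.samples[ch], windows.L_w)
        sl = view[windows.starts]
        if np.any(np.ptp(sl, axis=1) == 0):
            w = int(np.argwhere(np.ptp(sl, axis=1) == 0)[0, 0])
            raise DegenerateWindowError(
                f"degenerate window W_{w + 1} in channel "
                f"{signal.channel_labels[ch]!r}: constant samples",
                window=w + 1, channel=ch,
            )
        try:
            out[:, ch * order:(ch + 1) * order] = _burg_batch(sl, order=order)
        except DegenerateWindowError as err:  # zero prediction error mid-recursion
            raise DegenerateWindowError(
                f"degenerate window in channel {signal.channel_labels[ch]!r}: "
                f"{err}", channel=ch,
            ) from err
    return FeatureMatrix(values=out, window_set=windows, n_channels=q,
                         order=order)
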