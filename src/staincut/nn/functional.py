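"""Low-level array primitives for the convolutional layers.

Images are laid out NCHW.  ``im2col``/``col2im`` are exact adjoints of each
other, which is what makes the transposed convolution below literally the
gradient of a strided convolution.
"""

from __future__ import annotations

import numpy as np


def pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv_out_size(size: int, k: int, s: int, p: int) -> int:
    return (size + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """Unfold sliding k x k windows into a matrix.

    Parameters
    ----------
    x : (N, C, H, W) array
    k, s, p : kernel size, stride, zero padding

    Returns
    -------
    (N, C*k*k, L) array where L is the number of window positions.
    """
    x = pad2d(x, p)
    n, c, h, w = x.shape
    ho = (h - k) // s + 1
    wo = (w - k) // s + 1
    sn, sc, sh, sw = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * s, sw * s),
        writeable=False,
    )
    return windows.reshape(n, c * k * k, ho * wo)


def col2im(cols: np.ndarray, x_shape: tuple, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto the image grid."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * p, w + 2 * p
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + ho * s : s, j : j + wo * s : s] += cols[:, :, i, j]
    if p:
        out = out[:, :, p : hp - p, p : wp - p]
    return out
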