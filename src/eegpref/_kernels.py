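"""Numba-compiled patch extraction for the CNN engine.

The convolution layers spend most of their time rearranging 'same'-padded
input windows into the patch matrix consumed by the BLAS matrix product;
doing that in one compiled pass (with the zero padding folded in, so no
intermediate padded array exists) keeps the engine fast on one CPU core.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def elu_forward(x: np.ndarray, alpha: float):
    """One-pass ELU: returns (activation, derivative)."""
    flat = x.ravel()
    out = np.empty_like(flat)
    deriv = np.empty_like(flat)
    for i in range(flat.size):
        v = flat[i]
        if v > 0.0:
            out[i] = v
            deriv[i] = 1.0
        else:
            e = alpha * (np.exp(v) - 1.0)
            out[i] = e
            deriv[i] = e + alpha
    return out.reshape(x.shape), deriv.reshape(x.shape)


@njit(cache=True)
def im2col_same(x: np.ndarray, k: int, pad_before: int) -> np.ndarray:
    """Channels-last patch matrix for a stride-1 'same' convolution.

    x: (N, H, W, C) float32.  Returns (N*H*W, k*k*C) where column
    ``(i*k + j)*C + c`` holds ``x[n, u+i-pad_before, v+j-pad_before, c]``
    (zero outside the image).
    """
    n, h, w, c = x.shape
    out = np.zeros((n * h * w, k * k * c), dtype=x.dtype)
    for ni in range(n):
        for u in range(h):
            for i in range(k):
                su = u + i - pad_before
                if su < 0 or su >= h:
                    continue
                for v in range(w):
                    row = (ni * h + u) * w + v
                    for j in range(k):
                        sv = v + j - pad_before
                        if sv < 0 or sv >= w:
                            continue
                        base = (i * k + j) * c
                        for ci in range(c):
                            out[row, base + ci] = x[ni, su, sv, ci]
    return out
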