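"""Separable Gaussian-derivative filtering with DC-free derivative kernels.

Kernels are sampled Gaussians truncated at 4 sigma (matching the common
``truncate=4`` convention).  The second-derivative kernel of a *sampled*
Gaussian does not sum exactly to zero, so a raw filter responds slightly to
constant images; here the order-2 kernel is DC-corrected (its residual sum
is removed along the order-0 kernel), which makes every derivative response
to a constant image exactly zero and derivative planes exactly invariant
under constant intensity offsets.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi


@lru_cache(maxsize=64)
def derivative_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(order 0, 1, 2) 1D convolution kernels at ``sigma``, radius 4 sigma."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    s2 = sigma * sigma
    phi = np.exp(-0.5 * x * x / s2)
    phi /= phi.sum()
    k1 = -x / s2 * phi  # sums to zero exactly (antisymmetric)
    k2 = (x * x / (s2 * s2) - 1.0 / s2) * phi
    k2 = k2 - k2.sum() * phi  # DC correction
    return phi, k1, k2


def gaussian_derivative(
    image: np.ndarray, sigma: float, order: tuple[int, int], mode: str = "reflect"
) -> np.ndarray:
    """Convolve with the separable Gaussian-derivative kernel ``order=(dy, dx)``."""
    kernels = derivative_kernels(float(sigma))
    ky = kernels[order[0]]
    kx = kernels[order[1]]
    # correlate1d with the reversed kernel == convolution with the kernel
    out = ndi.correlate1d(np.asarray(image, dtype=np.float64), ky[::-1], axis=0, mode=mode)
    return ndi.correlate1d(out, kx[::-1], axis=1, mode=mode)
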