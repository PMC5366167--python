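"""Jitted inner loops for the Gibbs sampler.

Both kernels sweep all markers once, drawing each coefficient from its full
conditional and maintaining the full-length residual incrementally.  The
subsampled kernel evaluates the data dot product x_j'e on the current bag
only and scales the marker sum of squares by psi; at psi = 1 without
replacement (``idx = arange(n)``, ``psi = 1.0``) its arithmetic is
bit-identical to the full-data kernel, which is kept as an independent code
path for the plain Gauss-Seidel residual-updating (GSRU) sampler.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_coefficients_subsampled(gen, Xt, e, b, idx, psi, d, lam, var_e, order):
    """One SBMC coefficient sweep; returns in-bag observation touches.

    Xt is the p x n transposed genotype matrix (C-contiguous so each marker
    row is contiguous).  e (length n) and b (length p) are updated in place.
    Markers with zero sum of squares are skipped and their effect stays 0.
    """
    m = idx.shape[0]
    n = e.shape[0]
    touches = 0
    for oo in range(order.shape[0]):
        j = order[oo]
        dj = d[j]
        if dj <= 0.0:
            continue
        xe = 0.0
        for k in range(m):
            i = idx[k]
            xe += Xt[j, i] * e[i]
        touches += m
        denom = psi * dj + lam
        mean = (xe + psi * dj * b[j]) / denom
        sd = np.sqrt(var_e / denom)
        b_new = gen.normal(mean, sd)
        delta = b_new - b[j]
        if delta != 0.0:
            for i in range(n):
                e[i] -= Xt[j, i] * delta
        b[j] = b_new
    return touches


@njit(cache=True)
def sweep_coefficients_full(gen, Xt, e, b, d, lam, var_e, order):
    """One plain full-data GSRU coefficient sweep; returns touches (n per marker)."""
    n = e.shape[0]
    touches = 0
    for oo in range(order.shape[0]):
        j = order[oo]
        dj = d[j]
        if dj <= 0.0:
            continue
        xe = 0.0
        for i in range(n):
            xe += Xt[j, i] * e[i]
        touches += n
        denom = dj + lam
        mean = (xe + dj * b[j]) / denom
        sd = np.sqrt(var_e / denom)
        b_new = gen.normal(mean, sd)
        delta = b_new - b[j]
        if delta != 0.0:
            for i in range(n):
                e[i] -= Xt[j, i] * delta
        b[j] = b_new
    return touches
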