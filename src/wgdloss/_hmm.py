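"""Numba kernels for the subgenome-tracking chain.

The hidden chain runs along the pillar order over the 2^n tracking
configurations (one bit per genome; a set bit means the genome's track 1
currently holds the subgenome-2 gene).  Between adjacent pillars each
genome's bit flips independently with probability theta, so the full
configuration-transition operator factorises into n symmetric 2x2 flips;
the kernels apply it axis by axis in O(n * 2^n) per step.  Scaled forward
and backward recursions are exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(E, flips, theta):
    """Scaled forward pass.

    E: (P, C) per-pillar emission likelihoods.
    flips: (G, C) int64; flips[g, c] = index of c with genome g's bit flipped.
    Returns (loglik, alpha, scale) with alpha[p] the normalised filtering
    distribution and scale[p] its normaliser.
    """
    P, C = E.shape
    G = flips.shape[0]
    alpha = np.empty((P, C))
    scale = np.empty(P)
    a = np.full(C, 1.0 / C)
    b = np.empty(C)
    for p in range(P):
        if p > 0:
            for g in range(G):
                for c in range(C):
                    b[c] = (1.0 - theta) * a[c] + theta * a[flips[g, c]]
                a, b = b, a
        s = 0.0
        for c in range(C):
            a[c] = a[c] * E[p, c]
            s += a[c]
        if s <= 0.0:
            return -np.inf, alpha, scale
        scale[p] = s
        for c in range(C):
            a[c] /= s
            alpha[p, c] = a[c]
    ll = 0.0
    for p in range(P):
        ll += np.log(scale[p])
    return ll, alpha, scale


@njit(cache=True)
def backward_scaled(E, flips, theta, scale):
    """Scaled backward pass matching :func:`forward_scaled`'s scaling."""
    P, C = E.shape
    G = flips.shape[0]
    beta = np.empty((P, C))
    b = np.ones(C)
    tmp = np.empty(C)
    for c in range(C):
        beta[P - 1, c] = 1.0
    for p in range(P - 2, -1, -1):
        for c in range(C):
            tmp[c] = E[p + 1, c] * beta[p + 1, c]
        for g in range(G):
            for c in range(C):
                b[c] = (1.0 - theta) * tmp[c] + theta * tmp[flips[g, c]]
            tmp, b = b, tmp
        s = scale[p + 1]
        for c in range(C):
            beta[p, c] = tmp[c] / s
    return beta
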