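"""Inner numerics of the SGD trainer.

One epoch visits the samples in a given order; for sample (i, j) with label y:

    z   = a_i . b_j            (clipped to +/-30 before exponentiation)
    F   = 1 / (1 + exp(-z))
    e   = y - F
    a_i <- a_i + eta * (e * F(1-F) * b_j - lambda * a_i)
    b_j <- b_j + eta * (e * F(1-F) * a_i - lambda * b_j)   # pre-update a_i

Both updates use pre-update values (a simultaneous step: the gradient of the
objective at the current point). The loop is jitted with numba when
available; the pure-Python path computes identical IEEE double sequences.
"""

from __future__ import annotations

import math

import numpy as np

CLIP = 30.0


def _sgd_epoch_py(A, B, di, si, y, order, eta, lam):
    k = A.shape[1]
    for t in order:
        i = di[t]
        j = si[t]
        z = 0.0
        for c in range(k):
            z += A[i, c] * B[j, c]
        if z > CLIP:
            z = CLIP
        elif z < -CLIP:
            z = -CLIP
        F = 1.0 / (1.0 + math.exp(-z))
        g = (y[t] - F) * F * (1.0 - F)
        for c in range(k):
            a = A[i, c]
            b = B[j, c]
            A[i, c] = a + eta * (g * b - lam * a)
            B[j, c] = b + eta * (g * a - lam * b)


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sgd_epoch_fast = njit(cache=False)(_sgd_epoch_py)
except ImportError:  # pragma: no cover
    _sgd_epoch_fast = _sgd_epoch_py


def sgd_epoch_inplace(A, B, di, si, y, order, eta, lam):
    """Run one epoch in place over float64/intp arrays."""
    _sgd_epoch_fast(A, B, di, si, y, order, float(eta), float(lam))


def sigmoid_scores(A, B, di, si):
    """Vectorized F_ij = sigmoid(a_i . b_j) with the same +/-30 clip."""
    z = np.clip(np.einsum("ij,ij->i", A[di], B[si]), -CLIP, CLIP)
    return 1.0 / (1.0 + np.exp(-z))


def objective(A, B, di, si, y, lam):
    """Regularized squared loss over the given samples.

    (1/2) * sum over samples of [(y - F)^2 + lambda (|a_i|^2 + |b_j|^2)];
    the regularization accrues once per sample occurrence of a row, matching
    the per-visit weight decay of the update rule.
    """
    F = sigmoid_scores(A, B, di, si)
    with np.errstate(over="ignore"):  # divergence surfaces as inf, caught upstream
        sq = (y - F) ** 2
        reg = lam * ((A[di] ** 2).sum(axis=1) + (B[si] ** 2).sum(axis=1))
        return 0.5 * float((sq + reg).sum())
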