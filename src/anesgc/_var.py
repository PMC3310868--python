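"""Compiled vector-autoregression recursions shared by the generator and the
model-consistency check."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def simulate_var(coefs, intercept, innovations, burn):
    """Simulate a k-dim VAR(p): y_t = c + sum_l A_l y_{t-l} + e_t.

    Parameters
    ----------
    coefs : (p, k, k) lag coefficient matrices A_1..A_p
    intercept : (k,) constant term
    innovations : (burn + n, k) pre-drawn innovation sequence
    burn : samples discarded from the start

    Returns (n, k) array.
    """
    p, k, _ = coefs.shape
    total = innovations.shape[0]
    y = np.zeros((total, k))
    for t in range(total):
        acc = intercept + innovations[t]
        for l in range(1, p + 1):
            if t - l >= 0:
                acc = acc + coefs[l - 1] @ y[t - l]
        y[t] = acc
    return y[burn:]


def companion_spectral_radius(coefs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a (p, k, k) VAR."""
    p, k, _ = coefs.shape
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate([coefs[l] for l in range(p)], axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye((p - 1) * k)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))
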