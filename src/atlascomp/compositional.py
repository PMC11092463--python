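"""Compositional-scale primitives shared across the package.

Category coefficients live on an unconstrained log-ratio scale; identifiability
is fixed by a sum-to-zero constraint across categories rather than a pinned
reference category, so intercept-free (cell-means) designs stay symmetric.
The constraint is enforced exactly by parametrising every coefficient row in
an orthonormal basis of the sum-to-zero subspace.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit
from scipy.special import softmax as _softmax


def sum_to_zero_basis(k: int) -> np.ndarray:
    """Orthonormal basis Q of shape (k, k-1) spanning {v : sum(v) = 0}.

    Columns are orthonormal and each sums to zero, so for free coordinates
    ``f`` the constrained vector ``Q @ f`` sums to zero exactly and
    ``||Q @ f|| == ||f||`` (priors transfer unchanged between scales).
    """
    if k < 2:
        raise ValueError("need at least 2 categories")
    a = np.eye(k) - np.full((k, k), 1.0 / k)
    # eigenvectors of the centering projector with unit eigenvalue
    vals, vecs = np.linalg.eigh(a)
    q = vecs[:, vals > 0.5]
    assert q.shape == (k, k - 1)
    return q


def softmax(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    return _softmax(eta, axis=axis)


def clr(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centred log-ratio transform of (strictly positive) proportions."""
    logp = np.log(p)
    return logp - logp.mean(axis=axis, keepdims=True)


def proportions_with_pseudocount(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Row proportions after adding a pseudo-count, guaranteed in (0, 1)."""
    y = np.asarray(counts, dtype=float) + pseudocount
    return y / y.sum(axis=-1, keepdims=True)


def logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p) - np.log1p(-p)


def expit(x: np.ndarray) -> np.ndarray:
    return _expit(x)
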