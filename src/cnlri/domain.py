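"""Leverage-based applicability domain (AD).

The leverage of a query vector x against a training design X is

    h(x) = x^T (X^T X)^{-1} x,

the diagonal of the hat matrix for training rows — a Mahalanobis-like
weighted distance of x from the bulk of the training set. A prediction
is considered inside the applicability domain when its leverage does
not exceed a threshold h* set at the 95th percentile of the leverage
distribution obtained by a leave-one-out pass over the training rows
(each row scored against the design with that row removed).

Only the features the final predictive model actually uses enter the
design: the refit feature subset for a descriptor model, the
nonzero-importance bins for a CNL model. The Gram matrix is inverted
with the Moore-Penrose pseudo-inverse so rank-deficient designs (common
for near-binary loss features) are handled; an optional small ridge is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ADModel", "fit_ad", "leverage", "loo_threshold", "in_domain"]


@dataclass
class ADModel:
    X: np.ndarray
    gram_inverse: np.ndarray
    h_star: float
    loo_leverages: np.ndarray
    feature_names: list[str] | None = None
    percentile: float = 95.0

    @property
    def training_leverages(self) -> np.ndarray:
        """Leverage of each training row against the full design."""
        return np.einsum("ij,jk,ik->i", self.X, self.gram_inverse, self.X)


def _gram_inverse(X: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    G = X.T @ X
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    return np.linalg.pinv(G, hermitian=True)


def leverage(x: np.ndarray, ad: ADModel) -> float | np.ndarray:
    """h(x) = x^T (X^T X)^{-1} x for one vector or a stack of rows."""
    x = np.asarray(x, dtype=float)
    p = ad.gram_inverse.shape[0]
    if x.shape[-1] != p:
        raise ValueError(f"feature dimension mismatch: got {x.shape[-1]}, expected {p}")
    if x.ndim == 1:
        return float(x @ ad.gram_inverse @ x)
    return np.einsum("ij,jk,ik->i", x, ad.gram_inverse, x)


def loo_threshold(
    X: np.ndarray, percentile: float = 95.0, ridge: float = 0.0
) -> tuple[float, np.ndarray]:
    """Leave-one-out leverage distribution and its percentile threshold.

    Row i is scored against X with row i removed. When the (possibly
    ridged) Gram matrix is invertible this equals the Sherman-Morrison
    downdate h_ii / (1 - h_ii) of the full-design leverage h_ii;
    rank-deficient designs (or rows with h_ii ~ 1) fall back to explicit
    per-row pseudo-inverses, with a logged rank warning. The threshold
    is the requested percentile under the linear-interpolation
    definition.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 training rows for a leave-one-out pass")
    G_inv = _gram_inverse(X, ridge)
    full_rank = ridge > 0 or np.linalg.matrix_rank(X.T @ X) == p
    h_full = np.einsum("ij,jk,ik->i", X, G_inv, X)
    if full_rank and np.all(h_full < 1 - 1e-10):
        loo = h_full / (1.0 - h_full)
    else:
        if not full_rank:
            logger.warning(
                "rank-deficient Gram matrix (rank < %d); using per-row pseudo-inverses", p
            )
        loo = np.empty(n)
        for i in range(n):
            Xi = np.delete(X, i, axis=0)
            loo[i] = X[i] @ _gram_inverse(Xi, ridge) @ X[i]
    h_star = float(np.percentile(loo, percentile))
    return h_star, loo


def fit_ad(
    X: np.ndarray,
    feature_names: list[str] | None = None,
    percentile: float = 95.0,
    ridge: float = 0.0,
) -> ADModel:
    """Fit the applicability domain of a training design."""
    X = np.asarray(X, dtype=float)
    h_star, loo = loo_threshold(X, percentile=percentile, ridge=ridge)
    return ADModel(
        X=X,
        gram_inverse=_gram_inverse(X, ridge),
        h_star=h_star,
        loo_leverages=loo,
        feature_names=list(feature_names) if feature_names is not None else None,
        percentile=percentile,
    )


def in_domain(x: np.ndarray, ad: ADModel) -> tuple[bool | np.ndarray, float | np.ndarray]:
    """Whether x is covered by the training set, plus its leverage.

    Inclusive at the boundary: leverage exactly equal to h* is inside.
    """
    h = leverage(x, ad)
    if np.ndim(h) == 0:
        return bool(h <= ad.h_star), h
    return h <= ad.h_star, h
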