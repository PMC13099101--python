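"""Exact Shapley attribution for the boosted-tree classifier.

The Shapley value of feature i for an explained row x is

    Phi_i = sum over subsets S of the other features of
            |S|! (M - |S| - 1)! / M!  *  [v(S + {i}) - v(S)]

with the coalition value ``v(S)`` taken as the interventional (marginal)
expectation of the model margin over a background sample: features inside
S keep x's values, features outside S are replaced by each background
row's values, and the margins are averaged.  Attributions are therefore in
log-odds space and satisfy efficiency exactly:
``sum_i Phi_i = f(x) - mean_bg f``.

Subset enumeration is exponential in the feature count M and is refused
above M = 12 (use :func:`sampling_shap` there); at the 8-factor scale of
this package's analyses exact enumeration is fast.
"""

from __future__ import annotations

import math

import numpy as np

from .gbdt import GBDTModel, predict_margin

__all__ = ["exact_shap", "coalition_values", "sampling_shap"]

MAX_EXACT_FEATURES = 12


def coalition_values(
    model: GBDTModel,
    X: np.ndarray,
    background: np.ndarray,
) -> dict[int, np.ndarray]:
    """Value v(S) for every feature coalition S (bitmask -> (n_x,) array)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ValueError("background sample must be non-empty")
    m = model.n_features
    if X.shape[1] != m or bg.shape[1] != m:
        raise ValueError("feature-count mismatch with model")
    n_x, n_bg = len(X), len(bg)
    values: dict[int, np.ndarray] = {}
    for mask in range(1 << m):
        hybrid = np.broadcast_to(bg[None, :, :], (n_x, n_bg, m)).copy()
        for j in range(m):
            if mask >> j & 1:
                hybrid[:, :, j] = X[:, j][:, None]
        margins = predict_margin(model, hybrid.reshape(-1, m)).reshape(n_x, n_bg)
        values[mask] = margins.mean(axis=1)
    return values


def exact_shap(
    model: GBDTModel,
    X: np.ndarray,
    background: np.ndarray,
    features=None,
) -> np.ndarray:
    """Exact Shapley values (n_rows, n_features) in margin (log-odds) space.

    ``features`` restricts which columns of the result are computed (the
    full coalition lattice is evaluated regardless, so restricting saves
    only the pairing loop)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = model.n_features
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration refused for M={m} > {MAX_EXACT_FEATURES}; "
            "use sampling_shap"
        )
    feats = range(m) if features is None else list(features)
    v = coalition_values(model, X, background)
    # Shapley kernel weights by coalition size
    fact = [math.factorial(k) for k in range(m + 1)]
    w = [fact[s] * fact[m - s - 1] / fact[m] for s in range(m)]
    phi = np.zeros((len(X), m))
    sizes = {mask: bin(mask).count("1") for mask in range(1 << m)}
    for i in feats:
        bit = 1 << i
        acc = np.zeros(len(X))
        for mask in range(1 << m):
            if mask & bit:
                continue
            acc += w[sizes[mask]] * (v[mask | bit] - v[mask])
        phi[:, i] = acc
    return phi


def sampling_shap(
    model: GBDTModel,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo permutation estimate of the Shapley values (for M > 12).

    Averages marginal contributions over random feature orderings; the
    estimator is unbiased for the exact values."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    m = model.n_features
    rng = np.random.default_rng(seed)
    n_x, n_bg = len(X), len(bg)
    phi = np.zeros((n_x, m))
    for _ in range(n_permutations):
        order = rng.permutation(m)
        hybrid = np.broadcast_to(bg[None, :, :], (n_x, n_bg, m)).copy()
        prev = predict_margin(model, hybrid.reshape(-1, m)).reshape(n_x, n_bg).mean(axis=1)
        for j in order:
            hybrid[:, :, j] = X[:, j][:, None]
            cur = predict_margin(model, hybrid.reshape(-1, m)).reshape(n_x, n_bg).mean(axis=1)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_permutations
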