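"""Trade-off / synergy classification of ecosystem-service pairs.

A pair of ES layers is classified by the Spearman rank correlation of their
cell values: a significantly positive coefficient is a synergy (the two
services rise and fall together), a significantly negative one a trade-off.
Because all C(k,2) pairs are tested jointly, raw p-values are adjusted with
the Benjamini-Hochberg step-up procedure to control the false discovery
rate, and significance is judged on the adjusted values.

Correlation strength is binned as weak (|r| < 0.3), moderate (0.3-0.6) and
strong (> 0.6); the cutoffs are configurable.  A 95% confidence interval
for r is obtained through the Fisher z-transform.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairResult",
    "rank_with_ties",
    "spearman_r",
    "bh_fdr",
    "pairwise_relationship_matrix",
]

STRENGTH_BINS = (0.3, 0.6)  # weak < 0.3 <= moderate <= 0.6 < strong


@dataclass
class PairResult:
    pair: tuple[str, str]
    r: float
    n: int
    p_raw: float
    p_fdr: float
    ci95: tuple[float, float]
    relation: str  # synergy | trade-off | non-significant
    strength: str  # weak | moderate | strong


def rank_with_ties(values: np.ndarray) -> np.ndarray:
    """Average ranks (ties share the mean of their rank positions)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValueError("need >= 2 finite values")
    return sps.rankdata(v, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return math.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def spearman_r(
    x: np.ndarray,
    y: np.ndarray,
    n_mc: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman coefficient and two-sided p-value.

    r is the Pearson correlation of tie-averaged ranks.  The p-value is by
    exact permutation enumeration for n <= 8, seeded Monte-Carlo permutation
    for n in {9, 10}, and the t approximation above that.  Constant input
    yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx, ry = rank_with_ties(x), rank_with_ties(y)
    r = _pearson(rx, ry)
    if n <= 8:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            rp = _pearson(rx[list(perm)], ry)
            total += 1
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        return r, hits / total
    if n <= 10:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            rp = _pearson(rx[rng.permutation(n)], ry)
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        return r, (hits + 1) / (n_mc + 1)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z-transform."""
    if not np.isfinite(r) or n <= 3 or abs(r) >= 1.0:
        return (math.nan, math.nan)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    q = sps.norm.ppf(0.5 + level / 2.0)
    return (math.tanh(z - q * se), math.tanh(z + q * se))


def strength_label(r: float, bins=STRENGTH_BINS) -> str:
    a = abs(r)
    if a < bins[0]:
        return "weak"
    if a <= bins[1]:
        return "moderate"
    return "strong"


def pairwise_relationship_matrix(
    layers: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    alpha: float = 0.05,
    strength_bins=STRENGTH_BINS,
) -> list[PairResult]:
    """Classify every unordered pair of layers; FDR applied across all pairs.

    ``layers`` maps ES name to raster (or flat vector); cells outside the
    mask or non-finite in either layer of a pair are dropped pairwise.
    """
    names = list(layers)
    if len(names) < 2:
        raise ValueError("need at least two layers")
    flat = {}
    for name in names:
        v = np.asarray(layers[name], dtype=float)
        flat[name] = v[mask] if mask is not None else v.ravel()
    results, raw_p = [], []
    for a, b in itertools.combinations(names, 2):
        va, vb = flat[a], flat[b]
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 common valid cells")
        r, p = spearman_r(va[ok], vb[ok])
        results.append((a, b, r, p, int(ok.sum())))
        raw_p.append(1.0 if math.isnan(p) else p)
    p_adj = bh_fdr(raw_p)
    out = []
    for (a, b, r, p, n), q in zip(results, p_adj):
        if math.isnan(r) or q >= alpha:
            relation = "non-significant"
        elif r > 0:
            relation = "synergy"
        else:
            relation = "trade-off"
        out.append(
            PairResult(
                pair=(a, b),
                r=r,
                n=n,
                p_raw=p,
                p_fdr=float(q),
                ci95=fisher_ci(r, n),
                relation=relation,
                strength=strength_label(r, strength_bins) if not math.isnan(r) else "weak",
            )
        )
    return out
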