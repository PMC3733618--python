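"""Circular statistics for propagation directions.

Rose histograms (max-normalized, as in the state-wise direction plots), a
two-sample Kuiper test (the rotation-invariant circular analog of the
two-sample Kolmogorov-Smirnov test) with an asymptotic p-value using
Stephens' effective-sample-size correction and an optional permutation
p-value, and the matched-pairs Wilcoxon signed-rank comparison used for
per-recording median speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = ["RoseHistogram", "KuiperResult", "rose_histogram",
           "kuiper_two_sample", "wilcoxon_matched_pairs"]

TWO_PI = 2.0 * np.pi


@dataclass
class RoseHistogram:
    bin_edges: np.ndarray        # radians, covering [0, 2*pi)
    counts: np.ndarray
    normalized: np.ndarray       # counts / max(counts)


@dataclass
class KuiperResult:
    statistic: float             # V
    p_value: float
    n1: int
    n2: int
    method: str = "asymptotic"


def rose_histogram(angles, n_bins: int = 18) -> RoseHistogram:
    """Histogram of angles wrapped to [0, 2*pi), normalized to the
    maximum bin count."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    a = a % TWO_PI
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    cmax = counts.max()
    normalized = counts / cmax if cmax > 0 else counts.astype(float)
    return RoseHistogram(bin_edges=edges, counts=counts, normalized=normalized)


def _kuiper_V(a: np.ndarray, b: np.ndarray) -> float:
    """V = sup(F_a - F_b) + sup(F_b - F_a) over the pooled sample points.

    Evaluated after grouping tied values, so identical samples give V = 0.
    The statistic is invariant under a common rotation of both samples.
    """
    n1, n2 = a.size, b.size
    vals = np.concatenate([a, b])
    w = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    d = np.cumsum(w[order])
    # evaluate the ECDF difference only after each distinct value
    last = np.r_[sv[1:] != sv[:-1], True]
    dd = d[last]
    return float(max(dd.max(), 0.0) - min(dd.min(), 0.0))


def _kuiper_p_asymptotic(V: float, ne: float) -> float:
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * V
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101)
    terms = (4.0 * j ** 2 * lam ** 2 - 1.0) * np.exp(-2.0 * j ** 2 * lam ** 2)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))


def kuiper_two_sample(a, b, method: str = "asymptotic",
                      n_permutations: int = 9999,
                      seed: int | None = None) -> KuiperResult:
    """Two-sample Kuiper test on circular data (radians).

    ``method="asymptotic"`` uses the Kuiper tail series with effective
    sample size n1*n2/(n1+n2); ``method="permutation"`` pools the samples
    and re-labels them `n_permutations` times (add-one estimator).
    """
    a = np.asarray(a, dtype=float) % TWO_PI
    b = np.asarray(b, dtype=float) % TWO_PI
    n1, n2 = a.size, b.size
    if n1 < 8 or n2 < 8:
        raise ValueError("both samples must have at least 8 angles")
    V = _kuiper_V(a, b)
    ne = n1 * n2 / (n1 + n2)
    if method == "asymptotic":
        p = _kuiper_p_asymptotic(V, ne)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        vals = np.concatenate([a, b])
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        last = np.r_[sv[1:] != sv[:-1], True]
        base = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
        perms = rng.permuted(
            np.broadcast_to(base, (n_permutations, n1 + n2)).copy(), axis=1)
        d = np.cumsum(perms, axis=1)[:, last]
        v_perm = (np.maximum(d.max(axis=1), 0.0)
                  - np.minimum(d.min(axis=1), 0.0))
        p = (1.0 + np.count_nonzero(v_perm >= V - 1e-12)) / (n_permutations + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KuiperResult(statistic=V, p_value=float(p), n1=n1, n2=n2,
                        method=method)


def wilcoxon_matched_pairs(x, y):
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Pairs with zero difference are dropped; the p-value is exact for
    n <= 25 remaining pairs (normal approximation beyond).  Returns
    ``(statistic, p_value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired (equal length)")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = spstats.wilcoxon(d, alternative="two-sided", method=method)
    except ValueError:
        res = spstats.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)
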