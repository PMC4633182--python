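"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most transparent method
available (O(n³) loops, closed forms) and stay independent of the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def upgma_cophenetic(D: np.ndarray) -> np.ndarray:
    """Average-linkage cophenetic matrix by direct O(n³) agglomeration.

    Cluster distance is the arithmetic mean of all original pairwise
    leaf distances; ties are broken by the smallest (row, column) pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def cluster_dist(a: list[int], b: list[int]) -> float:
        return float(np.mean([D[i, j] for i in a for j in b]))

    while len(clusters) > 1:
        best = None
        for p in range(len(clusters)):
            for q in range(p + 1, len(clusters)):
                d = cluster_dist(clusters[p], clusters[q])
                if best is None or d < best[0]:
                    best = (d, p, q)
        d, p, q = best
        for i in clusters[p]:
            for j in clusters[q]:
                coph[i, j] = coph[j, i] = d
        clusters[p] = clusters[p] + clusters[q]
        del clusters[q]
    return coph


def is_ultrametric(coph: np.ndarray, rtol: float = 1e-9) -> bool:
    """Every triple satisfies d(i,k) <= max(d(i,j), d(j,k))."""
    n = coph.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if coph[i, k] > max(coph[i, j], coph[j, k]) * (1 + rtol) + 1e-12:
                    return False
    return True


def fisher_direction(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Two-class Fisher discriminant direction w ∝ S_w⁻¹ (μ₁ − μ₂)."""
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    S = (
        (X1 - mu1).T @ (X1 - mu1) + (X2 - mu2).T @ (X2 - mu2)
    ) / (len(X1) + len(X2) - 2)
    return np.linalg.solve(S, mu1 - mu2)


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form Welch t-test p-value from the t distribution."""
    from scipy.stats import t as tdist

    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(2 * tdist.sf(abs(t), df))
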