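"""Independent reference implementations used as test oracles.

These deliberately share no code with the package's vectorized paths:
the SPER oracle is a plain triple loop over (type, spot, neighbor), the
weight oracle evaluates the Poisson pmf from its factorial definition, and
the AUROC oracle is the Mann-Whitney U identity on midranks.
"""

from __future__ import annotations

import math

import numpy as np


def shell_of(d: float, bin_width: float, n_rings: int, same_spot: bool) -> int:
    """Shell index of one pair: 0 = same spot, ring i covers (d_{i-1}, d_i],
    distances beyond the cap fall into ring ``n_rings``."""
    if same_spot:
        return 0
    s = math.ceil(d / bin_width * (1.0 - 1e-12))
    return min(max(s, 1), n_rings)


def sper_oracle(E_norm, C_raw, coords, bin_width, max_distance, lam):
    """Triple-loop paired expression ratios, weights and score.

    Returns ``(R, phi, S)`` with ``R`` of shape (n_shells, k, m). Expression
    must already be normalized; ``C_raw`` rows are normalized over spots here.
    """
    E = np.asarray(E_norm, dtype=float)
    C = np.asarray(C_raw, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, m = E.shape
    k = C.shape[0]
    n_rings = math.ceil(max_distance / bin_width - 1e-9)
    n_shells = n_rings + 1
    Ct = np.empty_like(C)
    for t in range(k):
        s = C[t].sum()
        Ct[t] = C[t] / s if s > 0 else 0.0
    shell_idx = np.empty((n, n), dtype=int)
    for j in range(n):
        for jp in range(n):
            d = math.dist(coords[j], coords[jp])
            shell_idx[j, jp] = shell_of(d, bin_width, n_rings, j == jp)
    R = np.zeros((n_shells, k, m))
    for i in range(n_shells):
        for t in range(k):
            for j in range(n):
                nbrs = [jp for jp in range(n) if shell_idx[j, jp] == i]
                if not nbrs:
                    continue  # zero-neighbor shells contribute nothing
                avg = E[nbrs].mean(axis=0)
                R[i, t] += Ct[t, j] * avg
    phi = np.array([math.exp(-lam) * lam**i / math.factorial(i) for i in range(n_shells)])
    phi = phi / phi.sum()
    S = np.zeros((k, m))
    for i in range(n_shells):
        S += phi[i] * R[i]
    return R, phi, S


def auroc_mann_whitney(y, scores) -> float:
    """AUROC via the Mann-Whitney U identity with midranks."""
    y = np.asarray(y).astype(int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def bh_adjust(p):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * n / rank)
        adj[idx] = val
        prev = val
    return adj
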