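"""Independent, deliberately naive reference implementations used as oracles.

Everything here is written with explicit loops and textbook formulas, kept
free of the package's vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def ref_pearson(x, y) -> float:
    """Two-pass Pearson correlation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def ref_window_fc(block: np.ndarray) -> np.ndarray:
    """Naive M x M correlation matrix of an (l, M) block."""
    M = block.shape[1]
    C = np.eye(M)
    for i in range(M):
        for j in range(i + 1, M):
            C[i, j] = C[j, i] = ref_pearson(block[:, i], block[:, j])
    return C


def _one_minus_mean_pair_corr(vectors: list[np.ndarray]) -> float:
    N = len(vectors)
    total = 0.0
    for i, j in combinations(range(N), 2):
        total += ref_pearson(vectors[i], vectors[j])
    return 1.0 - total / (N * (N - 1) / 2)


def ref_nodal_variability(windows: np.ndarray, k: int) -> float:
    """Loop-based V_k: profiles are FC rows with the self-entry removed."""
    N, M, _ = windows.shape
    profiles = [np.delete(windows[i, k, :], k) for i in range(N)]
    return _one_minus_mean_pair_corr(profiles)


def ref_intra_variability(windows: np.ndarray, nodes: list[int]) -> float:
    """Loop-based intra-network variability over a module's upper triangle."""
    vectors = []
    for w in windows:
        vec = [w[a, b] for a, b in combinations(sorted(nodes), 2)]
        vectors.append(np.array(vec))
    return _one_minus_mean_pair_corr(vectors)


def ref_inter_variability(windows: np.ndarray, nodes_a: list[int], nodes_b: list[int]) -> float:
    """Loop-based inter-network variability over the full cross block."""
    vectors = []
    for w in windows:
        vec = [w[a, b] for a in sorted(nodes_a) for b in sorted(nodes_b)]
        vectors.append(np.array(vec))
    return _one_minus_mean_pair_corr(vectors)


def ref_exhaustive_perm_p(ctrl: np.ndarray, pat: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive label-permutation p-values over all C(n, n_pat) relabelings.

    Returns (observed_diff, p_greater, p_smaller) with tail proportions over
    the complete permutation distribution (including the identity).
    """
    pooled = np.concatenate([pat, ctrl])
    n = pooled.size
    n_pat = pat.size
    observed = pat.mean() - ctrl.mean()
    diffs = []
    for idx in combinations(range(n), n_pat):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        diffs.append(pooled[sel].mean() - pooled[~sel].mean())
    diffs = np.array(diffs)
    p_greater = np.mean(diffs >= observed - 1e-12)
    p_smaller = np.mean(diffs <= observed + 1e-12)
    return observed, float(p_greater), float(p_smaller)


def ref_exhaustive_signflip_p(diffs: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive sign-flip p over all 2^n flips of paired differences."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    observed = d.mean()
    means = []
    for mask in range(2**n):
        signs = np.array([1.0 if (mask >> i) & 1 else -1.0 for i in range(n)])
        means.append((signs * d).mean())
    means = np.array(means)
    p_greater = np.mean(means >= observed - 1e-12)
    p_smaller = np.mean(means <= observed + 1e-12)
    return float(observed), float(p_greater), float(p_smaller)
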