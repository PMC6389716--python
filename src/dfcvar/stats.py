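"""Group inference and clinical correlation.

Group differences in variability are tested non-parametrically: group
labels are permuted (preserving group sizes), the difference of group means
is recomputed for each permutation, and the tail proportion gives the
p-value.  The add-one estimator (k + 1) / (n_perm + 1) is used so a Monte
Carlo p is never exactly zero.  Within-group intra-vs-inter comparisons use
a paired sign-flip permutation.  Clinical association is Spearman rank
correlation after removing values more than 3 SD from the group mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _perms
from math import factorial

import numpy as np
from scipy import stats as sps

DEFAULT_N_PERM = 10_000
DEFAULT_OUTLIER_SD = 3.0


@dataclass(frozen=True)
class PermutationResult:
    unit: str
    observed_diff: float
    n_perm: int
    p_greater: float
    p_smaller: float
    seed: int
    n_control: int = 0
    n_patient: int = 0
    degenerate: bool = False
    n_dropped: int = 0

    @property
    def p_two_sided(self) -> float:
        return min(1.0, 2.0 * min(self.p_greater, self.p_smaller))


@dataclass(frozen=True)
class ClinicalCorrelation:
    unit: str
    rho: float
    p: float
    n_used: int
    n_outliers: int
    rho_with_outliers: float
    p_with_outliers: float


def _drop_missing(x: np.ndarray) -> tuple[np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    return x[ok], int((~ok).sum())


def permutation_membership(
    n_total: int, n_patient: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_perm, n_total) patient-membership matrix, sizes preserved."""
    u = rng.random((n_perm, n_total))
    order = np.argsort(u, axis=1)
    member = np.zeros((n_perm, n_total), dtype=bool)
    np.put_along_axis(member, order[:, :n_patient], True, axis=1)
    return member


def group_diffs_under_permutation(
    values: np.ndarray, member: np.ndarray
) -> np.ndarray:
    """Permuted mean(patient) - mean(control) for a values matrix.

    ``values`` is (n_subjects,) or (n_subjects, n_units); ``member`` is the
    membership matrix from :func:`permutation_membership`.  Returns
    (n_perm,) or (n_perm, n_units).
    """
    values = np.asarray(values, dtype=float)
    n_pat = int(member[0].sum())
    n_ctrl = member.shape[1] - n_pat
    m = member.astype(float)
    return (m @ values) / n_pat - ((1.0 - m) @ values) / n_ctrl


def permutation_group_test(
    values_control: np.ndarray,
    values_patient: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    unit: str = "",
) -> PermutationResult:
    """Two-group permutation test on the difference of means."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ctrl, d1 = _drop_missing(values_control)
    pat, d2 = _drop_missing(values_patient)
    if ctrl.size < 2 or pat.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    observed = float(pat.mean() - ctrl.mean())
    pooled = np.concatenate([ctrl, pat])
    if np.ptp(pooled) == 0:
        return PermutationResult(
            unit=unit, observed_diff=0.0, n_perm=n_perm, p_greater=1.0, p_smaller=1.0,
            seed=seed, n_control=ctrl.size, n_patient=pat.size, degenerate=True,
            n_dropped=d1 + d2,
        )
    rng = np.random.default_rng(seed)
    member = permutation_membership(pooled.size, pat.size, n_perm, rng)
    diffs = group_diffs_under_permutation(pooled, member)
    # tie tolerance: identity relabelings must count as >= the observed diff
    eps = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    p_greater = (np.count_nonzero(diffs >= observed - eps) + 1) / (n_perm + 1)
    p_smaller = (np.count_nonzero(diffs <= observed + eps) + 1) / (n_perm + 1)
    return PermutationResult(
        unit=unit, observed_diff=observed, n_perm=n_perm, p_greater=float(p_greater),
        p_smaller=float(p_smaller), seed=seed, n_control=ctrl.size, n_patient=pat.size,
        n_dropped=d1 + d2,
    )


def paired_signflip_test(
    intra_values: np.ndarray,
    inter_values: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    unit: str = "",
) -> PermutationResult:
    """Paired sign-flip test on within-subject intra - inter differences.

    ``p_smaller`` is the one-sided p for intra < inter (negative mean
    difference), the direction reported for a stable within-module
    architecture.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    intra = np.asarray(intra_values, dtype=float)
    inter = np.asarray(inter_values, dtype=float)
    if intra.shape != inter.shape:
        raise ValueError("paired vectors must have equal length")
    d = intra - inter
    d, dropped = _drop_missing(d)
    if d.size < 3:
        raise ValueError("need >= 3 complete pairs")
    observed = float(d.mean())
    if np.all(d == 0):
        return PermutationResult(
            unit=unit, observed_diff=0.0, n_perm=n_perm, p_greater=1.0, p_smaller=1.0,
            seed=seed, degenerate=True, n_dropped=dropped,
        )
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    eps = 1e-12 * max(1.0, float(np.abs(d).max()))
    p_greater = (np.count_nonzero(null >= observed - eps) + 1) / (n_perm + 1)
    p_smaller = (np.count_nonzero(null <= observed + eps) + 1) / (n_perm + 1)
    return PermutationResult(
        unit=unit, observed_diff=observed, n_perm=n_perm, p_greater=float(p_greater),
        p_smaller=float(p_smaller), seed=seed, n_dropped=dropped,
    )


def remove_outliers(values: np.ndarray, n_sd: float = DEFAULT_OUTLIER_SD) -> np.ndarray:
    """Boolean keep-mask: single pass, drop |x - mean| > n_sd * SD (SD with n-1).

    A zero SD keeps everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier screening needs >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= n_sd * sd


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; exact permutation p for n <= 9."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        perm = np.array(list(_perms(range(n))))
        ry_perm = ry[perm]
        zx = (rx - rx.mean()) / rx.std()
        zy = (ry_perm - ry_perm.mean(axis=1, keepdims=True)) / ry_perm.std(axis=1, keepdims=True)
        rhos = zy @ zx / n
        p = float(np.count_nonzero(np.abs(rhos) >= np.abs(rho) - 1e-12) / factorial(n))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def spearman_with_outlier_removal(
    variability: np.ndarray,
    scores: np.ndarray,
    n_sd: float = DEFAULT_OUTLIER_SD,
    screen_scores: bool = False,
    unit: str = "",
) -> ClinicalCorrelation:
    """Spearman correlation between variability and clinical score.

    Pairs with a missing value are dropped; outlier screening (beyond
    ``n_sd`` SD from the mean) is applied to the variability values and,
    optionally, to the scores.  Results with and without screening are both
    retained.
    """
    v = np.asarray(variability, dtype=float)
    s = np.asarray(scores, dtype=float)
    if v.shape != s.shape:
        raise ValueError("variability and scores must have equal length")
    ok = np.isfinite(v) & np.isfinite(s)
    v, s = v[ok], s[ok]
    if v.size < 5:
        raise ValueError("need >= 5 complete pairs")
    rho_all, p_all = _spearman(v, s)
    keep = remove_outliers(v, n_sd)
    if screen_scores:
        keep &= remove_outliers(s, n_sd)
    if keep.sum() < 5:
        keep = np.ones(v.size, dtype=bool)
    rho, p = _spearman(v[keep], s[keep])
    return ClinicalCorrelation(
        unit=unit, rho=rho, p=p, n_used=int(keep.sum()),
        n_outliers=int((~keep).sum()), rho_with_outliers=rho_all, p_with_outliers=p_all,
    )


def sex_ratio_test(counts: np.ndarray) -> float:
    """Two-sided chi-square p (no continuity correction) for a 2x2 sex table."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    return float(sps.chi2_contingency(counts, correction=False).pvalue)


def two_sample_t(
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    *,
    summary: tuple[float, float, int, float, float, int] | None = None,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t test (Welch by default) from raw vectors or summaries.

    ``summary`` is (mean1, sd1, n1, mean2, sd2, n2), the form in which
    demographic tables print group statistics.
    """
    if summary is not None:
        m1, s1, n1, m2, s2, n2 = summary
        if min(n1, n2) < 2 or min(s1, s2) <= 0:
            raise ValueError("need n >= 2 and SD > 0 per group")
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    elif x is None or y is None:
        raise ValueError("provide raw vectors x and y, or summary statistics")
    else:
        x, _ = _drop_missing(x)
        y, _ = _drop_missing(y)
        if min(x.size, y.size) < 2:
            raise ValueError("need n >= 2 per group")
        res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
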