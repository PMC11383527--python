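"""Group statistics: Mann-Whitney, chi-square, significance labels.

The diffusion coefficient D1-4 is compared between conditions with a
two-tailed Mann-Whitney test (exact permutation enumeration for combined
n ≤ 12, with midranks for ties; normal approximation with tie and
continuity correction otherwise).  Categorical fractions (mobile/immobile,
aggregation classes) are compared with a Pearson chi-square test on the
contingency table, no continuity correction.  p-value labels follow the
convention n.s. (p > 0.05), * (≤ 0.05), ** (≤ 0.01), *** (≤ 0.001),
**** (≤ 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 12


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    label: str


def significance_label(p: float) -> str:
    """Most extreme applicable significance label for a p-value."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "n.s."


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney via full enumeration (midranks for ties).

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled midranks to
    group a; two-tailed p is 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.
    """
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = float(ranks[:na].sum()) - na * (na + 1) / 2.0
    total = comb(na + nb, na)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(na + nb), na):
        u = float(ranks[list(idx)].sum()) - na * (na + 1) / 2.0
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def mann_whitney_two_tailed(sample_a, sample_b) -> StatResult:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration for combined n ≤ 12, normal approximation with tie
    and continuity correction otherwise.  The statistic is U of sample a.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(a) + len(b) <= EXACT_MAX_N:
        u, p = _exact_mann_whitney(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        u, p = float(res.statistic), float(res.pvalue)
    return StatResult(test="mann_whitney_two_tailed", statistic=u,
                      p_value=p, label=significance_label(p))


def chi_square_contingency(table) -> StatResult:
    """Pearson chi-square on an r×k contingency table (no continuity corr.)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2×2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if np.any(expected <= 0):
        raise ValueError("zero expected count in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return StatResult(test="chi_square", statistic=float(chi2),
                      p_value=float(p), label=significance_label(float(p)))


def anova_tukey(*groups) -> dict:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Convenience wrapper (used for migration-assay style comparisons of
    several conditions); not part of the SPT quantification surface.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    pairs = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pp = float(tukey.pvalue[i, j])
            pairs[f"{i}v{j}"] = {"p_value": pp, "label": significance_label(pp)}
    return {"anova_F": float(f), "anova_p": float(p),
            "anova_label": significance_label(float(p)), "tukey": pairs}
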