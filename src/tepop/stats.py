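"""Nonparametric and GLM comparisons used on the summary tables.

Thin, contract-checked wrappers: Kruskal-Wallis (tie-corrected H, chi-squared
p), Wilcoxon signed rank (V = sum of positive-difference ranks, R's
convention, tie-corrected normal approximation with continuity correction),
Mann-Whitney rank sum (U = number of (a, b) pairs with a > b, halves for
ties), and a Poisson log-link GLM on a categorical predictor with Wald z per
group against the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    df: int | None
    p_value: float
    degenerate: bool = False
    note: str = ""
    extra: dict = field(default_factory=dict)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across ≥ 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    values = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(values == values[0]):
        return TestResult("H", 0.0, len(groups) - 1, 1.0, degenerate=True,
                          note="all observations identical")
    h, p = sps.kruskal(*groups)
    return TestResult("H", float(h), len(groups) - 1, float(p))


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float], continuity: bool = True
) -> TestResult:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped before ranking; V is the sum of the ranks of
    the positive differences. The p-value uses the tie-corrected normal
    approximation, with a 0.5 continuity correction when requested.
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("V", 0.0, None, 1.0, degenerate=True,
                          note="all differences zero")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    if sigma2 <= 0:
        return TestResult("V", v, None, 1.0, degenerate=True, note="zero variance")
    z_num = v - mu
    if continuity:
        z_num -= 0.5 * np.sign(z_num)
    z = z_num / math.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return TestResult("V", v, None, float(min(p, 1.0)), extra={"z": float(z), "n": n})


def rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Mann-Whitney rank-sum test; U counts (a, b) pairs with a > b (+½ ties)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult("U", len(a) * len(b) / 2, None, 1.0, degenerate=True,
                          note="all observations identical")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                            use_continuity=True)
    return TestResult("U", float(u), None, float(p),
                      note="U = #{(a,b): a > b} + ties/2")


def poisson_glm_counts(
    counts: Sequence[int], group_labels: Sequence[str]
) -> list[TestResult]:
    """Poisson log-link regression of counts on a categorical predictor.

    Returns one result per non-baseline group (baseline = first label in
    sorted order): coefficient log(mean_g / mean_baseline) at the MLE with
    Wald z and p. A group with all-zero counts yields a flagged -inf
    coefficient instead of a fit.
    """
    y = np.asarray(counts, float)
    labels = np.asarray(group_labels)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    baseline = groups[0]
    means = {g: y[labels == g].mean() for g in groups}

    if any(means[g] == 0 for g in groups):
        results = []
        for g in groups[1:]:
            if means[g] == 0 or means[baseline] == 0:
                coef = -math.inf if means[g] == 0 else math.inf
                results.append(TestResult(
                    "z", float("nan"), None, float("nan"), degenerate=True,
                    note=f"group {g!r} vs {baseline!r}: zero group mean",
                    extra={"coef": coef, "group": g, "baseline": baseline},
                ))
            else:
                results.append(_poisson_wald(y, labels, g, baseline, means))
        return results

    import statsmodels.api as sm

    design = np.column_stack(
        [np.ones(len(y))] + [(labels == g).astype(float) for g in groups[1:]]
    )
    fit = sm.GLM(y, design, family=sm.families.Poisson()).fit()
    results = []
    for i, g in enumerate(groups[1:], start=1):
        results.append(TestResult(
            "z", float(fit.tvalues[i]), None, float(fit.pvalues[i]),
            extra={"coef": float(fit.params[i]), "group": g, "baseline": baseline,
                   "mean_group": means[g], "mean_baseline": means[baseline]},
        ))
    return results


def _poisson_wald(y, labels, g, baseline, means) -> TestResult:
    # closed-form Wald fallback for the two-group contrast
    n_g = (labels == g).sum()
    n_0 = (labels == baseline).sum()
    coef = math.log(means[g] / means[baseline])
    se = math.sqrt(1 / (means[g] * n_g) + 1 / (means[baseline] * n_0))
    z = coef / se
    return TestResult("z", z, None, float(2 * sps.norm.sf(abs(z))),
                      extra={"coef": coef, "group": g, "baseline": baseline})
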