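"""Group-comparison machinery for repeated hemodynamic measurements.

The design is repeated measures: every animal (block) is observed at every
dose or condition (treatment).  Normal-theory comparisons use repeated-
measures one-way ANOVA with Scheffé's F-test for all pairwise contrasts;
rank-based comparisons use the Friedman test (tie-corrected, with an exact
permutation p-value when the enumeration is small), the Wilcoxon signed-rank
test for paired contrasts, and the Steel–Dwass all-pairs procedure, which
refers pairwise standardized rank-sum statistics to the studentized-range
distribution to control the familywise error across the k(k-1)/2 pairs.

No sphericity correction is applied to the repeated-measures ANOVA; its F
reference distribution assumes compound symmetry.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Cap on enumeration size for exact permutation p-values ((k!)^n assignments).
EXACT_ENUMERATION_LIMIT = 1_000_000


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str
    degenerate: bool = False
    exact_p_value: float | None = None
    n_zeros_dropped: int = 0


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def _as_blocked(data) -> np.ndarray:
    a = np.asarray(data, float)
    if a.ndim != 2:
        raise ValueError("blocked data must be 2-D (subjects x treatments)")
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 treatments")
    if not np.isfinite(a).all():
        raise ValueError("blocked data must be complete and finite")
    return a


def rm_anova_oneway(data) -> TestResult:
    """Repeated-measures one-way ANOVA (subjects x treatments).

    Two-way additive decomposition removing the subject effect:
    F = MS_treatment / MS_error on (k-1, (k-1)(n-1)) df.
    """
    a = _as_blocked(data)
    n, k = a.shape
    grand = a.mean()
    ss_treat = n * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((a.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((a - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_subj
    df_t = k - 1
    df_e = (k - 1) * (n - 1)
    ms_err = ss_err / df_e
    if ms_err <= 0:
        # zero residual variance: any treatment effect is infinitely significant
        degenerate = True
        if ss_treat > 0:
            return TestResult(float("inf"), (df_t, df_e), 0.0, "rm_anova", degenerate)
        return TestResult(0.0, (df_t, df_e), 1.0, "rm_anova", degenerate)
    f = (ss_treat / df_t) / ms_err
    return TestResult(float(f), (df_t, df_e), float(sps.f.sf(f, df_t, df_e)), "rm_anova")


def scheffe_posthoc(
    data, alpha: float = 0.05, labels: Sequence[str] | None = None
) -> list[PairwiseResult]:
    """Scheffé all-pairs contrasts on the repeated-measures ANOVA error term.

    For the pair (i, j) the contrast F is n (m_i - m_j)^2 / (2 MS_error); it is
    significant when it exceeds (k-1) F_{alpha; k-1, df_error}.  The reported
    p-value is the Scheffé bound P(F_{k-1, df_e} >= F_contrast / (k-1)),
    coherent with the omnibus test: no pair can be significant when the
    omnibus F is below its critical value.
    """
    a = _as_blocked(data)
    n, k = a.shape
    if labels is None:
        labels = [f"T{j}" for j in range(k)]
    grand = a.mean()
    ss_total = ((a - grand) ** 2).sum()
    ss_treat = n * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((a.mean(axis=1) - grand) ** 2).sum()
    df_e = (k - 1) * (n - 1)
    ms_err = (ss_total - ss_treat - ss_subj) / df_e
    means = a.mean(axis=0)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        if ms_err <= 0:
            diff = means[i] != means[j]
            out.append(
                PairwiseResult((labels[i], labels[j]), float("inf") if diff else 0.0,
                               0.0 if diff else 1.0, bool(diff), degenerate=True)
            )
            continue
        f_contrast = n * (means[i] - means[j]) ** 2 / (2.0 * ms_err)
        p = float(sps.f.sf(f_contrast / (k - 1), k - 1, df_e))
        out.append(
            PairwiseResult((labels[i], labels[j]), float(f_contrast), p, p < alpha)
        )
    return out


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-robust Friedman statistic from within-block mid-ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    den = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if den == 0:
        return 0.0
    return float(num / den)


def friedman_test(data, exact: bool | None = None) -> TestResult:
    """Friedman rank test over blocked data, tie-corrected.

    p-value from chi-square on k-1 df.  When ``exact`` is True — or None and
    the enumeration (k!)^n is small — an exact permutation p-value over all
    within-block orderings is also computed and reported alongside.
    """
    a = _as_blocked(data)
    n, k = a.shape
    ranks = np.apply_along_axis(rankdata, 1, a)
    stat = _friedman_statistic(ranks)
    p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    n_assign = math.factorial(k) ** n
    do_exact = exact if exact is not None else n_assign <= EXACT_ENUMERATION_LIMIT
    exact_p = None
    if do_exact:
        if n_assign > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact enumeration of {n_assign} assignments exceeds the "
                f"{EXACT_ENUMERATION_LIMIT} limit"
            )
        perms = list(itertools.permutations(range(k)))
        count = 0
        # one permuted rank matrix per assignment of an ordering to each block
        for assignment in itertools.product(range(len(perms)), repeat=n):
            permuted = np.empty_like(ranks)
            for b, pi in enumerate(assignment):
                permuted[b] = ranks[b, list(perms[pi])]
            if _friedman_statistic(permuted) >= stat - 1e-12:
                count += 1
        exact_p = count / n_assign
    return TestResult(stat, (k - 1,), p, "friedman", exact_p_value=exact_p)


def wilcoxon_signed_rank(differences, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (and logged).  ``mode`` is ``"exact"`` (sign
    enumeration via convolution over mid-ranks of |d|), ``"approx"`` (normal
    approximation with tie-corrected variance and continuity correction), or
    ``"auto"`` (exact for n <= 25 after zero removal).
    """
    d = np.asarray(differences, float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("differences must be a nonempty 1-D vector")
    nz = d[d != 0]
    n_zeros = len(d) - len(nz)
    if n_zeros:
        logger.info("wilcoxon_signed_rank: dropped %d zero difference(s)", n_zeros)
    if len(nz) == 0:
        return TestResult(0.0, (0,), 1.0, "wilcoxon_signed_rank",
                          degenerate=True, n_zeros_dropped=n_zeros)
    n = len(nz)
    ranks = rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= 25 else "approx"
    if mode == "exact":
        # distribution of W+ over the 2^n equiprobable sign assignments;
        # doubled ranks are integers even with mid-rank ties
        r2 = np.round(2 * ranks).astype(int)
        pmf = np.zeros(r2.sum() + 1)
        pmf[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: len(pmf) - r]
            pmf = 0.5 * (pmf + shifted)
        w2 = int(round(2 * w_plus))
        p_le = pmf[: w2 + 1].sum()
        p_ge = pmf[w2:].sum()
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
    elif mode == "approx":
        mean = ranks.sum() / 2.0
        var = (ranks**2).sum() / 4.0
        if var == 0:
            return TestResult(w_plus, (float(n),), 1.0, "wilcoxon_signed_rank",
                              degenerate=True, n_zeros_dropped=n_zeros)
        z = (w_plus - mean - math.copysign(0.5, w_plus - mean)) / math.sqrt(var)
        if abs(w_plus - mean) < 0.5:
            z = 0.0
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(w_plus, (float(n),), p, "wilcoxon_signed_rank",
                      n_zeros_dropped=n_zeros)


def _pairwise_ranksum_z(g1: np.ndarray, g2: np.ndarray) -> tuple[float, bool]:
    """Standardized Wilcoxon rank-sum z for one pair, tie-corrected variance."""
    n1, n2 = len(g1), len(g2)
    pooled = np.concatenate([g1, g2])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    e1 = n1 * (n1 + n2 + 1) / 2.0
    nn = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (nn * (nn - 1))
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return 0.0, True
    return float((r1 - e1) / math.sqrt(var)), False


def steel_dwass_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseResult]:
    """Steel–Dwass all-pairs comparison over k independent-style groups.

    Each unordered pair is jointly mid-ranked; the standardized rank-sum
    statistic z is referred, as sqrt(2)|z|, to the studentized-range
    distribution with k groups and infinite df (the large-sample form of the
    procedure).  In the repeated-measures setting of this package the
    treatment columns are passed as the groups, matching the test's use as a
    Friedman post hoc.
    """
    gs = [np.asarray(g, float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"G{j}" for j in range(k)]
    out = []
    for i, j in itertools.combinations(range(k), 2):
        z, degenerate = _pairwise_ranksum_z(gs[i], gs[j])
        if degenerate:
            out.append(PairwiseResult((labels[i], labels[j]), 0.0, 1.0, False, True))
            continue
        q = math.sqrt(2.0) * abs(z)
        p = float(sps.studentized_range.sf(q, k, np.inf))
        out.append(PairwiseResult((labels[i], labels[j]), float(z), p, p < alpha))
    return out
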