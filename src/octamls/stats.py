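"""Statistical tests for the feature study and model comparison.

Nonstandard pieces are implemented here: the one-way permutation ANOVA
with pairwise-permutation / Benjamini-Hochberg post hoc, the DeLong test
for correlated ROC curves, the McNemar-Bowker symmetry test, and
stratified bootstrap confidence intervals.  Mann-Whitney gets an exact
small-sample enumeration (ties included); Kruskal-Wallis and the
Kolmogorov-Smirnov normality check are thin, documented wrappers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest pooled sample size for which Mann-Whitney is enumerated exactly.
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    n_permutations: int | None = None
    p_adjusted: float | None = None
    pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _rank_u_statistic(pooled_ranks: np.ndarray, x_index: np.ndarray, n1: int) -> float:
    return float(pooled_ranks[x_index].sum() - n1 * (n1 + 1) / 2)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates all C(n1+n2, n1) label assignments of the
    pooled values (ties handled through midranks), giving the exact
    permutation two-sided p: the fraction of assignments whose U is at
    least as far from its null mean n1*n2/2 as the observed U.  ``'auto'``
    uses the exact test when n1+n2 <= 12 and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult("mann_whitney", statistic=n1 * n2 / 2, p_value=1.0)
    ranks = sps.rankdata(pooled)
    u_obs = _rank_u_statistic(ranks, np.arange(n1), n1)
    mu = n1 * n2 / 2.0

    if mode == "exact" or (mode == "auto" and n1 + n2 <= EXACT_MW_LIMIT):
        if n1 + n2 > 2 * EXACT_MW_LIMIT:
            raise ValueError("exact enumeration infeasible at this sample size")
        dev = abs(u_obs - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = _rank_u_statistic(ranks, np.asarray(combo), n1)
            hits += abs(u - mu) >= dev - 1e-9
            total += 1
        return TestResult("mann_whitney_exact", statistic=u_obs, p_value=hits / total)

    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return TestResult("mann_whitney", statistic=u_obs, p_value=1.0)
    z = (u_obs - mu) / np.sqrt(var)
    return TestResult(
        "mann_whitney", statistic=u_obs, p_value=float(2 * sps.norm.sf(abs(z)))
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square p (df = k - 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", statistic=0.0, p_value=1.0, df=len(groups) - 1)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:
        return TestResult("kruskal_wallis", statistic=0.0, p_value=1.0, df=len(groups) - 1)
    h /= correction
    df = len(groups) - 1
    return TestResult(
        "kruskal_wallis", statistic=float(h), p_value=float(sps.chi2.sf(h, df)), df=df
    )


def _oneway_f(values: np.ndarray, sizes: np.ndarray) -> float:
    """One-way ANOVA F statistic for groups laid out contiguously."""
    n, k = len(values), len(sizes)
    grand = values.mean()
    total_ss = ((values - grand) ** 2).sum()
    ssb = 0.0
    start = 0
    for nj in sizes:
        ssb += nj * (values[start : start + nj].mean() - grand) ** 2
        start += nj
    ssw = total_ss - ssb
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def permutation_oneway(groups, n_perm: int = 10_000, seed: int = 0) -> TestResult:
    """One-way analysis permutation test.

    The group labels are permuted ``n_perm`` times; the p-value uses the
    add-one estimator ``(1 + #{F* >= F_obs}) / (1 + n_perm)``, so it is
    never below ``1 / (1 + n_perm)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_perm < 999:
        warnings.warn(f"n_perm={n_perm} < 999; p-value resolution is coarse", stacklevel=2)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    f_obs = _oneway_f(pooled, sizes)
    rng = np.random.default_rng(seed)
    n = len(pooled)
    hits = 0
    batch = max(1, min(n_perm, 2_000_000 // max(n, 1)))
    done = 0
    # contiguous-block F after shuffling values is equivalent to permuting labels
    k = len(sizes)
    grand = pooled.mean()
    total_ss = ((pooled - grand) ** 2).sum()
    starts = np.concatenate([[0], np.cumsum(sizes)])
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[idx]
        ssb = np.zeros(b)
        for j in range(k):
            seg = perm[:, starts[j] : starts[j + 1]]
            ssb += sizes[j] * (seg.mean(axis=1) - grand) ** 2
        ssw = total_ss - ssb
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ssb / (k - 1)) / (ssw / (n - k))
        f_perm = np.where(ssw <= 0, np.where(ssb > 0, np.inf, 0.0), f_perm)
        hits += int((f_perm >= f_obs - 1e-12).sum())
        done += b
    p = (1 + hits) / (1 + n_perm)
    return TestResult(
        "permutation_oneway", statistic=f_obs, p_value=p, n_permutations=n_perm
    )


def _two_sample_permutation_p(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    d_obs = abs(x.mean() - y.mean())
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[idx]
    d = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
    hits = int((d >= d_obs - 1e-12).sum())
    return d_obs, (1 + hits) / (1 + n_perm)


def pairwise_permutation_fdr(
    groups, n_perm: int = 10_000, seed: int = 0
) -> list[TestResult]:
    """All pairwise two-sample permutation tests, Benjamini-Hochberg adjusted.

    The statistic is the absolute difference of group means; each pair gets
    its own permutation null.  Results are ordered by pair index (i < j)
    and carry both raw and FDR-adjusted p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_perm < 999:
        warnings.warn(f"n_perm={n_perm} < 999; p-value resolution is coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw = []
    stats_ = []
    for i, j in pairs:
        d, p = _two_sample_permutation_p(groups[i], groups[j], n_perm, rng)
        raw.append(p)
        stats_.append(d)
    adjusted = multipletests(raw, method="fdr_bh")[1]
    return [
        TestResult(
            f"pairwise_permutation[{i},{j}]",
            statistic=stats_[m],
            p_value=raw[m],
            n_permutations=n_perm,
            p_adjusted=float(adjusted[m]),
            pair=(i, j),
        )
        for m, (i, j) in enumerate(pairs)
    ]


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    ``labels`` are binary (positive = 1/True).  Midranks handle score ties,
    so a tied pair contributes 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _delong_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    theta = v10.mean()
    return v10, v01, float(theta)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUROC estimate."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    v10, v01, _ = _delong_placements(scores, labels)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(scores_a, scores_b, labels) -> TestResult:
    """DeLong test comparing two correlated AUROCs on the same subjects.

    Covariance between the two AUROC estimates comes from the empirical
    covariance of the placement values; the two-sided p is from the normal
    reference for z = (AUC_a - AUC_b) / SE.  Identical score vectors give
    z = 0, p = 1 by convention (the variance of the difference is zero).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must share one shape")
    v10a, v01a, ta = _delong_placements(scores_a, labels)
    v10b, v01b, tb = _delong_placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        z = 0.0
    else:
        z = (ta - tb) / np.sqrt(var)
    return TestResult("delong", statistic=float(z), p_value=float(2 * sps.norm.sf(abs(z))))


def mcnemar_bowker(table) -> TestResult:
    """Bowker symmetry test for a paired K x K classification table.

    statistic = sum over unordered off-diagonal pairs with n_ij + n_ji > 0
    of (n_ij - n_ji)^2 / (n_ij + n_ji); df = number of included pairs.
    For K = 2 this is McNemar's chi-square without continuity correction.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.number):
        raise ValueError("table entries must be nonnegative counts")
    stat = 0.0
    df = 0
    k = t.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            s = t[i, j] + t[j, i]
            if s > 0:
                stat += (t[i, j] - t[j, i]) ** 2 / s
                df += 1
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return TestResult("mcnemar_bowker", statistic=float(stat), p_value=p, df=df)


def stratified_bootstrap_ci(
    metric_fn,
    labels,
    values,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI with resampling stratified by class.

    Each replicate resamples subjects *within* each class stratum with
    replacement, preserving class counts, so metrics needing both classes
    (AUROC, sensitivity, specificity) are always defined.
    """
    labels = np.asarray(labels)
    values = np.asarray(values)
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        estimates[b] = metric_fn(labels[idx], values[idx])
    low, high = np.percentile(estimates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


def ks_normality(sample) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against N(mean, sd) of the sample.

    Parameters are estimated from the data, so the asymptotic p is
    conservative (the Lilliefors correction is not applied); this mirrors
    routine usage where KS-normality gates the choice of rank tests.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult("ks_normality", statistic=float(stat), p_value=float(p))


def plot_pvalue_grid(pvalues, alpha: float = 0.05, ax=None):
    """Heat grid of -log10(p) per (layer, sector); X marks p > alpha.

    ``pvalues`` is a DataFrame with layers as rows and sectors as columns.
    Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data = -np.log10(np.clip(pvalues.to_numpy(dtype=float), 1e-300, 1.0))
    im = ax.imshow(data, cmap="viridis")
    ax.set_xticks(range(pvalues.shape[1]), pvalues.columns)
    ax.set_yticks(range(pvalues.shape[0]), pvalues.index)
    for i in range(pvalues.shape[0]):
        for j in range(pvalues.shape[1]):
            if pvalues.iloc[i, j] > alpha:
                ax.text(j, i, "X", ha="center", va="center", color="red")
    ax.figure.colorbar(im, ax=ax, label=r"$-\log_{10} p$")
    return ax
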