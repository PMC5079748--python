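"""Statistical primitives of the calling pipeline.

* an exact conditional two-group negative-binomial count test with
  method-of-moments dispersion (the replicated WT-vs-mutant enrichment
  test),
* Benjamini-Hochberg FDR step-up,
* a paired sign-flip permutation test for positional enrichment
  (upstream vs downstream window means),
* region-overlap randomization (uniform per-chromosome relocation).

Rank-sum tests and correlations used in downstream summaries are thin
pass-throughs to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import overlaps_any

__all__ = [
    "TestResult",
    "estimate_dispersion",
    "nb_two_group_test",
    "bh_fdr",
    "PermutationResult",
    "paired_permutation_test",
    "RandomizationResult",
    "randomize_regions",
    "randomize_regions_test",
    "rank_sum_test",
    "pearson",
    "spearman",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    direction: str  # which group is enriched: "A", "B" or "none"
    q_value: float = float("nan")


# ---------------------------------------------------------------------------
# dispersion

def estimate_dispersion(
    counts: np.ndarray,
    group_labels: np.ndarray,
    library_sizes: np.ndarray,
    trim: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Method-of-moments NB dispersion per region.

    ``counts`` is regions x samples.  Counts are normalized to the mean
    library size; within each group with >= 2 replicates the moment
    estimate phi = (s^2 - mu) / mu^2 is formed and averaged over groups
    weighted by degrees of freedom, clipped at zero.  Regions whose
    estimate is zero (or undefined) fall back to the trimmed mean of the
    positive estimates across regions (the common dispersion).

    Returns ``(per_region_phi, common_phi)``.
    """
    counts = np.asarray(counts, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    group_labels = np.asarray(group_labels)
    norm = counts * (library_sizes.mean() / library_sizes)

    per_group = []
    weights = []
    for g in np.unique(group_labels):
        sel = group_labels == g
        n = int(sel.sum())
        if n < 2:
            continue
        mu = norm[:, sel].mean(axis=1)
        s2 = norm[:, sel].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        per_group.append(phi)
        weights.append(n - 1)
    if not per_group:
        warnings.warn("no group has >= 2 replicates; returning common dispersion 0")
        return np.zeros(counts.shape[0]), 0.0
    phi_hat = np.clip(np.average(per_group, axis=0, weights=weights), 0.0, None)

    positive = np.sort(phi_hat[phi_hat > 0])
    if positive.size:
        k = int(len(positive) * trim)
        trimmed = positive[k : len(positive) - k] if len(positive) > 2 * k else positive
        common = float(trimmed.mean())
    else:
        common = 0.0
    phi_out = np.where(phi_hat > 0, phi_hat, common)
    return phi_out, common


# ---------------------------------------------------------------------------
# exact conditional NB test

def _group_total_logpmf(support: np.ndarray, mean: float, phi_group: float) -> np.ndarray:
    """log pmf of a group's replicate-total count: NB with variance
    mean + phi_group * mean^2 (phi_group = phi / n_replicates); Poisson at
    phi_group = 0."""
    if mean <= 0:
        out = np.full(len(support), -np.inf)
        out[support == 0] = 0.0
        return out
    if phi_group <= 0:
        return sps.poisson.logpmf(support, mean)
    r = 1.0 / phi_group
    p = r / (r + mean)
    return sps.nbinom.logpmf(support, r, p)


def nb_two_group_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: np.ndarray,
    lib_b: np.ndarray,
    dispersion: float,
    alternative: str = "greater",
) -> TestResult:
    """Exact conditional test of equal normalized means between two groups.

    Conditions on the grand total T: the group-A total is compared with its
    null conditional distribution P(A = a | A + B = T), built from NB pmfs
    for the two group totals under the pooled mean estimate.  The group
    totals are NB with effective dispersion ``dispersion / n_replicates``
    (exact when per-replicate library sizes are equal within the group).
    At dispersion 0 this is the exact binomial split test with success
    probability L_A / (L_A + L_B).

    ``alternative='greater'`` tests enrichment in group A (the pipeline
    retains WT-enriched regions only).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    counts_a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    lib_a = np.atleast_1d(np.asarray(lib_a, dtype=float))
    lib_b = np.atleast_1d(np.asarray(lib_b, dtype=float))
    a_obs = int(round(counts_a.sum()))
    b_obs = int(round(counts_b.sum()))
    total = a_obs + b_obs
    la, lb = lib_a.sum(), lib_b.sum()
    fold = (counts_a.sum() / la) / max(counts_b.sum() / lb, 1e-300) if total else 1.0
    if total == 0:
        return TestResult(statistic=0.0, p_value=1.0, direction="none")

    mu = total / (la + lb)  # pooled per-unit-library rate under H0
    support = np.arange(total + 1)
    log_fa = _group_total_logpmf(support, mu * la, dispersion / len(counts_a))
    log_fb = _group_total_logpmf(support[::-1], mu * lb, dispersion / len(counts_b))
    log_joint = log_fa + log_fb
    log_joint -= log_joint.max()
    joint = np.exp(log_joint)
    joint /= joint.sum()
    if alternative == "greater":
        p = float(joint[a_obs:].sum())
    elif alternative == "less":
        p = float(joint[: a_obs + 1].sum())
    elif alternative == "two-sided":
        p = float(min(1.0, 2 * min(joint[a_obs:].sum(), joint[: a_obs + 1].sum())))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    direction = "A" if fold > 1 else ("B" if fold < 1 else "none")
    return TestResult(statistic=float(fold), p_value=min(p, 1.0), direction=direction)


# ---------------------------------------------------------------------------
# BH-FDR

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up: q(i) = min_{j>=i} p(j) * m / j on sorted p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# paired permutation test

@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    exhaustive: bool


def paired_permutation_test(
    upstream_means,
    downstream_means,
    n_perm: int = 10_000,
    seed: int | None = None,
    side: str = "greater",
) -> PermutationResult:
    """Paired sign-flip permutation test on per-feature window means.

    The statistic is the mean over features of (downstream - upstream);
    the null swaps the two labels independently within each feature.  With
    2^n <= n_perm all sign patterns are enumerated and the p-value is the
    exact fraction of patterns at least as extreme as the identity;
    otherwise n_perm random patterns are drawn and
    p = (#{permuted >= observed} + 1) / (n_perm + 1).
    """
    up = np.asarray(upstream_means, dtype=float)
    down = np.asarray(downstream_means, dtype=float)
    if up.shape != down.shape:
        raise ValueError("upstream and downstream vectors must have equal length")
    if up.size == 0:
        raise ValueError("need at least one feature")
    diffs = down - up
    observed = diffs.mean()
    n = diffs.size

    def extreme(null_stats: np.ndarray) -> np.ndarray:
        if side == "greater":
            return null_stats >= observed - 1e-12
        if side == "less":
            return null_stats <= observed + 1e-12
        if side == "two-sided":
            return np.abs(null_stats) >= abs(observed) - 1e-12
        raise ValueError(f"unknown side {side!r}")

    if n <= 62 and 2**n <= n_perm:
        patterns = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
        null_stats = (patterns * diffs).mean(axis=1)
        p = float(extreme(null_stats).mean())
        return PermutationResult(observed, p, 2**n, exhaustive=True)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    null_stats = (signs * diffs).mean(axis=1)
    p = (int(extreme(null_stats).sum()) + 1) / (n_perm + 1)
    return PermutationResult(observed, p, n_perm, exhaustive=False)


# ---------------------------------------------------------------------------
# region-overlap randomization

@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    p_enrichment: float
    p_depletion: float

    @property
    def enrichment_ratio(self) -> float:
        mean_null = float(self.null.mean())
        return self.observed / mean_null if mean_null > 0 else float("inf")


def randomize_regions(
    regions: pd.DataFrame, chrom_sizes: dict[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Relocate every region uniformly on its own chromosome, preserving
    length and strand."""
    lengths = (regions["end"] - regions["start"]).to_numpy()
    max_start = np.array(
        [chrom_sizes[c] for c in regions["chrom"]], dtype=np.int64
    ) - lengths
    if (max_start < 0).any():
        bad = regions.iloc[int(np.argmax(max_start < 0))]
        raise ValueError(f"region longer than its chromosome: {bad['chrom']}")
    starts = (rng.random(len(regions)) * (max_start + 1)).astype(np.int64)
    out = regions.copy()
    out["start"] = starts
    out["end"] = starts + lengths
    return out


def randomize_regions_test(
    query_regions: pd.DataFrame,
    reference_regions: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n: int = 1000,
    seed: int | None = None,
    statistic: str = "overlap-count",
) -> RandomizationResult:
    """Empirical overlap test against per-chromosome uniform relocation of
    the query set.

    statistic 'overlap-count' counts reference regions overlapping at least
    one query region (observed and per randomization); a callable taking a
    query frame can be supplied instead.
    """
    if callable(statistic):
        stat = statistic
    elif statistic == "overlap-count":
        def stat(q):
            return float(overlaps_any(reference_regions, q).sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    observed = stat(query_regions)
    null = np.array([stat(randomize_regions(query_regions, chrom_sizes, rng)) for _ in range(n)])
    p_enr = (int((null >= observed).sum()) + 1) / (n + 1)
    p_dep = (int((null <= observed).sum()) + 1) / (n + 1)
    return RandomizationResult(observed, null, p_enr, p_dep)


# ---------------------------------------------------------------------------
# pass-through utilities

def rank_sum_test(x, y, alternative: str = "two-sided"):
    return sps.mannwhitneyu(x, y, alternative=alternative)


def pearson(x, y):
    return sps.pearsonr(x, y)


def spearman(x, y):
    return sps.spearmanr(x, y)
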