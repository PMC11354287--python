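"""Comparative statistics: Wilcoxon rank-sum with Bonferroni adjustment,
ordinary least squares with adjusted R-squared, phylogenetic generalized
least squares under Brownian motion, and Blomberg's K with a permutation
p-value.

The phylogenetic covariance C holds shared root-path lengths under Brownian
motion (diagonal = root-to-tip lengths); on a star phylogeny C is
proportional to the identity and PGLS reduces exactly to OLS.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    adjusted_p: float | None = None
    warning: str = ""


def bonferroni(p_values, m: int | None = None):
    """min(1, m * p) for a family of m comparisons (default: len(p_values))."""
    p_values = list(p_values)
    m = m if m is not None else len(p_values)
    return [min(1.0, m * p) for p in p_values]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided", exact_threshold: int = 20
) -> TestResult:
    """Rank-sum test; exact permutation enumeration for small samples,
    normal approximation with tie and continuity correction otherwise.

    The statistic is the rank sum of ``x``. With every value tied across
    both groups p = 1 (flagged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult(
            float(sps.rankdata(combined)[: x.size].sum()),
            1.0, "wilcoxon-degenerate", (x.size, y.size),
            warning="all values tied across both groups",
        )
    ranks = sps.rankdata(combined)
    w_obs = ranks[: x.size].sum()
    n, m = x.size, y.size
    if n + m <= exact_threshold:
        total = 0
        count = 0
        mu = (n + m + 1) * n / 2
        for subset in itertools.combinations(range(n + m), n):
            w = ranks[list(subset)].sum()
            total += 1
            if alternative == "less":
                count += w <= w_obs + 1e-9
            elif alternative == "greater":
                count += w >= w_obs - 1e-9
            else:
                count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
        return TestResult(
            float(w_obs), count / total, "wilcoxon-exact", (n, m)
        )
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return TestResult(float(w_obs), float(res.pvalue), "wilcoxon-normal", (n, m))


# ---------------------------------------------------------------------------
# Linear and phylogenetic regressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    coefficients: tuple  # (intercept, slopes...)
    p_values: tuple
    r2_adj: float | None
    method: str
    n: int


def linear_fit(y, x) -> FitResult:
    """Ordinary least squares of y on x (1-D or 2-D) with intercept;
    reports adjusted R-squared. Collinear predictors raise."""
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictors")
    if y.shape[0] <= design.shape[1]:
        raise ValueError("need n > number of parameters")
    fit = sm.OLS(y, design).fit()
    return FitResult(
        tuple(fit.params), tuple(fit.pvalues), float(fit.rsquared_adj), "OLS",
        int(y.shape[0]),
    )


def phylo_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = shared root-path length of
    tips i and j (diagonal = root-to-tip lengths)."""
    leaf = {l.taxon.label: l for l in tree.leaf_node_iter()}
    missing = set(taxa) - set(leaf)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent else 0.0) + (
            node.edge.length or 0.0 if parent else 0.0
        )

    def root_path(node):
        out = []
        while node is not None:
            out.append(id(node))
            node = node.parent_node
        return out

    paths = {t: root_path(leaf[t]) for t in taxa}
    n = len(taxa)
    c = np.zeros((n, n))
    for i, t1 in enumerate(taxa):
        set1 = set(paths[t1])
        for j, t2 in enumerate(taxa):
            if j < i:
                continue
            # deepest shared node on the two root paths
            shared = [nid for nid in paths[t2] if nid in set1]
            mrca_depth = max(depth[nid] for nid in shared)
            c[i, j] = c[j, i] = mrca_depth
    return c


def pgls_fit(tree: dendropy.Tree, y: pd.Series, x: pd.Series | pd.DataFrame) -> FitResult:
    """Generalized least squares with Brownian covariance from the tree:
    beta = (X' C^-1 X)^-1 X' C^-1 y, with t-tests on coefficients."""
    taxa = list(y.index)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate tip rows in trait data")
    c = phylo_covariance(tree, taxa)
    if np.linalg.cond(c) > 1e12:
        raise ValueError(
            "singular phylogenetic covariance; consider a branch-length floor"
        )
    xmat = np.atleast_2d(np.asarray(x.loc[taxa], dtype=float))
    if xmat.shape[0] != len(taxa):
        xmat = xmat.T
    design = sm.add_constant(xmat)
    fit = sm.GLS(np.asarray(y, dtype=float), design, sigma=c).fit()
    return FitResult(
        tuple(fit.params), tuple(fit.pvalues), None, "PGLS", len(taxa)
    )


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlombergK:
    k: float
    p_value: float | None
    n_perm: int
    defined: bool = True
    note: str = ""


def _k_statistic(vals: np.ndarray, c_inv: np.ndarray, expectation: float) -> float:
    n = vals.size
    one = np.ones(n)
    denom = one @ c_inv @ one
    a_hat = (one @ c_inv @ vals) / denom
    resid = vals - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ c_inv @ resid / (n - 1)
    return (mse0 / mse) / expectation


def blomberg_k(
    tree: dendropy.Tree, trait: pd.Series, n_perm: int = 999, seed: int = 0
) -> BlombergK:
    """Blomberg's K with a tip-shuffling permutation p-value.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_expected, where MSE0 is the mean
    squared deviation from the phylogenetic (GLS) mean, MSE the
    C-corrected error, and the Brownian expectation is
    (tr(C) - n / (1' C^-1 1)) / (n - 1). K ~ 1 under Brownian motion;
    K > 1 means stronger-than-Brownian similarity of relatives. p is the
    fraction of trait permutations with K at least as large as observed."""
    taxa = list(trait.index)
    vals = np.asarray(trait, dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(vals, vals[0]):
        return BlombergK(float("nan"), None, 0, defined=False,
                         note="zero-variance trait")
    c = phylo_covariance(tree, taxa)
    if np.any(np.diag(c) <= 0):
        raise ValueError("branch lengths must be positive")
    c_inv = np.linalg.inv(c)
    n = vals.size
    one = np.ones(n)
    expectation = (np.trace(c) - n / (one @ c_inv @ one)) / (n - 1)
    k_obs = _k_statistic(vals, c_inv, expectation)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        k_perm = _k_statistic(rng.permutation(vals), c_inv, expectation)
        if k_perm >= k_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return BlombergK(float(k_obs), p, n_perm)


def simulate_brownian(
    tree: dendropy.Tree, taxa: list[str], seed: int = 0, sigma: float = 1.0,
    root_value: float = 0.0,
) -> pd.Series:
    """One Brownian-motion trait realization on the tree."""
    rng = np.random.default_rng(seed)
    c = phylo_covariance(tree, taxa)
    vals = rng.multivariate_normal(np.full(len(taxa), root_value), sigma**2 * c)
    return pd.Series(vals, index=taxa)
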