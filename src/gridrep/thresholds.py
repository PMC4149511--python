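"""Trend smooths and break-point detection for metric tables.

Two complementary summaries of how a metric responds to sample size and
surface heterogeneity (SD):

* :func:`fit_smooth` — an additive model ``y ~ s(sample_size) + s(sd)``
  with cubic penalized B-spline smooths.  Each smooth uses up to 10
  interior knots at covariate quantiles and a second-difference penalty
  on the basis coefficients; the common smoothing parameter is chosen by
  generalized cross-validation (GCV).  Reported "deviance explained" is
  1 - RSS/TSS (the Gaussian identity-link case).
* :func:`fit_ctree` — conditional-inference recursive partitioning.  At
  each node the association of every covariate with the response is
  tested with a Monte-Carlo permutation test on the absolute centered
  cross-product statistic; p-values are Bonferroni-adjusted across
  covariates, splitting stops when none is significant, and the split
  point maximizes the standardized two-sample mean difference.  Internal
  node split values are the detected break-points ("thresholds").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SmoothFit",
    "TreeNode",
    "fit_smooth",
    "fit_ctree",
    "count_splits_by_covariate",
]


# ---------------------------------------------------------------------
# Penalized-spline additive smooth
# ---------------------------------------------------------------------

_N_INTERIOR_KNOTS = 10
_SPLINE_DEGREE = 3


@dataclass
class _SmoothTerm:
    name: str
    knots: np.ndarray  # full knot vector (boundary knots repeated)
    col_means: np.ndarray  # centering applied to the basis columns
    sl: slice  # columns of this term in the design matrix

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, self.knots[_SPLINE_DEGREE], self.knots[-_SPLINE_DEGREE - 1])
        B = BSpline.design_matrix(x, self.knots, _SPLINE_DEGREE).toarray()
        return B - self.col_means


@dataclass
class SmoothFit:
    """A fitted additive penalized-spline trend."""

    response_name: str
    terms: list[_SmoothTerm]
    coefficients: np.ndarray
    lambda_: float
    deviance_explained: float
    edf: float
    fitted: np.ndarray
    se: np.ndarray
    sigma2: float
    _x_cols: list[str] = field(default_factory=list)
    _xtx_inv: np.ndarray | None = None

    def predict(self, x_table: pd.DataFrame, with_se: bool = False):
        """Fitted values (optionally with pointwise SE) at new covariates."""
        X = self._design(x_table)
        fit = X @ self.coefficients
        if not with_se:
            return fit
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self._xtx_inv, X) * self.sigma2)
        return fit, se

    def band(self, x_table: pd.DataFrame) -> pd.DataFrame:
        """Fit with pointwise 95% interval, as a data frame."""
        fit, se = self.predict(x_table, with_se=True)
        out = x_table.copy()
        out["fit"] = fit
        out["lower"] = fit - 1.96 * se
        out["upper"] = fit + 1.96 * se
        return out

    def _design(self, x_table: pd.DataFrame) -> np.ndarray:
        n = len(x_table)
        ncol = 1 + sum(t.sl.stop - t.sl.start for t in self.terms)
        X = np.zeros((n, ncol))
        X[:, 0] = 1.0
        for t in self.terms:
            X[:, t.sl] = t.basis(x_table[t.name].to_numpy(dtype=float))
        return X


def _term_knots(x: np.ndarray) -> np.ndarray:
    """Full cubic-spline knot vector: interior knots at quantiles."""
    qs = np.linspace(0, 1, _N_INTERIOR_KNOTS + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs))
    lo, hi = x.min(), x.max()
    interior = interior[(interior > lo) & (interior < hi)]
    return np.concatenate(
        [np.repeat(lo, _SPLINE_DEGREE + 1), interior, np.repeat(hi, _SPLINE_DEGREE + 1)]
    )


def _second_difference_penalty(k: int) -> np.ndarray:
    if k < 3:
        return np.zeros((k, k))
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


def fit_smooth(
    x_table: pd.DataFrame,
    y,
    response_name: str = "y",
    lambdas: np.ndarray | None = None,
) -> SmoothFit:
    """Fit ``y ~ s(sample_size) + s(sd)`` (one smooth per covariate).

    Rows with non-finite y (e.g. undefined correlations) are dropped.
    A zero-variance covariate loses its smooth with a warning.  The
    smoothing parameter is selected by minimizing
    ``GCV = n * RSS / (n - edf)^2`` over a log-spaced grid.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(x_table) != len(y):
        raise ValueError("x_table and y length mismatch")
    keep = np.isfinite(y)
    x_table = x_table.loc[keep].reset_index(drop=True)
    y = y[keep]
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 rows with finite response")

    terms: list[_SmoothTerm] = []
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    start = 1
    for name in x_table.columns:
        x = x_table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"covariate {name!r} has zero variance; smooth dropped")
            continue
        knots = _term_knots(x)
        B = BSpline.design_matrix(x, knots, _SPLINE_DEGREE).toarray()
        col_means = B.mean(axis=0)  # center for identifiability vs intercept
        Bc = B - col_means
        sl = slice(start, start + B.shape[1])
        terms.append(_SmoothTerm(name, knots, col_means, sl))
        blocks.append(Bc)
        start = sl.stop
    X = np.hstack(blocks)
    p = X.shape[1]
    P = np.zeros((p, p))
    for t in terms:
        k = t.sl.stop - t.sl.start
        P[t.sl, t.sl] = _second_difference_penalty(k)

    XtX = X.T @ X
    Xty = X.T @ y
    tss = float(((y - y.mean()) ** 2).sum())

    if lambdas is None:
        lambdas = np.logspace(-6, 8, 40)
    best = None
    ridge = 1e-10 * np.eye(p)  # numerical floor; P has a null space
    for lam in lambdas:
        A = XtX + lam * P + ridge
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        beta = Ainv @ Xty
        fitted = X @ beta
        rss = float(((y - fitted) ** 2).sum())
        edf = float(np.trace(Ainv @ XtX))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, fitted, rss, edf, Ainv)
    if best is None:
        raise np.linalg.LinAlgError("no smoothing parameter yielded a solvable fit")
    _, lam, beta, fitted, rss, edf, Ainv = best
    dev_expl = 0.0 if tss == 0.0 else min(max(1.0 - rss / tss, 0.0), 1.0)
    sigma2 = rss / max(n - edf, 1.0)
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, Ainv, X) * sigma2)
    return SmoothFit(
        response_name=response_name,
        terms=terms,
        coefficients=beta,
        lambda_=float(lam),
        deviance_explained=dev_expl,
        edf=edf,
        fitted=fitted,
        se=se,
        sigma2=sigma2,
        _x_cols=list(x_table.columns),
        _xtx_inv=Ainv,
    )


def smooth_to_csv(fit: SmoothFit, x_table: pd.DataFrame, path) -> None:
    """Export (covariate grid, fit, lower, upper) as CSV."""
    fit.band(x_table).to_csv(path, index=False)


# ---------------------------------------------------------------------
# Conditional-inference tree
# ---------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node of a conditional-inference partition."""

    node_id: int
    n_observations: int
    is_leaf: bool
    leaf_mean: float
    split_covariate: str | None = None
    split_value: float | None = None
    adjusted_p: float | None = None
    left: "TreeNode | None" = None  # rows with covariate <= split_value
    right: "TreeNode | None" = None  # rows with covariate > split_value

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "n": self.n_observations,
            "is_leaf": self.is_leaf,
            "mean": self.leaf_mean,
        }
        if not self.is_leaf:
            d.update(
                split_covariate=self.split_covariate,
                split_value=self.split_value,
                adjusted_p=self.adjusted_p,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return (
                f"{pad}[{self.node_id}] leaf: n={self.n_observations}, "
                f"mean={self.leaf_mean:.4g}\n"
            )
        out = (
            f"{pad}[{self.node_id}] {self.split_covariate} <= "
            f"{self.split_value:.4g} (p_adj={self.adjusted_p:.4g}, "
            f"n={self.n_observations})\n"
        )
        return out + self.left.to_text(indent + 1) + self.right.to_text(indent + 1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _permutation_pvalue(
    x: np.ndarray, y: np.ndarray, perms: np.ndarray
) -> float:
    """Plus-one-corrected Monte-Carlo p for |sum((x-xbar)(y-ybar))|.

    ``perms`` is a (B, n) matrix of permuted row indices shared across
    covariates at a node.  The permutation distribution of the absolute
    centered cross-product is location/scale-free in y (standardizing by
    the permutation SD would not change the ranking), so the raw
    statistic is compared directly.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    t_obs = abs(float(xc @ yc))
    t_perm = np.abs(yc[perms] @ xc)
    return (int((t_perm >= t_obs - 1e-12).sum()) + 1) / (len(perms) + 1)


def _best_cutpoint(
    x: np.ndarray, y: np.ndarray, min_node: int
) -> tuple[float, float] | None:
    """Cutpoint maximizing |mean_L - mean_R| * sqrt(nL*nR/n).

    Scans midpoints between distinct sorted x values, keeping only cuts
    leaving >= min_node rows on each side; ties go to the lower
    cutpoint.  Returns (cutpoint, statistic) or None if no feasible cut.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    csum = np.cumsum(ys)
    total = csum[-1]
    # candidate boundaries after position i (0-based): left = xs[:i+1]
    distinct = xs[:-1] != xs[1:]
    nl = np.arange(1, n)
    nr = n - nl
    feasible = distinct & (nl >= min_node) & (nr >= min_node)
    if not feasible.any():
        return None
    mean_l = csum[:-1] / nl
    mean_r = (total - csum[:-1]) / nr
    stat = np.abs(mean_l - mean_r) * np.sqrt(nl * nr / n)
    stat = np.where(feasible, stat, -np.inf)
    i = int(np.argmax(stat))  # argmax takes the first (lowest) maximizer
    cut = 0.5 * (xs[i] + xs[i + 1])
    return float(cut), float(stat[i])


def fit_ctree(
    x_table: pd.DataFrame,
    y,
    alpha: float = 0.05,
    permutations: int = 9999,
    min_node: int = 20,
    rng: np.random.Generator | int | None = None,
) -> TreeNode:
    """Conditional-inference recursive partitioning of y on the covariates.

    At each node: (1) a Monte-Carlo permutation p-value per covariate
    for association with y; (2) Bonferroni adjustment across covariates;
    (3) stop if the minimum adjusted p >= alpha, the node is smaller
    than ``2 * min_node``, or y is constant; (4) otherwise split the
    most significant covariate at the cutpoint maximizing the
    standardized two-sample mean difference, and recurse.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if permutations < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    y = np.asarray(y, dtype=float).ravel()
    if len(x_table) != len(y):
        raise ValueError("x_table and y length mismatch")
    keep = np.isfinite(y)
    X = x_table.loc[keep].reset_index(drop=True)
    y = y[keep]
    if len(y) < 2 * min_node:
        # too small to ever split: a single leaf
        return TreeNode(1, len(y), True, float(y.mean()) if len(y) else float("nan"))
    rng = np.random.default_rng(rng)
    counter = [0]

    cov_arrays = {c: X[c].to_numpy(dtype=float) for c in X.columns}

    def grow(idx: np.ndarray) -> TreeNode:
        counter[0] += 1
        nid = counter[0]
        yn = y[idx]
        node_n = len(idx)
        leaf = TreeNode(nid, node_n, True, float(yn.mean()))
        if node_n < 2 * min_node or np.ptp(yn) == 0.0:
            return leaf
        # shared permutation matrix for this node
        perms = np.argsort(rng.random((permutations, node_n)), axis=1)
        pvals = {}
        for name, arr in cov_arrays.items():
            xn = arr[idx]
            if np.ptp(xn) == 0.0:
                continue
            pvals[name] = _permutation_pvalue(xn, yn, perms)
        if not pvals:
            return leaf
        k = len(pvals)
        adj = {name: min(1.0, p * k) for name, p in pvals.items()}
        best_cov = min(adj, key=lambda name: (adj[name], name))
        if adj[best_cov] >= alpha:
            return leaf
        cut = _best_cutpoint(cov_arrays[best_cov][idx], yn, min_node)
        if cut is None:
            return leaf
        cut_value, _ = cut
        go_left = cov_arrays[best_cov][idx] <= cut_value
        node = TreeNode(
            nid,
            node_n,
            False,
            float(yn.mean()),
            split_covariate=best_cov,
            split_value=cut_value,
            adjusted_p=adj[best_cov],
        )
        node.left = grow(idx[go_left])
        node.right = grow(idx[~go_left])
        return node

    return grow(np.arange(len(y)))


def count_splits_by_covariate(tree: TreeNode) -> dict[str, int]:
    """Number of internal nodes splitting on each covariate."""
    counts: dict[str, int] = {}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        counts[node.split_covariate] = counts.get(node.split_covariate, 0) + 1
        walk(node.left)
        walk(node.right)

    walk(tree)
    return counts
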