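"""Phylogenetic generalized least squares with Pagel's lambda.

Closely related species do not give independent data points: under a
Brownian-motion model of trait evolution the residual covariance of two
tips is proportional to the branch length they share from the root.
PGLS fits a linear model with that covariance, and Pagel's lambda
scales the off-diagonal (shared) part to measure how much phylogenetic
signal the residuals actually carry (0 = none, 1 = full Brownian).

This module builds the Brownian covariance from a Newick tree,
estimates lambda by restricted (or full) maximum likelihood over a
bounded grid with golden-section refinement, provides the
least-squares-style consensus of a sample of trees (mean patristic
distances, neighbor joining, nonnegative branch-length refit), prunes
non-significant interaction terms sequentially, and reports variance
explained as one minus the ratio of raw residual variance to response
variance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls

__all__ = [
    "PGLSError",
    "PGLSResult",
    "read_trees",
    "consensus_tree",
    "phylo_covariance",
    "pagel_transform",
    "fit_pgls",
    "build_design",
    "prune_interactions",
    "variance_explained",
]


class PGLSError(ValueError):
    pass


@dataclass
class PGLSResult:
    """Fitted PGLS model: coefficients, tests, lambda and fit summary."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lambda_hat: float
    loglik: float
    var_explained: float
    n: int
    method: str
    pruning_trace: list[dict] = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )


def read_trees(path) -> list[dendropy.Tree]:
    """Read one or more Newick trees (one per line) sharing a taxon namespace."""
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", taxon_namespace=tns
    )
    if len(trees) == 0:
        raise PGLSError(f"no trees found in {path}")
    return list(trees)


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return D


def consensus_tree(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Distance-based consensus of a sample of trees on the same tips.

    The patristic (tip-to-tip path length) distance matrix is averaged
    across the sample; a topology is built from the mean matrix by
    neighbor joining and its branch lengths are re-fitted by nonnegative
    least squares against the mean distances. The result is midpoint
    rooted. A single input tree is returned unchanged.
    """
    if not trees:
        raise PGLSError("need at least one tree")
    labels = sorted(_tip_labels(trees[0]))
    for t in trees[1:]:
        if sorted(_tip_labels(t)) != labels:
            raise PGLSError("trees have mismatched tip sets")
    if len(trees) == 1:
        return trees[0]
    D = np.mean([_patristic_matrix(t, labels) for t in trees], axis=0)

    import skbio

    dm = skbio.DistanceMatrix(D, ids=labels)
    nj_tree = skbio.tree.nj(dm)
    newick = io.StringIO()
    nj_tree.write(newick)
    tree = dendropy.Tree.get(data=newick.getvalue(), schema="newick")
    _fit_branch_lengths_nnls(tree, D, labels)
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def _fit_branch_lengths_nnls(
    tree: dendropy.Tree, D: np.ndarray, labels: list[str]
) -> None:
    """Refit branch lengths by NNLS so path lengths match D (in place)."""
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    edge_index = {id(e): k for k, e in enumerate(edges)}
    # leaf -> set of edge indices on its root path
    paths: dict[str, set[int]] = {}
    for leaf in tree.leaf_node_iter():
        path = set()
        node = leaf
        while node.parent_node is not None:
            path.add(edge_index[id(node.edge)])
            node = node.parent_node
        paths[leaf.taxon.label] = path
    n = len(labels)
    rows = []
    targets = []
    for i in range(n):
        for j in range(i + 1, n):
            sym = paths[labels[i]] ^ paths[labels[j]]
            row = np.zeros(len(edges))
            row[list(sym)] = 1.0
            rows.append(row)
            targets.append(D[i, j])
    sol, _ = nnls(np.array(rows), np.array(targets))
    for e, length in zip(edges, sol):
        e.length = float(length)


def phylo_covariance(
    tree: dendropy.Tree, labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance matrix: shared root-to-MRCA path lengths.

    ``C[i, j]`` is the branch length shared by tips i and j from the
    root; the diagonal holds root-to-tip depths. Computed as
    ``(depth_i + depth_j - d_ij) / 2`` from depths and patristic
    distances.
    """
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise PGLSError("negative branch length")
    if labels is None:
        labels = sorted(_tip_labels(tree))
    depth = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    missing = [l for l in labels if l not in depth]
    if missing:
        raise PGLSError(f"species not on the tree: {missing[:5]}")
    D = _patristic_matrix(tree, labels)
    dep = np.array([depth[l] for l in labels])
    C = (dep[:, None] + dep[None, :] - D) / 2.0
    C[np.diag_indices_from(C)] = dep
    return C, labels


def pagel_transform(C: np.ndarray, lam_p: float) -> np.ndarray:
    """Scale the off-diagonal covariance by Pagel's lambda."""
    C = np.asarray(C, dtype=float)
    V = lam_p * C
    V[np.diag_indices_from(V)] = np.diag(C)
    return V


def _gls_profile(X: np.ndarray, y: np.ndarray, V: np.ndarray, method: str):
    """GLS estimates and profiled (restricted) log-likelihood for fixed V."""
    n, p = X.shape
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(V)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if method == "REML":
        df = n - p
        sigma2 = rss / df
        sign, logdetXtX = np.linalg.slogdet(XtX)
        ll = -0.5 * (
            df * np.log(2 * np.pi * sigma2)
            + df
            + logdetV
            + logdetXtX
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdetV)
    cov_beta = sigma2 * np.linalg.inv(XtX)
    return beta, cov_beta, sigma2, ll


def fit_pgls(
    X,
    y,
    C: np.ndarray,
    method: str = "REML",
    *,
    terms: list[str] | None = None,
    lambda_bounds: tuple[float, float] = (0.0, 1.0),
    grid_step: float = 0.01,
) -> PGLSResult:
    """Fit PGLS, estimating Pagel's lambda by (restricted) ML.

    The profiled log-likelihood is evaluated on a grid over
    ``lambda_bounds`` (step ``grid_step``) and refined around the best
    grid point by bounded scalar optimization. Coefficient standard
    errors come from ``sigma2 (X' V^-1 X)^-1`` and two-sided t-tests
    use ``n - p`` degrees of freedom.

    ``X`` should include the intercept column (see
    :func:`build_design`); predictors are expected standardized.
    """
    from scipy import stats

    if isinstance(X, pd.DataFrame):
        terms = terms or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if terms is None:
        terms = [f"b{j}" for j in range(p)]
    if n < p + 2:
        raise PGLSError(f"n = {n} too small for {p} terms")
    if np.linalg.matrix_rank(X) < p:
        raise PGLSError("singular design matrix")
    if method not in ("ML", "REML"):
        raise PGLSError("method must be ML or REML")

    def negll(lam_p: float) -> float:
        V = pagel_transform(C, lam_p)
        try:
            return -_gls_profile(X, y, V, method)[3]
        except np.linalg.LinAlgError:
            return np.inf

    lo, hi = lambda_bounds
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = np.array([negll(g) for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(0, k - 1)]
    b = grid[min(len(grid) - 1, k + 1)]
    if b > a:
        res = minimize_scalar(
            negll, bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x) if res.fun <= vals[k] else float(grid[k])
    else:
        lam_hat = float(grid[k])

    V = pagel_transform(C, lam_hat)
    beta, cov_beta, sigma2, ll = _gls_profile(X, y, V, method)
    se = np.sqrt(np.diag(cov_beta))
    tstat = beta / se
    df = n - p
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    fitted = X @ beta
    ve = variance_explained_values(y, fitted)
    return PGLSResult(
        terms=list(terms),
        beta=beta,
        se=se,
        t=tstat,
        p=pvals,
        lambda_hat=lam_hat,
        loglik=float(ll),
        var_explained=ve,
        n=n,
        method=method,
    )


def variance_explained_values(y, fitted) -> float:
    """1 - var(raw residuals)/var(response), both with n-1 denominators."""
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise PGLSError("response has zero variance")
    return 1.0 - float(np.var(y - fitted, ddof=1)) / vy


def variance_explained(result: PGLSResult, X, y) -> float:
    """Variance explained recomputed from a fitted result and its data."""
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    return variance_explained_values(y, X @ result.beta)


def _interaction_order(term: str) -> int:
    return term.count(":") + 1


def build_design(
    data: pd.DataFrame,
    predictors: list[str],
    max_order: int | None = None,
    *,
    standardize: bool = True,
) -> pd.DataFrame:
    """Design matrix with intercept, main effects and all interactions.

    Predictors are standardized to mean 0, variance 1 before products
    are formed. ``max_order`` caps the interaction order (default: all
    orders up to the number of predictors). Interaction columns are
    named ``a:b`` (alphabetical component order preserved from the
    predictor list).
    """
    from itertools import combinations

    cols = {"(Intercept)": np.ones(len(data))}
    Z = {}
    for name in predictors:
        x = data[name].to_numpy(dtype=float)
        if standardize:
            sd = x.std(ddof=1)
            if sd <= 0:
                raise PGLSError(f"predictor {name} is constant")
            x = (x - x.mean()) / sd
        Z[name] = x
        cols[name] = x
    k = len(predictors)
    top = k if max_order is None else min(max_order, k)
    for order in range(2, top + 1):
        for combo in combinations(predictors, order):
            cols[":".join(combo)] = np.prod([Z[c] for c in combo], axis=0)
    return pd.DataFrame(cols, index=data.index)


def prune_interactions(
    design: pd.DataFrame,
    y,
    C: np.ndarray,
    alpha: float = 0.05,
    method: str = "REML",
) -> PGLSResult:
    """Sequentially remove non-significant interaction terms.

    Starting from the full design, the highest-order interactions are
    examined first: while any removable interaction has p >= alpha, the
    least significant one of the highest order still present is dropped
    and the model refitted. Main effects and the intercept are never
    removed. If the full design is not estimable for the available n,
    interaction orders are trimmed from the top until it is (recorded
    in the trace).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = design.copy()
    trace: list[dict] = []
    # trim inestimable high orders
    while design.shape[1] + 2 > n:
        orders = [_interaction_order(t) for t in design.columns
                  if t != "(Intercept)"]
        top = max(orders)
        if top == 1:
            raise PGLSError("too few observations for the main-effects model")
        drop = [t for t in design.columns
                if t != "(Intercept)" and _interaction_order(t) == top]
        design = design.drop(columns=drop)
        trace.append({"action": "trim_inestimable", "order": top,
                      "terms": drop})

    while True:
        result = fit_pgls(design, y, C, method=method)
        pmap = dict(zip(result.terms, result.p))
        inter = [t for t in design.columns if _interaction_order(t) > 1]
        if not inter:
            break
        top = max(_interaction_order(t) for t in inter)
        candidates = [t for t in inter
                      if _interaction_order(t) == top and pmap[t] >= alpha]
        if not candidates:
            if any(pmap[t] >= alpha for t in inter):
                # only lower-order interactions are removable, but a
                # higher-order term containing them is still present and
                # significant: stop (hierarchy respected)
                lower = [t for t in inter if _interaction_order(t) < top
                         and pmap[t] >= alpha]
                free = [t for t in lower if not any(
                    set(t.split(":")) <= set(h.split(":"))
                    for h in inter if _interaction_order(h) == top)]
                if not free:
                    break
                worst = max(free, key=lambda t: pmap[t])
            else:
                break
        else:
            worst = max(candidates, key=lambda t: pmap[t])
        design = design.drop(columns=[worst])
        trace.append({"action": "remove", "term": worst,
                      "p": float(pmap[worst])})
    result.pruning_trace = trace
    return result
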