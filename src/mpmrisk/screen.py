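"""Variable-importance screen for species-mean metrics vs Red List rank.

A regression forest is grown on the species-by-metric table with the
ordinal Red List rank (1-5) as a continuous response, and predictors
are ranked by conditional permutation importance: the increase in
out-of-bag (OOB) mean squared error when a predictor is permuted,
averaged over trees, where the permutation is carried out within strata
defined by the tree's own split points on covariates correlated with
the permuted predictor. Conditioning on correlated covariates keeps a
predictor from borrowing importance from its correlates, which matters
here because demographic metrics are strongly interdependent.

Pure-noise predictors draw importances scattered around zero, so
negative values estimate the scale of random variation. A predictor is
declared important only when its importance is at least twice the
magnitude of the most negative importance observed.

The ensemble uses variance-reduction (CART) splits over ``mtry``
randomly drawn candidate predictors per node, grown on subsamples drawn
without replacement; the conditional-importance semantics follow the
conditional-inference forest literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ForestConfig",
    "RegressionForest",
    "ImportanceResult",
    "fit_forest",
    "conditional_importance",
    "select_important",
    "screen",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest and importance settings.

    ``mtry`` candidate predictors are tried at each node; trees are
    grown on ``bootstrap_fraction`` subsamples without replacement;
    nodes with fewer than ``min_node_size`` observations are not split.
    ``conditional_threshold`` is the absolute Pearson correlation above
    which a covariate joins the conditioning set of a permuted
    predictor.
    """

    n_trees: int = 1000
    mtry: int = 4
    min_node_size: int = 5
    bootstrap_fraction: float = 0.632
    conditional_threshold: float = 0.2
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if not (1 <= self.mtry):
            raise ValueError("mtry must be at least 1")
        if not (0 < self.bootstrap_fraction <= 1):
            raise ValueError("bootstrap_fraction must be in (0, 1]")


@dataclass
class RegressionForest:
    """A fitted ensemble with per-tree out-of-bag bookkeeping."""

    trees: list[DecisionTreeRegressor]
    oob_indices: list[np.ndarray]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    config: ForestConfig

    def oob_prediction(self) -> np.ndarray:
        """OOB ensemble prediction per observation (NaN if never OOB)."""
        n = len(self.y)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size:
                total[oob] += tree.predict(self.X[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    def oob_r2(self) -> float:
        pred = self.oob_prediction()
        ok = np.isfinite(pred)
        resid = self.y[ok] - pred[ok]
        return float(1 - resid.var() / self.y[ok].var())


@dataclass
class ImportanceResult:
    importances: dict[str, float]
    threshold: float
    selected: list[str]
    seed: int
    n_used: int = 0
    n_dropped: int = 0
    config: ForestConfig | None = None
    dropped_species: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = sorted(self.importances, key=self.importances.get, reverse=True)
        return pd.DataFrame(
            {
                "metric": names,
                "importance": [self.importances[n] for n in names],
                "selected": [n in self.selected for n in names],
                "threshold": self.threshold,
            }
        )


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    return Xv, yv, names


def fit_forest(X, y, config: ForestConfig) -> RegressionForest:
    """Grow the regression forest; reproducible for a fixed seed."""
    Xv, yv, names = _as_xy(X, y)
    n, p = Xv.shape
    config.validate(p)
    if n < config.min_node_size:
        raise ValueError("fewer observations than min_node_size")
    if not np.all(np.isfinite(Xv)):
        raise ValueError("predictors contain missing values; drop those rows first")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_sub = max(2, int(round(config.bootstrap_fraction * n)))
    mtry = min(config.mtry, p)
    trees: list[DecisionTreeRegressor] = []
    oobs: list[np.ndarray] = []
    for _ in range(config.n_trees):
        sub = rng.choice(n, size=n_sub, replace=False)
        oob = np.setdiff1d(np.arange(n), sub)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_split=config.min_node_size,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xv[sub], yv[sub])
        trees.append(tree)
        oobs.append(oob)
    return RegressionForest(
        trees=trees, oob_indices=oobs, feature_names=names,
        X=Xv, y=yv, config=config,
    )


def _tree_split_points(tree: DecisionTreeRegressor, feature: int) -> np.ndarray:
    """Sorted thresholds this tree uses to split on ``feature``."""
    t = tree.tree_
    mask = t.feature == feature
    return np.unique(t.threshold[mask])


def _strata_labels(
    tree: DecisionTreeRegressor, X_oob: np.ndarray, cond: np.ndarray
) -> np.ndarray:
    """Stratum id per OOB row from the tree's split points on ``cond``."""
    n = X_oob.shape[0]
    if cond.size == 0:
        return np.zeros(n, dtype=np.int64)
    labels = np.zeros(n, dtype=np.int64)
    for l in cond:
        cuts = _tree_split_points(tree, int(l))
        if cuts.size == 0:
            continue
        bins = np.searchsorted(cuts, X_oob[:, l], side="right")
        labels = labels * (cuts.size + 2) + bins
    return labels


def conditional_importance(forest: RegressionForest) -> dict[str, float]:
    """Conditional permutation importances (OOB MSE increase per predictor).

    For each tree and predictor the OOB rows are permuted within strata
    formed by the tree's split points on every covariate whose absolute
    correlation with the predictor reaches the conditioning threshold;
    the per-tree MSE difference (permuted minus intact) is averaged over
    trees. Predictors a tree never uses contribute exactly zero for
    that tree.
    """
    X, y = forest.X, forest.y
    n, p = X.shape
    cfg = forest.config
    # conditioning sets from the global correlation structure
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    cond_sets = [
        np.flatnonzero(
            (np.abs(corr[k]) >= cfg.conditional_threshold)
            & (np.arange(p) != k)
        )
        for k in range(p)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    sums = np.zeros(p)
    counts = np.zeros(p)
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if oob.size < 2:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base_mse = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        used = set(tree.tree_.feature[tree.tree_.feature >= 0].tolist())
        for k in range(p):
            counts[k] += 1
            if k not in used:
                continue  # permutation cannot move the prediction
            labels = _strata_labels(tree, X_oob, cond_sets[k])
            Xp = X_oob.copy()
            for lab in np.unique(labels):
                idx = np.flatnonzero(labels == lab)
                if idx.size > 1:
                    Xp[idx, k] = Xp[rng.permutation(idx), k]
            perm_mse = float(np.mean((tree.predict(Xp) - y_oob) ** 2))
            sums[k] += perm_mse - base_mse
    with np.errstate(invalid="ignore"):
        imp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return dict(zip(forest.feature_names, imp.tolist()))


def select_important(
    importances: dict[str, float],
) -> tuple[list[str], float]:
    """Apply the noise-threshold selection rule.

    The threshold is twice the magnitude of the most negative
    importance (random variation estimated from predictors that hurt
    when permuted). When no importance is negative the fallback is
    twice the smallest positive importance. Selected predictors are
    those at or above the threshold (and strictly positive), ordered by
    decreasing importance.
    """
    vals = np.array(list(importances.values()), dtype=float)
    if vals.size == 0:
        return [], 0.0
    vmin = float(vals.min())
    if vmin < 0:
        threshold = 2.0 * abs(vmin)
    else:
        positive = vals[vals > 0]
        threshold = 2.0 * float(positive.min()) if positive.size else float("inf")
    selected = [
        name
        for name in sorted(importances, key=importances.get, reverse=True)
        if importances[name] >= threshold and importances[name] > 0
    ]
    return selected, threshold


def screen(
    X: pd.DataFrame, y, config: ForestConfig | None = None
) -> ImportanceResult:
    """Full screen: drop incomplete rows, fit, rank, select.

    Rows (species) with any missing predictor or response are dropped
    and recorded on the result.
    """
    config = config or ForestConfig()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    ok = X.notna().all(axis=1) & y.notna()
    dropped = [str(i) for i in X.index[~ok]]
    Xc, yc = X[ok], y[ok]
    if yc.size < config.min_node_size:
        raise ValueError("too few complete species for the screen")
    forest = fit_forest(Xc, yc, config)
    importances = conditional_importance(forest)
    selected, threshold = select_important(importances)
    return ImportanceResult(
        importances=importances,
        threshold=threshold,
        selected=selected,
        seed=config.seed,
        n_used=int(ok.sum()),
        n_dropped=len(dropped),
        config=config,
        dropped_species=dropped,
    )
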