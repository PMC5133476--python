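"""Regression forests with out-of-bag permutation importance.

The forest is an explicit bagged ensemble of CART regression trees with
per-tree out-of-bag (OOB) bookkeeping, because the importance score that
drives variable selection is computed per tree: for each variable j and
each tree, the OOB mean squared error is recomputed after permuting column
j among that tree's OOB samples, and the variable's raw importance (VIM)
is the tree-averaged percent change in MSE,

    VIM_j = (1/ntree) * sum_t 100 * (MSE_t(perm j) - MSE_t) / MSE_t.

Permuting a variable a tree never splits on cannot change its predictions,
so those trees contribute exactly 0 and are skipped.

Random forests cannot handle missing predictor values; inputs must be
filtered first (see io_qc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "MissingDataError",
    "ForestParams",
    "VimVector",
    "RegressionForest",
    "fit_forest",
    "permutation_vim",
    "tune_parameters",
]


class MissingDataError(ValueError):
    """Predictors or outcome contain missing values."""


@dataclass(frozen=True)
class ForestParams:
    """Forest hyper-parameters.

    ``mtry=None`` resolves at fit time to ``max(1, round(p / 6))``, keeping
    the candidate-variable fraction at roughly one sixth of the inputs at
    desk scale; any explicit value in [1, p] is accepted. ``min_node_size``
    is the minimum samples per leaf (regression default 5).
    """

    ntree: int = 500
    mtry: int | None = None
    seed: int = 0
    min_node_size: int = 5

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, round(p / 6))
        if not 1 <= m <= p:
            raise ValueError(f"mtry must be in [1, {p}], got {m}")
        return m

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass
class VimVector:
    """Raw permutation importances from one forest run.

    One value per input variable (variants and covariates alike), as percent
    change in OOB MSE; ``oob_mse`` is the forest-level out-of-bag error.
    """

    ids: list[str]
    vim: np.ndarray
    oob_mse: float
    seed: int

    def __post_init__(self) -> None:
        self.vim = np.asarray(self.vim, dtype=float)
        if self.vim.shape != (len(self.ids),):
            raise ValueError("one vim per variable required")
        if not np.isfinite(self.vim).all():
            raise ValueError("vims must be finite")
        if self.oob_mse < 0:
            raise ValueError("oob_mse must be non-negative")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"variable_id": self.ids, "vim": self.vim}).to_csv(
            path, sep="\t", index=False)


@dataclass
class RegressionForest:
    trees: list[DecisionTreeRegressor]
    oob_indices: list[np.ndarray]
    params: ForestParams
    X32: np.ndarray           # training matrix, float32 C-order (permutation reuses it)
    oob_mse: float
    ids: list[str]


def _validate_xy(X, y):
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per outcome value")
    if np.isnan(X).any():
        raise MissingDataError(
            "predictors contain missing values; random forests cannot handle "
            "missingness — drop affected variants/samples with io_qc.filter_variants"
            " / io_qc.filter_samples first")
    if np.isnan(y).any():
        raise MissingDataError("outcome contains missing values")
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; nothing to regress")
    return X, y


def fit_forest(X, y, params: ForestParams, ids: list[str] | None = None) -> RegressionForest:
    """Grow ``ntree`` regression trees on bootstrap samples, recording each
    tree's out-of-bag membership. Deterministic given ``params.seed``."""
    X, y = _validate_xy(X, y)
    n, p = X.shape
    mtry = params.resolve_mtry(p)
    if ids is None:
        ids = [f"x{j}" for j in range(p)]
    elif len(ids) != p:
        raise ValueError("ids length must match the number of columns")

    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, 0])
    tree_seeds = rng.integers(0, 2**31 - 1, size=params.ntree)
    all_idx = np.arange(n)
    trees, oobs = [], []
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    for t in range(params.ntree):
        boot = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob = all_idx[~in_bag]
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=params.min_node_size,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[boot], y[boot], check_input=False)
        trees.append(tree)
        oobs.append(oob)
        if oob.size:
            pred = tree.tree_.predict(np.ascontiguousarray(X[oob])).ravel()
            oob_sum[oob] += pred
            oob_cnt[oob] += 1
    covered = oob_cnt > 0
    if not covered.any():
        raise ValueError("no out-of-bag samples; increase ntree")
    oob_mse = float(np.mean((y[covered] - oob_sum[covered] / oob_cnt[covered]) ** 2))
    return RegressionForest(trees, oobs, replace(params, mtry=mtry), X, oob_mse, list(ids))


def _perm_rng(seed: int, tree_index: int, variable_index: int) -> np.random.Generator:
    # independent stream per (run, tree, variable) so importances are
    # reproducible regardless of evaluation order
    return np.random.default_rng([seed & 0x7FFFFFFF, 1, tree_index, variable_index])


def permutation_vim(forest: RegressionForest, X=None, y=None) -> VimVector:
    """Permutation VIM for every input variable of a fitted forest.

    One permutation per variable per tree, drawn from a stream keyed by
    (run seed, tree, variable). A variable that is constant within a tree's
    OOB set, or never used by the tree, contributes 0 for that tree.
    """
    if X is not None:
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.shape != forest.X32.shape or not np.array_equal(X, forest.X32):
            raise ValueError("X does not match the matrix the forest was fitted on")
    X = forest.X32
    if y is None:
        raise ValueError("y (the training outcome) is required")
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    seed = forest.params.seed
    vim = np.zeros(p)
    for t, (tree, oob) in enumerate(zip(forest.trees, forest.oob_indices)):
        if oob.size == 0:
            continue
        Xo = np.ascontiguousarray(X[oob])
        yo = y[oob]
        mse0 = float(np.mean((yo - tree.tree_.predict(Xo).ravel()) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if mse0 == 0.0:
            continue  # perfect OOB fit: percent change undefined, no-op
        for j in used:
            col = Xo[:, j].copy()
            perm = _perm_rng(seed, t, int(j)).permutation(oob.size)
            Xo[:, j] = col[perm]
            mse_p = float(np.mean((yo - tree.tree_.predict(Xo).ravel()) ** 2))
            Xo[:, j] = col
            vim[j] += 100.0 * (mse_p - mse0) / mse0
    vim /= forest.params.ntree
    return VimVector(list(forest.ids), vim, forest.oob_mse, seed)


def tune_parameters(X, y, grid: list[ForestParams]) -> ForestParams:
    """Pick the grid element with the lowest forest OOB MSE; ties broken by
    smaller ntree, then smaller resolved mtry (the cheaper model)."""
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    best = None
    for params in grid:
        f = fit_forest(X, y, params)
        key = (f.oob_mse, params.ntree, f.params.mtry)
        if best is None or key < best[0]:
            best = (key, params)
    return best[1]
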