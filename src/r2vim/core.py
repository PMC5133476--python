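"""Relative recurrency variable importance (r2VIM): the selection method.

Three components turn raw forest importances into a selection rule:

1. *Raw importance.* Each forest run yields a permutation VIM per variable
   (percent change in OOB MSE; see forest module).

2. *Null-variance estimate.* Under the global null the VIMs scatter
   symmetrically around zero, so the absolute value of the lowest
   (usually negative) VIM estimates the spread of null importances. A run's
   relative importance score is RIS = VIM / |min VIM|, which puts runs on a
   common scale with minimum -1; multiplying the estimate by integer factors
   gives progressively stricter thresholds, and on the RIS scale the
   factor-f threshold is simply RIS > f.

3. *Recurrency.* Forests are stochastic: a noise variable may score high in
   one run. The forest is run several times (5-10 by convention) with
   different seeds and per-variable RIS values are combined by taking the
   minimum over runs ("recurrency-corrected" min.RIS), so a variable is
   selected only if it clears the threshold in every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .forest import ForestParams, VimVector, fit_forest, permutation_vim
from .simdata import GenotypeMatrix, PhenotypeTable

__all__ = [
    "DegenerateNullError",
    "RISMatrix",
    "SelectionResult",
    "null_variance_estimate",
    "factor_thresholds",
    "relative_importance",
    "make_forest_inputs",
    "run_r2vim",
    "select_variants",
]


class DegenerateNullError(ValueError):
    """The run's minimum VIM does not provide a usable null-variance estimate."""


def _vims(vim) -> np.ndarray:
    v = vim.vim if isinstance(vim, VimVector) else np.asarray(vim, dtype=float)
    if v.size == 0:
        raise ValueError("empty VIM vector")
    return v


def null_variance_estimate(vim) -> float:
    """Absolute value of the lowest VIM.

    E.g. a run whose lowest VIM is -0.05 has null-variance estimate 0.05.
    An exactly-zero minimum admits no estimate and raises; an all-positive
    vector (no negative importance observed, contrary to the usual case)
    returns the positive minimum with a warning.
    """
    v = _vims(vim)
    m = float(v.min())
    if m == 0.0:
        raise DegenerateNullError("minimum VIM is exactly 0; no null-variance estimate")
    if m > 0.0:
        warnings.warn(
            f"no negative VIM observed; using the smallest positive VIM ({m:g}) "
            "as the null-variance estimate", stacklevel=2)
        return m
    return abs(m)


def factor_thresholds(estimate: float, factors) -> list[float]:
    """Multiply the null-variance estimate by each factor (e.g. estimate 0.05
    with factors 2, 3, 4 gives thresholds 0.10, 0.15, 0.20)."""
    if not estimate > 0:
        raise ValueError("null-variance estimate must be positive")
    factors = list(factors)
    if any(f <= 0 for f in factors):
        raise ValueError("threshold factors must be positive")
    return [estimate * f for f in factors]


def relative_importance(vim) -> np.ndarray:
    """RIS = VIM / |min VIM|; scale-free, and the run's minimum RIS is -1
    whenever the minimum VIM is negative."""
    v = _vims(vim)
    return v / null_variance_estimate(v)


@dataclass
class RISMatrix:
    """Per-variable RIS across runs plus the recurrency-corrected minimum.

    ``variant_mask`` marks which variables are genetic variants (covariates
    take part in per-run normalisation but are never selected).
    """

    ids: list[str]
    ris: np.ndarray            # variables x runs
    run_seeds: list[int]
    variant_mask: np.ndarray

    def __post_init__(self) -> None:
        self.ris = np.asarray(self.ris, dtype=float)
        if self.ris.shape != (len(self.ids), len(self.run_seeds)):
            raise ValueError("ris must be variables x runs")
        self.variant_mask = np.asarray(self.variant_mask, dtype=bool)

    @property
    def n_runs(self) -> int:
        return len(self.run_seeds)

    @property
    def min_ris(self) -> np.ndarray:
        return self.ris.min(axis=1)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.ris, index=pd.Index(self.ids, name="variable_id"),
                          columns=[f"ris_run{i + 1}" for i in range(self.n_runs)])
        df["min_ris"] = self.min_ris
        df.to_csv(path, sep="\t")


@dataclass
class SelectionResult:
    """Variants exceeding a threshold, with truth-annotation counts."""

    threshold: float
    selected: set[str]
    counts: dict[str, int]
    n_universe: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.counts.get("all", len(self.selected)) != len(self.selected):
            raise ValueError("counts['all'] must equal the selection size")

    def to_json_dict(self) -> dict:
        return {"threshold": self.threshold, "label": self.label,
                "selected": sorted(self.selected), "counts": self.counts,
                "n_universe": self.n_universe}


def make_forest_inputs(genotypes: GenotypeMatrix, phenotype: PhenotypeTable,
                       covariate_names=("sex", "medication", "smoking")):
    """Assemble (X, y, ids, variant_mask) for the forest: dosages plus the
    requested covariate columns as ordinary input variables.

    A covariate with missing values cannot enter the forest and is dropped
    with a warning (the typical case being age); the regression baseline can
    still use it.
    """
    if list(genotypes.samples) != list(phenotype.samples):
        raise ValueError("genotype and phenotype sample order differ")
    cov_cols = []
    for name in covariate_names:
        col = phenotype.covariates[name]
        if col.isna().any():
            warnings.warn(f"covariate {name!r} has missing values and is excluded "
                          "from the forest inputs", stacklevel=2)
            continue
        cov_cols.append(name)
    X = np.column_stack([genotypes.dosages] +
                        [phenotype.covariates[c].to_numpy(dtype=np.float32)
                         for c in cov_cols]) if cov_cols else genotypes.dosages
    ids = list(genotypes.variants) + cov_cols
    mask = np.zeros(len(ids), dtype=bool)
    mask[: genotypes.n_variants] = True
    return np.ascontiguousarray(X, dtype=np.float32), phenotype.outcome, ids, mask


def run_r2vim(X, y, covariates: pd.DataFrame | None = None,
              params: ForestParams | None = None, n_runs: int = 5,
              base_seed: int = 0, allow_positive_null: bool = False,
              variable_ids: list[str] | None = None,
              variant_mask: np.ndarray | None = None) -> RISMatrix:
    """Run the forest ``n_runs`` times (seeds ``base_seed + 0..n_runs-1``),
    convert each run's VIMs to RIS, and record the per-variable minimum.

    Covariate columns, if given, are appended to X and participate in
    normalisation but are flagged non-variant. A run with no negative VIM is
    a degenerate null and raises, naming the offending seed, unless
    ``allow_positive_null`` permits falling back to the smallest positive VIM.
    """
    params = params or ForestParams()
    if not 5 <= n_runs <= 10:
        warnings.warn(f"n_runs={n_runs} is outside the conventional 5-10 range",
                      stacklevel=2)
    if isinstance(X, pd.DataFrame):
        variable_ids = variable_ids or list(X.columns)
        X = X.to_numpy(dtype=np.float32)
    X = np.asarray(X, dtype=np.float32)
    n_variants = X.shape[1]
    if covariates is not None:
        X = np.column_stack([X, covariates.to_numpy(dtype=np.float32)])
        cov_ids = list(covariates.columns)
    else:
        cov_ids = []
    p = X.shape[1]
    if variable_ids is None:
        variable_ids = [f"v{j + 1}" for j in range(n_variants)]
    ids = list(variable_ids) + cov_ids
    if len(ids) != p:
        raise ValueError("variable id count does not match input columns")
    if variant_mask is None:
        variant_mask = np.zeros(p, dtype=bool)
        variant_mask[:n_variants] = True

    ris = np.empty((p, n_runs))
    seeds = [int(base_seed) + r for r in range(n_runs)]
    for r, seed in enumerate(seeds):
        forest = fit_forest(X, y, replace(params, seed=seed), ids=ids)
        vv = permutation_vim(forest, y=y)
        if vv.vim.min() >= 0 and not allow_positive_null:
            raise DegenerateNullError(
                f"run with seed {seed} produced no negative VIM; "
                "pass allow_positive_null=True to use the smallest positive VIM")
        ris[:, r] = relative_importance(vv)
    return RISMatrix(ids, ris, seeds, variant_mask)


def select_variants(ris_matrix: RISMatrix, threshold: float,
                    truth: dict[str, str] | None = None,
                    label: str = "") -> SelectionResult:
    """Variants (never covariates) with min.RIS strictly greater than
    *threshold*, with counts against the truth classes when available.

    Selections are nested: a higher threshold selects a subset.
    """
    if not np.isfinite(threshold) and threshold != -np.inf:
        raise ValueError("threshold must be finite (or -inf for 'select all')")
    min_ris = ris_matrix.min_ris
    sel = {vid for vid, m, is_var in zip(ris_matrix.ids, min_ris, ris_matrix.variant_mask)
           if is_var and m > threshold}
    counts = {"all": len(sel)}
    if truth is not None:
        counts["functional"] = sum(truth.get(v) == "functional" for v in sel)
        counts["functional_gene"] = sum(truth.get(v) == "functional_gene" for v in sel)
    return SelectionResult(threshold, sel, counts,
                           n_universe=int(ris_matrix.variant_mask.sum()),
                           label=label or f"min.RIS > {threshold:g}")
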