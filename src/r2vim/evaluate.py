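"""Evaluation harness: count tables, score concordance and the null analysis.

On synthetic data with a known truth annotation this reproduces the study
design used to benchmark the method: a count table per method x threshold
(total selected / directly functional / in a functional gene), the rank
concordance between min.RIS and -log10(p) from the regression scan, and a
permuted-phenotype run in which every selection is by construction a false
positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (RISMatrix, SelectionResult, make_forest_inputs, run_r2vim,
                   select_variants)
from .forest import ForestParams
from .simdata import GenotypeMatrix, PhenotypeTable, permute_phenotype

__all__ = [
    "build_comparison",
    "concordance",
    "null_analysis",
    "plot_scores",
    "plot_concordance",
]


def build_comparison(r2vim_selections: list[SelectionResult],
                     linreg_selections: list[SelectionResult]) -> pd.DataFrame:
    """One row per method x threshold with selection counts by truth class."""
    rows = []
    universes = set()
    for method, sels in (("r2VIM", r2vim_selections), ("linear_regression", linreg_selections)):
        for s in sels:
            universes.add(s.n_universe)
            rows.append({
                "method": method,
                "threshold": s.label or f"{s.threshold:g}",
                "n_selected": s.counts["all"],
                "n_functional": s.counts.get("functional", 0),
                "n_functional_gene": s.counts.get("functional_gene", 0),
            })
    if len(universes) > 1:
        raise ValueError(f"selections come from different variant universes: {sorted(universes)}")
    return pd.DataFrame(rows, columns=["method", "threshold", "n_selected",
                                       "n_functional", "n_functional_gene"])


def concordance(ris_matrix: RISMatrix, scan_result) -> tuple[float, pd.DataFrame, int]:
    """Spearman correlation between min.RIS and -log10(p) on the shared
    variant set; variants with undefined p are excluded pairwise.

    Returns (rho, paired per-variant table, number excluded).
    """
    min_ris = pd.Series(ris_matrix.min_ris, index=ris_matrix.ids)[ris_matrix.variant_mask]
    tab = scan_result.table.set_index("variant_id")
    shared = [v for v in min_ris.index if v in tab.index]
    if not shared:
        raise ValueError("no shared variants between the RIS matrix and the scan")
    df = pd.DataFrame({
        "min_ris": min_ris.loc[shared],
        "neglog10_p": -np.log10(tab.loc[shared, "p"]),
    })
    n_excluded = int(df["neglog10_p"].isna().sum())
    paired = df.dropna()
    rho = float(stats.spearmanr(paired["min_ris"], paired["neglog10_p"]).statistic)
    return rho, paired, n_excluded


def null_analysis(genotypes: GenotypeMatrix, phenotype: PhenotypeTable,
                  params: ForestParams | None = None, n_runs: int = 5,
                  seed: int = 0, thresholds=(0.0, 0.5, 1.0),
                  covariate_names=("sex", "medication", "smoking"),
                  truth: dict[str, str] | None = None,
                  ) -> tuple[RISMatrix, dict[float, SelectionResult]]:
    """Permute the phenotype and run the full pipeline; any variant selected
    at any threshold is a false positive by construction."""
    permuted = permute_phenotype(phenotype, seed)
    X, y, ids, mask = make_forest_inputs(genotypes, permuted, covariate_names)
    ris = run_r2vim(X, y, params=params, n_runs=n_runs, base_seed=seed,
                    variable_ids=ids, variant_mask=mask)
    selections = {t: select_variants(ris, t, truth=truth) for t in thresholds}
    return ris, selections


# ---------------------------------------------------------------------------
# plots (cosmetic; properties untested)


def plot_scores(scores: np.ndarray, highlight: np.ndarray | None = None,
                ylabel: str = "min.RIS", ax=None):
    """Manhattan-style plot of a per-variant score against variant index;
    ``highlight`` marks e.g. the functional variants in red."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    idx = np.arange(len(scores))
    ax.scatter(idx, scores, s=4, c="black")
    if highlight is not None:
        ax.scatter(idx[highlight], np.asarray(scores)[highlight], s=8, c="red")
    ax.set_xlabel("variant index")
    ax.set_ylabel(ylabel)
    return ax


def plot_concordance(paired: pd.DataFrame, highlight: np.ndarray | None = None, ax=None):
    """min.RIS (y) against -log10(p) (x) per variant."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(paired["neglog10_p"], paired["min_ris"], s=4, c="black")
    if highlight is not None:
        sub = paired[highlight]
        ax.scatter(sub["neglog10_p"], sub["min_ris"], s=8, c="red")
    ax.set_xlabel(r"$-\log_{10}(p)$")
    ax.set_ylabel("min.RIS")
    return ax
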