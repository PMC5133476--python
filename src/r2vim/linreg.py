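"""Single-variant linear-regression scan with covariate adjustment.

The comparison baseline: for each variant, ordinary least squares of the
outcome on allele dosage (additive 0/1/2 coding) plus covariates, with the
two-sided t-test p-value for the dosage term. Selection is either
Bonferroni (p < alpha / m over the m variants with a defined p-value) or a
fixed absolute p-value threshold.

Covariates may have missing rows (age, typically); these samples are
dropped (complete-case analysis) and the per-variant sample count is
reported. The fit residualises outcome and dosages against the covariate
block once (Frisch-Waugh-Lovell), which is algebraically identical to the
full OLS fit but runs in one vectorised pass over variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SelectionResult
from .simdata import GenotypeMatrix, PhenotypeTable

__all__ = ["ScanResult", "scan", "bonferroni_select"]


@dataclass
class ScanResult:
    """Per-variant OLS results: beta (per alt allele), se, two-sided p, n_used.

    Variants whose dosage is constant or collinear with the covariates get
    NaN beta/se/p (an explicit undefined marker, never silently dropped).
    """

    table: pd.DataFrame  # columns: variant_id, beta, se, p, n_used

    def __post_init__(self) -> None:
        required = {"variant_id", "beta", "se", "p", "n_used"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"scan table must have columns {sorted(required)}")
        p = self.table["p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def n_defined(self) -> int:
        return int(self.table["p"].notna().sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def scan(genotypes: GenotypeMatrix, phenotype: PhenotypeTable,
         covariate_names: list[str] | None = None) -> ScanResult:
    """OLS of outcome on dosage + covariates, one model per variant."""
    if list(genotypes.samples) != list(phenotype.samples):
        raise ValueError("genotype and phenotype sample order differ")
    if genotypes.has_missing():
        raise ValueError("genotypes contain missing dosages; run io_qc.filter_variants first")
    covariate_names = list(covariate_names or [])
    cov = phenotype.covariates[covariate_names] if covariate_names else \
        pd.DataFrame(index=phenotype.covariates.index)

    y_all = phenotype.outcome
    mask = np.isfinite(y_all)
    if covariate_names:
        mask &= cov.notna().all(axis=1).to_numpy()
    n_used = int(mask.sum())
    k_cov = 1 + len(covariate_names)  # intercept + covariates
    if n_used <= k_cov + 1:
        raise ValueError("too few complete cases for the model")

    Z = np.column_stack([np.ones(n_used)] +
                        [cov[c].to_numpy(dtype=float)[mask] for c in covariate_names])
    y = y_all[mask]
    X = genotypes.dosages[mask].astype(np.float64)

    # project out the covariate block from outcome and every dosage column
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)

    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    syy = float(y_r @ y_r)
    # degenerate: dosage constant or collinear with covariates
    scale = np.maximum(np.einsum("ij,ij->j", X, X), 1.0)
    defined = sxx > 1e-10 * scale
    df = n_used - k_cov - 1

    beta = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    pval = np.full(genotypes.n_variants, np.nan)
    b = sxy[defined] / sxx[defined]
    rss = syy - b * sxy[defined]
    rss = np.maximum(rss, 0.0)
    s2 = rss / df
    beta[defined] = b
    se[defined] = np.sqrt(s2 / sxx[defined])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[defined] / se[defined]
    pval[defined] = 2.0 * stats.t.sf(np.abs(tstat), df)

    table = pd.DataFrame({
        "variant_id": genotypes.variants,
        "beta": beta,
        "se": se,
        "p": pval,
        "n_used": n_used,
    })
    return ScanResult(table)


def bonferroni_select(scan_result: ScanResult, alpha: float = 0.05,
                      fixed_threshold: float | None = None,
                      truth: dict[str, str] | None = None,
                      label: str = "") -> SelectionResult:
    """Select variants by p-value.

    Default is Bonferroni: p < alpha / m with m the number of variants with a
    defined p-value. ``fixed_threshold`` switches to an absolute cutoff
    (p < fixed_threshold), e.g. a genome-wide constant such as 5e-7, and
    ``fixed_threshold=alpha`` gives the uncorrected nominal rule.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    tab = scan_result.table
    m = scan_result.n_defined()
    if fixed_threshold is not None:
        cutoff = float(fixed_threshold)
        default_label = f"p < {cutoff:g}"
    else:
        if m == 0:
            raise ValueError("no variant has a defined p-value")
        cutoff = alpha / m
        default_label = f"p < {alpha:g}/{m} (Bonferroni)"
    hit = tab["p"].notna() & (tab["p"] < cutoff)
    sel = set(tab.loc[hit, "variant_id"])
    counts = {"all": len(sel)}
    if truth is not None:
        counts["functional"] = sum(truth.get(v) == "functional" for v in sel)
        counts["functional_gene"] = sum(truth.get(v) == "functional_gene" for v in sel)
    return SelectionResult(cutoff, sel, counts, n_universe=len(tab),
                           label=label or default_label)
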