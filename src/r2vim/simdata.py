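"""Synthetic genotype/phenotype data with known functional variants.

Emulates the structure of an exome-style association study: a samples x
variants dosage matrix (0/1/2 alternative-allele counts), variants grouped
into genes, a designated subset of *functional* variants with additive
effects on a continuous blood-pressure-like outcome, binary and continuous
covariates, and a permuted null phenotype for false-positive calibration.

The generating model is additive with Gaussian noise:

    y_i = intercept + sum_v beta_v * dosage_iv + sum_c gamma_c * z_ic + e_i

with e_i ~ N(0, noise_sd^2). Effect sizes and minor-allele frequencies are
free parameters so that power can be varied across the realistic range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimConfig",
    "with_functional",
    "GenotypeMatrix",
    "PhenotypeTable",
    "simulate_genotypes",
    "simulate_phenotype",
    "permute_phenotype",
    "truth_annotation",
    "write_dataset",
]

PHENOTYPE_INTERCEPT = 120.0  # SBP-like baseline, mmHg


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_samples, n_variants
        Matrix dimensions.
    maf_range
        Per-variant minor-allele frequencies are drawn uniformly from this
        closed interval; both ends must lie in (0, 0.5].
    n_genes
        Number of contiguous gene blocks. Defaults to ``ceil(n_variants / 5)``
        (exome-like blocks of ~5 variants).
    functional_variant_ids
        Variants with a direct additive effect on the outcome.
    effect_sizes
        Map variant id -> effect in phenotype units per alternative allele.
        Must cover exactly the functional variants.
    covariate_effects
        Map covariate name -> effect. Recognised names: ``sex``,
        ``medication``, ``smoking`` (binary), ``age`` (continuous, with
        missingness), and ``pc1``, ``pc2``, ... (standard-normal scores).
    noise_sd
        Residual standard deviation, must be > 0.
    ld_rho
        Optional within-gene genotype correlation (Gaussian-copula allele
        model). 0 = independent variants (default).
    genotype_missing_rate
        Fraction of dosages set missing, to exercise QC filters. Default 0.
    age_missing_rate
        Fraction of ages set missing (the covariate the forest cannot use).
    """

    n_samples: int
    n_variants: int
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_genes: int | None = None
    functional_variant_ids: tuple[str, ...] = ()
    effect_sizes: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    ld_rho: float = 0.0
    genotype_missing_rate: float = 0.0
    age_missing_rate: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_samples < 1 or self.n_variants < 1:
            raise ConfigError("n_samples and n_variants must be positive")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be strictly positive (zero noise is forbidden)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0, 1)")
        ids = set(self.variant_ids())
        missing = [v for v in self.functional_variant_ids if v not in ids]
        if missing:
            raise ConfigError(f"functional variants not among the simulated variants: {missing[:5]}")
        if set(self.effect_sizes) != set(self.functional_variant_ids):
            raise ConfigError("effect_sizes keys must match functional_variant_ids exactly")

    def variant_ids(self) -> list[str]:
        return [f"v{i + 1}" for i in range(self.n_variants)]

    def sample_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]

    def gene_count(self) -> int:
        if self.n_genes is not None:
            if not 1 <= self.n_genes <= self.n_variants:
                raise ConfigError("n_genes must be in [1, n_variants]")
            return self.n_genes
        return -(-self.n_variants // 5)


def with_functional(config: SimConfig, index_to_effect: dict[int, float]) -> SimConfig:
    """Return a copy of *config* with functional variants given by 0-based index."""
    ids = config.variant_ids()
    effects = {ids[i]: e for i, e in index_to_effect.items()}
    return replace(
        config,
        functional_variant_ids=tuple(effects),
        effect_sizes=effects,
    )


@dataclass
class GenotypeMatrix:
    """Samples x variants alternative-allele dosages.

    ``dosages`` is float32 with entries in {0, 1, 2} or NaN for missing.
    Every variant belongs to exactly one gene.
    """

    samples: list[str]
    variants: list[str]
    genes: dict[str, str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        n, p = self.dosages.shape
        if n != len(self.samples) or p != len(self.variants):
            raise ValueError("dosage shape does not match sample/variant identifiers")
        if len(set(self.samples)) != n or len(set(self.variants)) != p:
            raise ValueError("sample and variant identifiers must be unique")
        if set(self.genes) != set(self.variants):
            raise ValueError("every variant must map to exactly one gene")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.variants)


@dataclass
class PhenotypeTable:
    """Continuous outcome plus covariate columns, sample order matching the genotypes."""

    samples: list[str]
    outcome: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.outcome.shape != (len(self.samples),):
            raise ValueError("outcome must have one value per sample")
        if list(self.covariates.index) != list(self.samples):
            self.covariates = self.covariates.set_axis(self.samples, axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.samples, "outcome": self.outcome})
        df = df.set_index("sample_id")
        out = pd.concat([df, self.covariates], axis=1)
        out.index.name = "sample_id"
        return out


# ---------------------------------------------------------------------------
# generation


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw dosages binomially (2 trials) at per-variant MAFs from ``maf_range``.

    Variants are partitioned into contiguous gene blocks. With ``ld_rho > 0``
    allele draws within a gene share a latent Gaussian factor, inducing
    positive dosage correlation within blocks.
    """
    rng = _rng(config, 0)
    n, p = config.n_samples, config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)

    n_genes = config.gene_count()
    gene_of = np.minimum(np.arange(p) * n_genes // p, n_genes - 1)

    if config.ld_rho == 0.0:
        dos = rng.binomial(2, mafs[None, :], size=(n, p)).astype(np.float32)
    else:
        # Gaussian copula: each of the 2 allele draws for variant v in gene g
        # is 1{z < Phi^-1(maf_v)} with z sharing a per-gene factor.
        from scipy.stats import norm

        thr = norm.ppf(mafs)
        rho = config.ld_rho
        dos = np.zeros((n, p), dtype=np.float32)
        for allele in range(2):
            factors = rng.standard_normal((n, n_genes))
            noise = rng.standard_normal((n, p))
            z = np.sqrt(rho) * factors[:, gene_of] + np.sqrt(1 - rho) * noise
            dos += (z < thr[None, :]).astype(np.float32)

    if config.genotype_missing_rate > 0:
        miss = rng.random((n, p)) < config.genotype_missing_rate
        dos[miss] = np.nan

    genes = {f"v{i + 1}": f"g{gene_of[i] + 1}" for i in range(p)}
    return GenotypeMatrix(config.sample_ids(), config.variant_ids(), genes, dos)


def _simulate_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    cols: dict[str, np.ndarray] = {
        "sex": rng.binomial(1, 0.5, n).astype(float),
        "medication": rng.binomial(1, 0.3, n).astype(float),
        "smoking": rng.binomial(1, 0.25, n).astype(float),
        "age": rng.normal(55.0, 10.0, n),
    }
    for name in config.covariate_effects:
        if name.startswith("pc") and name not in cols:
            cols[name] = rng.standard_normal(n)
        elif name not in cols:
            raise ConfigError(f"unrecognised covariate name: {name!r}")
    return pd.DataFrame(cols, index=config.sample_ids())


def simulate_phenotype(genotypes: GenotypeMatrix, config: SimConfig) -> PhenotypeTable:
    """Additive phenotype: genetic effects + covariate effects + Gaussian noise.

    Ages are drawn for everyone (and enter the outcome if an age effect is
    configured) but a fraction ``age_missing_rate`` is then masked, so that
    downstream methods must handle a covariate with missing values.
    """
    if list(genotypes.variants) != config.variant_ids() or genotypes.n_samples != config.n_samples:
        raise ConfigError("genotypes were not generated from this configuration")
    rng = _rng(config, 1)
    cov = _simulate_covariates(config, rng)

    y = np.full(config.n_samples, PHENOTYPE_INTERCEPT)
    col_of = {v: j for j, v in enumerate(genotypes.variants)}
    for vid in config.functional_variant_ids:
        d = np.nan_to_num(genotypes.dosages[:, col_of[vid]], nan=0.0)
        y = y + config.effect_sizes[vid] * d.astype(float)
    for name, gamma in config.covariate_effects.items():
        y = y + gamma * cov[name].to_numpy()
    y = y + rng.normal(0.0, config.noise_sd, config.n_samples)

    if config.age_missing_rate > 0:
        miss = rng.random(config.n_samples) < config.age_missing_rate
        cov.loc[miss, "age"] = np.nan

    return PhenotypeTable(list(genotypes.samples), y, cov)


def permute_phenotype(phenotype: PhenotypeTable, seed: int) -> PhenotypeTable:
    """Uniformly permute the outcome across samples, leaving covariates untouched.

    The permuted trait retains the outcome's marginal distribution but is,
    by construction, unassociated with every variant — the negative control
    for false-positive calibration.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(phenotype.samples))
    return PhenotypeTable(
        list(phenotype.samples),
        phenotype.outcome[perm],
        phenotype.covariates.copy(),
    )


def truth_annotation(config: SimConfig, genotypes: GenotypeMatrix) -> dict[str, str]:
    """Classify each variant: ``functional`` (direct effect), ``functional_gene``
    (same gene as a functional variant, no direct effect), or ``neither``.

    The three classes partition the variant set.
    """
    if set(genotypes.variants) != set(config.variant_ids()):
        raise ConfigError("genotypes do not match configuration")
    functional = set(config.functional_variant_ids)
    hot_genes = {genotypes.genes[v] for v in functional}
    out = {}
    for v in genotypes.variants:
        if v in functional:
            out[v] = "functional"
        elif genotypes.genes[v] in hot_genes:
            out[v] = "functional_gene"
        else:
            out[v] = "neither"
    return out


def write_dataset(genotypes: GenotypeMatrix, phenotype: PhenotypeTable,
                  config: SimConfig, outdir) -> dict[str, str]:
    """Write PLINK bed/bim/fam, phenotype TSV and a truth JSON under *outdir*.

    Returns a map of artifact name -> path.
    """
    import json
    from pathlib import Path

    from . import io_qc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = outdir / "genotypes"
    io_qc.write_plink(genotypes, prefix)
    pheno_path = outdir / "phenotype.tsv"
    io_qc.write_phenotype_tsv(phenotype, pheno_path)
    truth = truth_annotation(config, genotypes)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(
        {v: {"class": truth[v], "effect": config.effect_sizes.get(v, 0.0),
             "gene": genotypes.genes[v]} for v in genotypes.variants},
        indent=None))
    return {"plink_prefix": str(prefix), "phenotype": str(pheno_path), "truth": str(truth_path)}
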