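"""File I/O and quality control for genotype/phenotype data.

Reads and writes PLINK binary (bed/bim/fam, SNP-major 2-bit encoding) and a
plain TSV dialect (samples as rows, variant ids as header, values 0/1/2/NA),
applies variant- and sample-level missingness filters, and computes
principal-component covariates for population structure.

The bed codec maps 2-bit genotype codes to alternative-allele dosages with
A1 taken as the alternative allele: 00 -> 2, 10 -> 1, 11 -> 0, 01 -> missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, PhenotypeTable

__all__ = [
    "FormatError",
    "QCReport",
    "read_genotypes",
    "write_plink",
    "write_genotype_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "filter_variants",
    "filter_samples",
    "run_qc",
    "compute_pcs",
]

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"
# 2-bit code -> dosage (NaN = missing); index is the code value
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)


class FormatError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


@dataclass
class QCReport:
    """Bookkeeping for one QC pass; counts reconcile exactly with shape changes."""

    n_variants_in: int = 0
    n_singletons_removed: int = 0
    n_missing_variants_removed: int = 0
    n_samples_in: int = 0
    n_samples_removed: int = 0
    sample_missingness: dict[str, float] = field(default_factory=dict)

    @property
    def n_variants_out(self) -> int:
        return self.n_variants_in - self.n_singletons_removed - self.n_missing_variants_removed

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "n_variants_in": self.n_variants_in,
            "n_singletons_removed": self.n_singletons_removed,
            "n_missing_variants_removed": self.n_missing_variants_removed,
            "n_variants_out": self.n_variants_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_removed": self.n_samples_removed,
            "sample_missingness": self.sample_missingness,
        }, indent=2))


# ---------------------------------------------------------------------------
# PLINK binary


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write bed/bim/fam. Bed is SNP-major; bim uses chromosome 1 with
    positions equal to the variant index and A1='A' (alternative), A2='G'."""
    prefix = Path(prefix)
    n, p = genotypes.n_samples, genotypes.n_variants
    dos = genotypes.dosages
    # dosage -> 2-bit code
    codes = np.full((p, n), 0b01, dtype=np.uint8)  # missing by default
    d = dos.T
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (padded[:, 0::4]
              | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4)
              | (padded[:, 3::4] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for i, v in enumerate(genotypes.variants):
            fh.write(f"1\t{v}\t0\t{i + 1}\tA\tG\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in genotypes.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


def _read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FormatError(f"missing PLINK file: {f}")
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None,
                         names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None,
                         names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    variants = bim_df["id"].tolist()
    samples = fam_df["iid"].tolist()
    n, p = len(samples), len(variants)

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes at offset 0: {raw[:2]!r}")
    if raw[2:3] != _SNP_MAJOR:
        raise FormatError(f"{bed}: unsupported mode byte at offset 2: {raw[2:3]!r}")
    n_bytes = (n + 3) // 4
    expected = 3 + n_bytes * p
    if len(raw) != expected:
        raise FormatError(
            f"{bed}: size {len(raw)} does not match bim/fam dimensions "
            f"({p} variants x {n} samples -> expected {expected} bytes)")
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, n_bytes)
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    dos = _CODE_TO_DOSAGE[codes[:, :n]].T
    genes = {v: v for v in variants}  # no gene annotation in bim; one gene per variant
    return GenotypeMatrix(samples, variants, genes, dos)


# ---------------------------------------------------------------------------
# TSV dialects


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def _read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    genes = {v: v for v in df.columns}
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns), genes,
                          df.to_numpy(dtype=np.float32))


def read_genotypes(path, format: str = "plink_bed",
                   genes: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read genotypes from ``plink_bed`` (path = prefix) or ``tsv``.

    Dosages are alternative-allele counts with NaN as the missing marker.
    When no gene annotation is supplied each variant forms its own gene.
    """
    if format == "plink_bed":
        gm = _read_plink(path)
    elif format == "tsv":
        gm = _read_genotype_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if genes is not None:
        gm = GenotypeMatrix(gm.samples, gm.variants, dict(genes), gm.dosages)
    return gm


def write_phenotype_tsv(phenotype: PhenotypeTable, path) -> None:
    phenotype.to_dataframe().to_csv(path, sep="\t", na_rep="NA")


def read_phenotype_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    if "outcome" not in df.columns:
        raise FormatError(f"{path}: phenotype TSV must have an 'outcome' column")
    return PhenotypeTable(list(df.index.astype(str)), df["outcome"].to_numpy(),
                          df.drop(columns="outcome"))


# ---------------------------------------------------------------------------
# filters


def filter_variants(genotypes: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Drop singletons (minor-allele count exactly 1) and any variant with at
    least one missing dosage. Survivor order is preserved; idempotent."""
    dos = genotypes.dosages
    n_in = genotypes.n_variants
    has_missing = np.isnan(dos).any(axis=0)
    alt = np.nansum(dos, axis=0)
    n_called = (~np.isnan(dos)).sum(axis=0)
    mac = np.minimum(alt, 2 * n_called - alt)
    singleton = (mac == 1) & ~has_missing
    keep = ~(has_missing | singleton)
    idx = np.flatnonzero(keep)
    variants = [genotypes.variants[i] for i in idx]
    out = GenotypeMatrix(list(genotypes.samples), variants,
                         {v: genotypes.genes[v] for v in variants}, dos[:, idx])
    report = QCReport(
        n_variants_in=n_in,
        n_singletons_removed=int(singleton.sum()),
        n_missing_variants_removed=int(has_missing.sum()),
        n_samples_in=genotypes.n_samples,
    )
    return out, report


def filter_samples(genotypes: GenotypeMatrix,
                   max_missing: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose fraction of missing dosages strictly exceeds
    *max_missing* (a sample at exactly the threshold is retained)."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    rates = np.isnan(genotypes.dosages).mean(axis=1)
    keep = rates <= max_missing
    if not keep.any():
        raise ValueError("all samples exceed the missingness threshold")
    idx = np.flatnonzero(keep)
    out = GenotypeMatrix([genotypes.samples[i] for i in idx], list(genotypes.variants),
                         dict(genotypes.genes), genotypes.dosages[idx])
    report = QCReport(
        n_variants_in=genotypes.n_variants,
        n_samples_in=genotypes.n_samples,
        n_samples_removed=int((~keep).sum()),
        sample_missingness={s: float(r) for s, r in zip(genotypes.samples, rates)},
    )
    return out, report


def run_qc(genotypes: GenotypeMatrix,
           max_missing: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Samples-then-variants QC: drop high-missingness samples first, then
    singletons and variants with residual missingness."""
    gm, srep = filter_samples(genotypes, max_missing)
    gm, vrep = filter_variants(gm)
    vrep.n_samples_in = srep.n_samples_in
    vrep.n_samples_removed = srep.n_samples_removed
    vrep.sample_missingness = srep.sample_missingness
    return gm, vrep


# ---------------------------------------------------------------------------
# principal components


def compute_pcs(genotypes: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-*k* principal-component scores of the column-standardised dosage
    matrix, as covariate columns ``pc1..pck`` indexed by sample.

    Requires a missingness-free matrix (run the filters first). Components are
    ordered by decreasing explained variance; each component's sign is fixed
    so its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    if genotypes.has_missing():
        raise ValueError("compute_pcs requires missingness-free dosages; run filter_variants first")
    n, p = genotypes.n_samples, genotypes.n_variants
    if not 0 <= k <= min(n, p):
        raise ValueError(f"k must be in [0, min(n_samples, n_variants)] = [0, {min(n, p)}]")
    if k == 0:
        return pd.DataFrame(index=genotypes.samples)
    X = genotypes.dosages.astype(np.float64)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic columns contribute nothing
    X = X / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    return pd.DataFrame(scores, index=genotypes.samples,
                        columns=[f"pc{i + 1}" for i in range(k)])
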