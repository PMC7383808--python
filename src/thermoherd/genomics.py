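"""SNP quality control, the genomic relationship matrix G, and the single-step
combined relationship inverse H^-1.

G follows VanRaden's first method with observed allele frequencies,
``G_raw = M M' / (2 Σ p_j (1 - p_j))`` where ``M`` is the centered allele-count
matrix, blended with the pedigree block A22 (``G = α G_raw + (1-α) A22``) to
guarantee invertibility.  H^-1 copies A^-1 and adds ``G^-1 - A22^-1`` into the
genotyped block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "GMatrixConfig",
    "QCReport",
    "qc_filter",
    "allele_frequencies",
    "centered_genotypes",
    "g_matrix",
    "h_inverse",
    "read_genotype_tsv",
    "read_plink",
]

SEX_CHROMS = {"X", "Y", "x", "y", "30", "31"}


@dataclass
class GenotypeData:
    """Genotypes as allele counts plus a SNP map.

    ``codes`` is an animals × SNPs float matrix of {0, 1, 2, nan} counts of
    one allele; ``snp_map`` has columns snp_id, chrom, pos_bp.
    """

    animals: list
    codes: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.animals), len(self.snp_map)):
            raise ValueError("codes dimensions do not match animals x snp_map")
        if (self.snp_map["pos_bp"] < 0).any():
            raise ValueError("SNP positions must be non-negative")

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            animals=self.animals,
            codes=self.codes[:, mask],
            snp_map=self.snp_map.loc[mask].reset_index(drop=True),
        )

    def subset_animals(self, animals) -> "GenotypeData":
        pos = {a: i for i, a in enumerate(self.animals)}
        idx = [pos[a] for a in animals]
        return GenotypeData(animals=list(animals), codes=self.codes[idx], snp_map=self.snp_map)


@dataclass(frozen=True)
class GMatrixConfig:
    """G-matrix construction settings.

    ``blend_alpha`` is the weight on raw G in the blend with A22;
    ``allele_freq_source`` selects observed frequencies or a supplied vector.
    """

    blend_alpha: float = 0.95
    allele_freq_source: str = "observed"
    supplied_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.blend_alpha <= 1.0:
            raise ValueError("blend_alpha must be in [0, 1]")


@dataclass
class QCReport:
    n_input: int = 0
    n_sex_chrom: int = 0
    n_monomorphic: int = 0
    n_low_maf: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "sex_chromosome", "monomorphic", "low_maf", "retained"],
                "n_snps": [self.n_input, self.n_sex_chrom, self.n_monomorphic, self.n_low_maf, self.n_retained],
            }
        )


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Observed frequency of the counted allele, ignoring missing codes."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(codes, axis=0) / 2.0


def qc_filter(g: GenotypeData, maf_min: float = 0.01, sex_chroms=SEX_CHROMS):
    """Remove sex-chromosome, monomorphic and low-MAF SNPs.

    Rules are applied in order (a SNP is counted once, under the first rule
    that removes it); ``MAF == maf_min`` is retained (strictly-less-than
    removal).  Returns the filtered data and a :class:`QCReport`.
    """
    chrom = g.snp_map["chrom"].astype(str).to_numpy()
    on_sex = np.isin(chrom, list(sex_chroms))
    p = allele_frequencies(g.codes)
    maf = np.minimum(p, 1.0 - p)
    mono = (maf == 0.0) | np.isnan(maf)
    low = maf < maf_min

    sex_removed = on_sex
    mono_removed = mono & ~sex_removed
    low_removed = low & ~sex_removed & ~mono_removed
    keep = ~(sex_removed | mono_removed | low_removed)
    if not keep.any():
        raise ValueError("quality control removed every SNP")
    report = QCReport(
        n_input=g.n_snps,
        n_sex_chrom=int(sex_removed.sum()),
        n_monomorphic=int(mono_removed.sum()),
        n_low_maf=int(low_removed.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "SNP QC: %d input, %d sex-chromosome, %d monomorphic, %d MAF<%g, %d retained",
        report.n_input, report.n_sex_chrom, report.n_monomorphic, maf_min, report.n_retained,
    )
    return g.subset_snps(keep), report


def centered_genotypes(g: GenotypeData, freqs: np.ndarray | None = None):
    """Centered allele counts Z = codes - 2p with missing codes imputed to 2p.

    Returns ``(Z, p, k)`` where ``k = 2 Σ p(1-p)`` is VanRaden's scaling.
    """
    p = allele_frequencies(g.codes) if freqs is None else np.asarray(freqs, dtype=float)
    codes = g.codes.copy()
    nan_r, nan_c = np.nonzero(np.isnan(codes))
    codes[nan_r, nan_c] = 2.0 * p[nan_c]
    Z = codes - 2.0 * p
    k = float(2.0 * np.sum(p * (1.0 - p)))
    return Z, p, k


def g_matrix(g: GenotypeData, cfg: GMatrixConfig = GMatrixConfig(), a22: np.ndarray | None = None) -> np.ndarray:
    """Blended VanRaden-1 genomic relationship matrix.

    ``G = blend_alpha * M M' / (2 Σ p(1-p)) + (1 - blend_alpha) * A22``.
    ``a22`` may be omitted when ``blend_alpha == 1``.
    """
    freqs = cfg.supplied_freqs if cfg.allele_freq_source == "supplied" else None
    Z, _, k = centered_genotypes(g, freqs)
    if k == 0.0:
        raise ValueError("all SNPs monomorphic: 2*sum(p(1-p)) is zero")
    G_raw = (Z @ Z.T) / k
    if cfg.blend_alpha == 1.0:
        return G_raw
    if a22 is None:
        raise ValueError("A22 required for blending when blend_alpha < 1")
    return cfg.blend_alpha * G_raw + (1.0 - cfg.blend_alpha) * np.asarray(a22)


def h_inverse(
    a_inv: sparse.spmatrix,
    a22_inv: np.ndarray,
    g_inv: np.ndarray,
    genotyped_index: np.ndarray,
    sym_tol: float = 1e-8,
) -> sparse.csr_matrix:
    """Single-step relationship inverse: A^-1 plus (G^-1 - A22^-1) in the
    genotyped block.

    ``genotyped_index`` gives the positions of the genotyped animals within
    the pedigree ordering of ``a_inv``.
    """
    g_inv = np.asarray(g_inv)
    if g_inv.size and np.max(np.abs(g_inv - g_inv.T)) > sym_tol:
        raise ValueError("G inverse is not symmetric within tolerance")
    idx = np.asarray(genotyped_index, dtype=np.int64)
    H = sparse.lil_matrix(a_inv, copy=True)
    if idx.size:
        delta = g_inv - np.asarray(a22_inv)
        H[np.ix_(idx, idx)] = H[np.ix_(idx, idx)].toarray() + delta
    return H.tocsr()


# ----------------------------------------------------------------- file I/O
def read_genotype_tsv(matrix_path, snp_map_path) -> GenotypeData:
    """Read a TSV allele-count matrix (first column animal id, one column per
    SNP; NA = missing) plus a SNP map TSV (snp_id, chrom, pos_bp)."""
    mat = pd.read_csv(matrix_path, sep="\t")
    snp_map = pd.read_csv(snp_map_path, sep="\t", dtype={"chrom": str})
    animals = mat.iloc[:, 0].astype(str).tolist()
    codes = mat.iloc[:, 1:].to_numpy(dtype=float)
    if list(mat.columns[1:]) != snp_map["snp_id"].tolist():
        raise ValueError("genotype matrix columns do not match the SNP map")
    return GenotypeData(animals=animals, codes=codes, snp_map=snp_map[["snp_id", "chrom", "pos_bp"]])


def read_plink(ped_path, map_path) -> GenotypeData:
    """Read PLINK-style .ped/.map text files.

    Codes count copies of the lexicographically smaller allele observed at
    each SNP; '0 0' genotypes are missing.
    """
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos_bp"], dtype={"chrom": str}
    )[["snp_id", "chrom", "pos_bp"]]
    animals, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            animals.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(snp_map):
                raise ValueError("ped line has wrong number of allele columns")
            rows.append(alleles)
    n, m = len(animals), len(snp_map)
    codes = np.full((n, m), np.nan)
    arr = np.array(rows, dtype=object).reshape(n, m, 2) if rows else np.empty((0, m, 2), dtype=object)
    for j in range(m):
        col = arr[:, j, :]
        obs = col[col != "0"]
        if obs.size == 0:
            continue
        ref = min(set(obs.tolist()))
        missing = (col == "0").any(axis=1)
        codes[:, j] = (col == ref).sum(axis=1).astype(float)
        codes[missing, j] = np.nan
    return GenotypeData(animals=animals, codes=codes, snp_map=snp_map)
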