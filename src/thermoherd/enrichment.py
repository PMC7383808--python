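"""SNP-to-gene assignment, relevant-gene flagging, and gene-set
over-representation by Fisher's exact (cumulative hypergeometric) test.

A SNP belongs to a gene if it falls within the gene body or within a flanking
distance (default 15 kb) either side.  Per parity, the relevant SNPs are the
top fraction (default 5%) of the absolute SNP-effect distribution, ties at
the threshold included; a gene is relevant if flagged in at least
``min_parities`` parities.  Enrichment of each gene set is the one-sided
upper hypergeometric tail P(X ≥ k) over the SNP-covered gene universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

__all__ = [
    "GeneModel",
    "read_gene_annotation",
    "read_gmt",
    "write_gmt",
    "assign_snps_to_genes",
    "flag_relevant_genes",
    "fisher_enrichment",
    "enrichment_report",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (1-based, inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gene_annotation(path, zero_based_half_open: bool = False) -> list[GeneModel]:
    """Read a BED-like TSV (chrom, start, end, gene_id[, strand]).

    Coordinates are 1-based inclusive by default; pass
    ``zero_based_half_open=True`` to convert from true BED convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    off = 1 if zero_based_half_open else 0
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start) + off,
            end=int(r.end),
            strand=getattr(r, "strand", None),
        )
        for r in df.itertuples()
    ]


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: set id, description, then member genes."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set id {parts[0]}")
            members = {g for g in parts[2:] if g}
            if members:
                sets[parts[0]] = members
    return sets


def write_gmt(sets: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        for sid, members in sets.items():
            fh.write("\t".join([sid, sid] + sorted(members)) + "\n")


def assign_snps_to_genes(snp_map: pd.DataFrame, genes: list[GeneModel], flank: int = 15_000) -> pd.DataFrame:
    """Map SNPs to genes within gene body ± ``flank`` bp (strand-agnostic).

    A SNP may map to several genes.  Returns columns snp_index, snp_id,
    gene_id.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start - flank, gene.end + flank + 1, gene.gene_id
        )
    rows = []
    chroms = snp_map["chrom"].astype(str).to_numpy()
    positions = snp_map["pos_bp"].to_numpy()
    snp_ids = snp_map["snp_id"].to_numpy()
    for i, (chrom, pos, sid) in enumerate(zip(chroms, positions, snp_ids)):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.at(int(pos)):
            rows.append({"snp_index": i, "snp_id": sid, "gene_id": hit.data})
    return pd.DataFrame(rows, columns=["snp_index", "snp_id", "gene_id"])


def flag_relevant_genes(
    effects_by_parity: dict[int, np.ndarray],
    snp_gene_map: pd.DataFrame,
    top_frac: float = 0.05,
    min_parities: int = 2,
) -> set:
    """Genes flagged by at least one top-fraction SNP in ≥ ``min_parities``
    parities.

    Per parity, the threshold is the k-th largest |effect| with
    ``k = ceil(top_frac · m)``; SNPs tied at the threshold are included
    (all-equal effects flag every SNP).
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    if len(snp_gene_map) == 0:
        return set()
    flags: dict[str, int] = {}
    for parity, effects in effects_by_parity.items():
        a = np.abs(np.asarray(effects, dtype=float))
        k = max(int(math.ceil(top_frac * len(a))), 1)
        threshold = np.sort(a)[::-1][k - 1]
        relevant_idx = set(np.nonzero(a >= threshold)[0].tolist())
        hit = snp_gene_map.loc[snp_gene_map["snp_index"].isin(relevant_idx), "gene_id"].unique()
        for gid in hit:
            flags[gid] = flags.get(gid, 0) + 1
    return {gid for gid, cnt in flags.items() if cnt >= min_parities}


def fisher_enrichment(relevant: set, background: set, sets: dict[str, set]) -> pd.DataFrame:
    """One-sided over-representation test per gene set.

    With N background genes, K of them relevant, a set holding n background
    genes of which k are relevant, the p-value is the upper hypergeometric
    tail P(X ≥ k).  Set members outside the background are ignored.
    Returns columns set_id, n_genes, n_relevant, background_size,
    background_relevant, p_value.
    """
    if not background:
        raise ValueError("empty background gene universe")
    if not relevant <= background:
        raise ValueError("relevant genes must be a subset of the background")
    N = len(background)
    K = len(relevant)
    rows = []
    for sid, members in sets.items():
        in_bg = members & background
        n = len(in_bg)
        k = len(in_bg & relevant)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append(
            {
                "set_id": sid,
                "n_genes": n,
                "n_relevant": k,
                "background_size": N,
                "background_relevant": K,
                "p_value": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def enrichment_report(results: pd.DataFrame, alpha: float = 0.05, adjust: str = "none") -> pd.DataFrame:
    """Rank sets by p ascending, add -log10 p and (optionally) BH q-values."""
    out = results.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    with np.errstate(divide="ignore"):
        out["minus_log10_p"] = -np.log10(out["p_value"])
    if adjust == "BH":
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(out["p_value"].to_numpy(), alpha=alpha, method="fdr_bh")
        out["q_value"] = q
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'BH'")
    out["significant"] = out["p_value"] < alpha
    return out
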