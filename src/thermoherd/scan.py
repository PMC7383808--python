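"""Whole-genome window scans from single-step GBLUP solutions.

The mixed-model equations are solved with the combined relationship inverse
H^-1 in place of A^-1; SNP effects are then back-solved from the genotyped
animals' GEBVs as ``s = D Z' (Z D Z')^-1 u`` and summarized as the
percentage of an effect's genetic variance captured by 2.0 Mb windows of
adjacent SNPs: ``var(Σ_j z_j s_j) / σ²_u × 100`` with the variance taken
across genotyped animals.

Windows are sliding by default (anchored at each SNP, extending 2.0 Mb
downstream); a distinct (non-overlapping) mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .genomics import GenotypeData, centered_genotypes
from .model_mme import N_COEF, MMELayout, RandomEffectCovariances, assemble_mme

logger = logging.getLogger(__name__)

__all__ = [
    "EFFECT_LABELS",
    "BreedingValueSet",
    "SnpEffects",
    "solve_ssgblup",
    "backsolve_snp_effects",
    "window_variance",
    "top_regions",
    "manhattan_plot",
]

#: intercept (general) and slope (thermotolerance) effects per parity
EFFECT_LABELS = ("a1", "v1", "a2", "v2", "a3", "v3")


@dataclass
class BreedingValueSet:
    """Per-animal solutions for the six genetic effects.

    ``values`` is animals × 6 in EFFECT_LABELS order; ``solution`` is the
    full MME solution vector (fixed + genetic + permanent environment).
    """

    animals: list
    values: np.ndarray
    solution: np.ndarray

    def effect(self, label: str) -> np.ndarray:
        return self.values[:, EFFECT_LABELS.index(label)]

    def for_animals(self, animals) -> "BreedingValueSet":
        pos = {a: i for i, a in enumerate(self.animals)}
        idx = [pos[a] for a in animals]
        return BreedingValueSet(list(animals), self.values[idx], self.solution)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(EFFECT_LABELS))
        df.insert(0, "animal", self.animals)
        return df


@dataclass
class SnpEffects:
    """Back-solved marker effects for one genetic effect."""

    effect: str
    values: np.ndarray  # per QC'd SNP
    snp_map: pd.DataFrame


def solve_ssgblup(
    layout: MMELayout,
    cov: RandomEffectCovariances,
    h_inv: sparse.spmatrix,
    rtol: float = 1e-10,
    maxiter: int = 20_000,
) -> BreedingValueSet:
    """Solve the MME with H^-1 (or A^-1) by Jacobi-preconditioned CG.

    Variances are held fixed (posterior means or user-supplied).  Raises on
    non-convergence, reporting the residual history.
    """
    lhs, rhs = assemble_mme(layout, cov, h_inv)
    if not np.any(rhs):
        sol = np.zeros_like(rhs)
    else:
        diag = lhs.diagonal()
        diag[diag == 0] = 1.0
        M = LinearOperator(lhs.shape, matvec=lambda x: x / diag)
        history: list[float] = []
        rhs_norm = np.linalg.norm(rhs)

        def track(xk):
            history.append(float(np.linalg.norm(rhs - lhs @ xk) / rhs_norm))

        sol, info = cg(lhs, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=M, callback=track)
        if info != 0:
            raise RuntimeError(
                f"PCG did not converge in {maxiter} iterations; "
                f"last relative residuals: {[f'{h:.2e}' for h in history[-5:]]}"
            )
    g0 = layout.genetic_offset
    values = sol[g0 : g0 + N_COEF * layout.n_animals].reshape(layout.n_animals, N_COEF)
    return BreedingValueSet(animals=list(layout.pedigree_ids), values=values.copy(), solution=sol)


def backsolve_snp_effects(
    u: np.ndarray,
    g: GenotypeData,
    effect: str = "v1",
    d: np.ndarray | None = None,
    blend_alpha: float = 0.95,
    a22: np.ndarray | None = None,
) -> SnpEffects:
    """Back-solve SNP effects ``s = D Z' (Z D Z')^-1 u`` for one effect.

    ``u`` holds the GEBVs of the genotyped animals in ``g``'s animal order.
    ``Z D Z'`` is made invertible by the same blending policy as the G
    matrix: with D = I it equals ``k G_raw`` (k = 2Σp(1-p)), and the inverse
    is taken of ``blend_alpha·Z D Z' + (1-blend_alpha)·k·A22`` (identity
    replaces A22 when it is not supplied).  ``blend_alpha=1`` uses the raw
    product and requires it to be non-singular.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (len(g.animals),):
        raise ValueError("u must hold one GEBV per genotyped animal")
    Z, _, k = centered_genotypes(g)
    dvec = np.ones(g.n_snps) if d is None else np.asarray(d, dtype=float)
    ZDZ = (Z * dvec) @ Z.T
    if blend_alpha < 1.0:
        anchor = k * (np.eye(len(u)) if a22 is None else np.asarray(a22))
        ZDZ = blend_alpha * ZDZ + (1.0 - blend_alpha) * anchor
        w = np.linalg.solve(ZDZ, u)
    else:
        # centering makes Z's columns zero-mean, so Z D Z' is always rank
        # deficient (the all-ones vector is in its null space); the
        # Moore-Penrose inverse realizes the projection identity, giving the
        # planted effects exactly when Z has full column rank
        w = np.linalg.pinv(ZDZ, rcond=1e-10) @ u
    return SnpEffects(effect=effect, values=dvec * (Z.T @ w), snp_map=g.snp_map)


def window_variance(
    s: SnpEffects,
    g: GenotypeData,
    window_mb: float = 2.0,
    sigma_u2: float | None = None,
    u: np.ndarray | None = None,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Percentage of genetic variance per window of adjacent SNPs.

    For each window the per-animal score is ``Σ_{j in window} z_j s_j``
    (centered genotypes); the reported percentage is the variance of scores
    across genotyped animals divided by ``sigma_u2`` × 100.  When
    ``sigma_u2`` is not supplied it is the empirical variance of ``u``
    (the effect's GEBVs among genotyped animals).

    ``mode='sliding'`` anchors a window at every SNP, extending
    ``window_mb`` downstream; ``mode='distinct'`` tiles each chromosome in
    non-overlapping windows.  Returns columns effect, chrom,
    window_start_bp, window_end_bp, n_snps, pct_variance.
    """
    if sigma_u2 is None:
        if u is None:
            raise ValueError("supply sigma_u2 or the GEBV vector u")
        sigma_u2 = float(np.var(np.asarray(u, dtype=float)))
    if sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive")
    Z, _, _ = centered_genotypes(g)
    span = int(round(window_mb * 1e6))
    snp_map = s.snp_map
    order = np.lexsort((snp_map["pos_bp"].to_numpy(), snp_map["chrom"].astype(str).to_numpy()))
    rows = []
    for chrom in snp_map["chrom"].astype(str).unique():
        on = order[snp_map["chrom"].astype(str).to_numpy()[order] == chrom]
        pos = snp_map["pos_bp"].to_numpy()[on]
        if mode == "sliding":
            starts = pos
        elif mode == "distinct":
            starts = np.arange(0, pos.max() + 1, span) if len(pos) else np.array([], dtype=int)
        else:
            raise ValueError("mode must be 'sliding' or 'distinct'")
        for w0 in starts:
            in_win = on[(pos >= w0) & (pos < w0 + span)]
            if len(in_win):
                score = Z[:, in_win] @ s.values[in_win]
                pct = float(np.var(score) / sigma_u2 * 100.0)
            else:
                pct = 0.0
            rows.append(
                {
                    "effect": s.effect,
                    "chrom": chrom,
                    "window_start_bp": int(w0),
                    "window_end_bp": int(w0 + span),
                    "n_snps": int(len(in_win)),
                    "pct_variance": pct,
                }
            )
    return pd.DataFrame(rows)


def top_regions(result: pd.DataFrame, n: int | None = None) -> pd.DataFrame:
    """Windows ranked by percentage of variance, ties broken by (chrom, start)."""
    ranked = result.sort_values(
        by=["pct_variance", "chrom", "window_start_bp"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ranked if n is None else ranked.head(n)


def manhattan_plot(result: pd.DataFrame, path) -> None:
    """Manhattan-style plot of window percentages along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in result.groupby("chrom", sort=True):
        x = grp["window_start_bp"].to_numpy() + offset
        ax.scatter(x, grp["pct_variance"], s=4)
        ticks.append(offset + grp["window_start_bp"].max() / 2)
        labels.append(str(chrom))
        offset += grp["window_end_bp"].max()
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% genetic variance")
    effect = result["effect"].iloc[0] if len(result) else ""
    ax.set_title(f"2.0 Mb window scan — effect {effect}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
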