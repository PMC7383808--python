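"""Design matrices and Henderson mixed-model equations for the multitrait
(parity 1–3) repeatability reaction-norm model.

The observation model for insemination outcome y of cow n, parity l is

    y = HTD_kl + DIM_m + a_nl + pe_nl + (v_nl + q_nl) f(THI) + e_klmn

with herd-day-within-parity (HTD) and 20-day DIM-class fixed effects, genetic
intercept/slope (a, v) for every pedigree animal, permanent-environment
intercept/slope (pe, q) for every cow with records, and parity-specific
residual variances.  The binary outcome is modelled linearly, as in classic
test-day evaluations of conception traits.

Coefficient order within each random 6-block is (a1, v1, a2, v2, a3, v3):
parity-major, intercept before slope.  The genetic block of the equations
adds ``relationship_inv ⊗ Φ^-1`` (animal-major ordering), the
permanent-environment block ``I ⊗ ψ^-1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "MMEConfig",
    "RandomEffectCovariances",
    "MMELayout",
    "dim_class",
    "load_records",
    "build_design",
    "assemble_mme",
    "solve_mme",
]

N_PARITIES = 3
N_COEF = 2 * N_PARITIES  # (intercept, slope) x 3 parities


@dataclass(frozen=True)
class MMEConfig:
    dim_class_width: int = 20
    dim_max: int = 400
    drop_first_htd: bool = True  # one identifiability constraint per parity
    drop_first_dim: bool = True  # avoids collinearity of DIM dummies with HTD


@dataclass
class RandomEffectCovariances:
    """Covariances of the random regression coefficients.

    ``phi``: 6×6 genetic (co)variance matrix of (a1, v1, a2, v2, a3, v3);
    ``psi``: 6×6 permanent-environment analogue for (pe, q);
    ``r_diag``: residual variance per parity (length 3).
    """

    phi: np.ndarray
    psi: np.ndarray
    r_diag: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.r_diag = np.asarray(self.r_diag, dtype=float)
        for name, m in (("phi", self.phi), ("psi", self.psi)):
            if m.shape != (N_COEF, N_COEF):
                raise ValueError(f"{name} must be 6x6")
            if np.max(np.abs(m - m.T)) > 1e-10:
                raise ValueError(f"{name} must be symmetric")
        if self.r_diag.shape != (N_PARITIES,) or np.any(self.r_diag <= 0):
            raise ValueError("r_diag must be 3 positive residual variances")

    def validate_pd(self) -> None:
        for name, m in (("phi", self.phi), ("psi", self.psi)):
            if np.min(np.linalg.eigvalsh(m)) <= 0:
                raise ValueError(
                    f"{name} is not positive definite; add a ridge or re-estimate"
                )

    @staticmethod
    def sigma_index(parity: int, kind: str) -> tuple[int, int]:
        """Index into phi/psi for a scalar component of ``parity`` (1-based).

        kind: 'intercept' (σ²a / σ²pe), 'slope' (σ²v / σ²q) or
        'cov' (σav / σpq).
        """
        i = 2 * (parity - 1)
        if kind == "intercept":
            return i, i
        if kind == "slope":
            return i + 1, i + 1
        if kind == "cov":
            return i, i + 1
        raise ValueError(f"unknown component kind: {kind}")


def dim_class(dim, width: int = 20) -> int:
    """20-day days-in-milk class; class 1 = days 1..width."""
    arr = np.asarray(dim)
    if np.any(arr < 1):
        raise ValueError("days in milk must be >= 1")
    out = np.ceil(arr / width).astype(int)
    return out if out.ndim else int(out)


def load_records(source, config: MMEConfig = MMEConfig(), binary: bool = True) -> pd.DataFrame:
    """Load and validate insemination records (CSV path or DataFrame).

    Columns: cow, parity, herd, date, dim, outcome.  Records with missing
    herd/date/DIM, DIM outside [1, dim_max] or parity outside 1..3 are
    dropped with a logged count.
    """
    df = (
        pd.read_csv(source, dtype={"cow": str, "herd": str})
        if not isinstance(source, pd.DataFrame)
        else source.copy()
    )
    required = {"cow", "parity", "herd", "date", "dim", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["cow", "parity", "herd", "date", "dim", "outcome"])
    df["parity"] = df["parity"].astype(int)
    df["dim"] = df["dim"].astype(int)
    ok = (
        df["parity"].between(1, N_PARITIES)
        & df["dim"].between(1, config.dim_max)
    )
    if binary:
        ok &= df["outcome"].isin([0, 1])
    df = df.loc[ok].reset_index(drop=True)
    if len(df) < n0:
        logger.warning("dropped %d invalid insemination record(s) at load", n0 - len(df))
    return df


@dataclass
class MMELayout:
    """Assembled design structure for the reaction-norm model.

    Column order: [HTD levels | DIM classes | genetic 6-blocks per pedigree
    animal | permanent-environment 6-blocks per cow with records].
    """

    records: pd.DataFrame
    pedigree_ids: list
    cow_ids: list
    htd_levels: pd.DataFrame          # herd, date, parity, col (-1 = constrained out)
    dim_levels: pd.DataFrame          # dim_class, col (-1 = constrained out)
    n_fixed: int
    rec_htd_col: np.ndarray
    rec_dim_col: np.ndarray
    rec_animal: np.ndarray            # pedigree index
    rec_cow: np.ndarray               # cow index
    rec_parity: np.ndarray            # 1-based
    rec_f: np.ndarray                 # heat-load covariate
    y: np.ndarray
    _w: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.pedigree_ids)

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    @property
    def genetic_offset(self) -> int:
        return self.n_fixed

    @property
    def pe_offset(self) -> int:
        return self.n_fixed + N_COEF * self.n_animals

    @property
    def n_equations(self) -> int:
        return self.n_fixed + N_COEF * (self.n_animals + self.n_cows)

    def design_matrix(self) -> sparse.csr_matrix:
        """Full sparse incidence matrix W (records × equations)."""
        if self._w is not None:
            return self._w
        n = self.n_records
        rows, cols, vals = [], [], []
        for r in range(n):
            for c in (self.rec_htd_col[r], self.rec_dim_col[r]):
                if c >= 0:
                    rows.append(r), cols.append(c), vals.append(1.0)
            base = 2 * (self.rec_parity[r] - 1)
            g0 = self.genetic_offset + N_COEF * self.rec_animal[r]
            p0 = self.pe_offset + N_COEF * self.rec_cow[r]
            f = self.rec_f[r]
            rows += [r, r]
            cols += [g0 + base, p0 + base]
            vals += [1.0, 1.0]
            if f != 0.0:
                rows += [r, r]
                cols += [g0 + base + 1, p0 + base + 1]
                vals += [f, f]
        self._w = sparse.csr_matrix((vals, (rows, cols)), shape=(n, self.n_equations))
        return self._w

    def r_inv_per_record(self, r_diag: np.ndarray) -> np.ndarray:
        return 1.0 / np.asarray(r_diag)[self.rec_parity - 1]


def build_design(
    records: pd.DataFrame,
    pedigree: Pedigree,
    config: MMEConfig = MMEConfig(),
) -> MMELayout:
    """Build the MME layout from validated records with ``f_thi`` attached.

    Fixed effects are herd-date-within-parity (HTD) contemporary groups and
    DIM classes; identifiability is handled by zeroing the first HTD level of
    each parity and the first DIM class (configurable).
    """
    if "f_thi" not in records.columns:
        raise ValueError("records need an f_thi column (use thermal.attach_heat_load)")
    unknown = [c for c in records["cow"].unique() if c not in pedigree._pos]
    if unknown:
        raise ValueError(f"records cite cows absent from the pedigree: {unknown[:5]}")

    df = records.reset_index(drop=True)
    parity = df["parity"].to_numpy(dtype=np.int64)

    # HTD levels: distinct (herd, date, parity), first level per parity constrained
    htd_keys = df[["herd", "date", "parity"]].drop_duplicates().sort_values(
        ["parity", "herd", "date"]
    ).reset_index(drop=True)
    htd_col = np.full(len(htd_keys), -1, dtype=np.int64)
    next_col = 0
    seen_parity: set[int] = set()
    for i, p in enumerate(htd_keys["parity"]):
        if config.drop_first_htd and p not in seen_parity:
            seen_parity.add(p)
            continue
        htd_col[i] = next_col
        next_col += 1
    htd_levels = htd_keys.assign(col=htd_col)
    key_to_col = {
        (h, d, p): c
        for h, d, p, c in zip(htd_levels["herd"], htd_levels["date"], htd_levels["parity"], htd_levels["col"])
    }
    rec_htd = np.array(
        [key_to_col[(h, d, p)] for h, d, p in zip(df["herd"], df["date"], df["parity"])],
        dtype=np.int64,
    )

    # DIM classes present in the data
    classes = dim_class(df["dim"].to_numpy(), config.dim_class_width)
    uniq = np.unique(classes)
    dim_col = np.full(len(uniq), -1, dtype=np.int64)
    for i in range(len(uniq)):
        if config.drop_first_dim and i == 0:
            continue
        dim_col[i] = next_col
        next_col += 1
    dim_levels = pd.DataFrame({"dim_class": uniq, "col": dim_col})
    cls_to_col = dict(zip(uniq, dim_col))
    rec_dim = np.array([cls_to_col[c] for c in classes], dtype=np.int64)

    cow_ids = sorted(df["cow"].unique(), key=lambda c: pedigree.index_of(c))
    cow_pos = {c: i for i, c in enumerate(cow_ids)}

    return MMELayout(
        records=df,
        pedigree_ids=list(pedigree.ids),
        cow_ids=cow_ids,
        htd_levels=htd_levels,
        dim_levels=dim_levels,
        n_fixed=next_col,
        rec_htd_col=rec_htd,
        rec_dim_col=rec_dim,
        rec_animal=pedigree.indices(df["cow"].tolist()),
        rec_cow=np.array([cow_pos[c] for c in df["cow"]], dtype=np.int64),
        rec_parity=parity,
        rec_f=df["f_thi"].to_numpy(dtype=float),
        y=df["outcome"].to_numpy(dtype=float),
    )


def assemble_mme(
    layout: MMELayout,
    cov: RandomEffectCovariances,
    relationship_inv: sparse.spmatrix,
):
    """Henderson's mixed-model equations.

    LHS = W' R^-1 W + blockdiag(0_fixed, relationship_inv ⊗ Φ^-1, I ⊗ ψ^-1);
    RHS = W' R^-1 y.  ``relationship_inv`` is A^-1 (pedigree BLUP) or H^-1
    (single-step).
    """
    cov.validate_pd()
    W = layout.design_matrix()
    rinv = layout.r_inv_per_record(cov.r_diag)
    Rinv = sparse.diags(rinv)
    lhs = (W.T @ Rinv @ W).tolil()
    rhs = W.T @ (rinv * layout.y)

    phi_inv = np.linalg.inv(cov.phi)
    psi_inv = np.linalg.inv(cov.psi)

    g0 = layout.genetic_offset
    gblock = sparse.kron(sparse.csr_matrix(relationship_inv), sparse.csr_matrix(phi_inv))
    pe_block = sparse.kron(sparse.identity(layout.n_cows, format="csr"), sparse.csr_matrix(psi_inv))
    n = layout.n_equations
    pad = sparse.block_diag(
        [sparse.csr_matrix((g0, g0)), gblock, pe_block], format="csr"
    )
    if pad.shape != (n, n):  # pragma: no cover - defensive
        raise ValueError("random-effect block dimensions inconsistent with layout")
    lhs = (lhs.tocsr() + pad).tocsr()
    # sparse matmul summation order can leave tiny (i,j)/(j,i) float
    # discrepancies; enforce exact symmetry
    lhs = ((lhs + lhs.T) * 0.5).tocsr()
    return lhs, rhs


def solve_mme(lhs: sparse.spmatrix, rhs: np.ndarray, method: str = "auto") -> np.ndarray:
    """Solve the MME (direct sparse solve; dense fallback for tiny systems)."""
    if method == "dense" or (method == "auto" and lhs.shape[0] <= 500):
        return np.linalg.solve(lhs.toarray(), rhs)
    return spsolve(lhs.tocsc(), rhs)
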