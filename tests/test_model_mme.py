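"""Design building and Henderson MME assembly, checked against a dense GLS
oracle that forms V = Z G Z' + R explicitly."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.linalg import block_diag

from thermoherd.model_mme import (
    MMEConfig,
    RandomEffectCovariances,
    assemble_mme,
    build_design,
    dim_class,
    load_records,
    solve_mme,
)
from thermoherd.pedigree import Pedigree
from thermoherd.simulate import default_covariances, simulate_pedigree


def small_cov(seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((6, 6))
    b = rng.standard_normal((6, 6))
    return RandomEffectCovariances(
        phi=scale * (a @ a.T + 6 * np.eye(6)) / 20,
        psi=scale * (b @ b.T + 6 * np.eye(6)) / 20,
        r_diag=np.array([1.0, 0.8, 1.2]),
    )


def gls_oracle(layout, cov, A):
    """BLUE/BLUP by brute-force GLS on the explicit V matrix."""
    W = layout.design_matrix().toarray()
    nf = layout.n_fixed
    g0, p0 = layout.genetic_offset, layout.pe_offset
    X = W[:, :nf]
    Zg = W[:, g0 : g0 + 6 * layout.n_animals]
    Zp = W[:, p0:]
    Gfull = np.kron(A, cov.phi)
    Pfull = np.kron(np.eye(layout.n_cows), cov.psi)
    R = np.diag(cov.r_diag[layout.rec_parity - 1])
    V = Zg @ Gfull @ Zg.T + Zp @ Pfull @ Zp.T + R
    Vi = np.linalg.inv(V)
    y = layout.y
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y) if nf else np.zeros(0)
    resid = y - (X @ beta if nf else 0.0)
    u = Gfull @ Zg.T @ Vi @ resid
    pe = Pfull @ Zp.T @ Vi @ resid
    return np.concatenate([beta, u, pe])


class TestDimClass:
    @pytest.mark.parametrize("dim, expected", [(1, 1), (20, 1), (21, 2), (399, 20), (400, 20)])
    def test_boundaries(self, dim, expected):
        assert dim_class(dim) == expected

    def test_load_rejects_late_records(self):
        df = pd.DataFrame(
            {
                "cow": ["c", "c"],
                "parity": [1, 1],
                "herd": ["h", "h"],
                "date": ["2014-01-01"] * 2,
                "dim": [400, 401],
                "outcome": [1, 0],
            }
        )
        assert len(load_records(df)) == 1


class TestBuildDesign:
    def test_zero_heat_load_zeroes_slope_columns(self, trio, tiny_records):
        layout = build_design(tiny_records, trio)
        W = layout.design_matrix().toarray()
        rec0 = tiny_records.index[tiny_records["f_thi"] == 0.0][0]
        g0 = layout.genetic_offset
        slope_cols = [g0 + 2 * l + 1 for l in range(3)]
        assert np.all(W[rec0, slope_cols] == 0.0)

    def test_htd_levels_count_distinct_triples(self, trio, tiny_records):
        layout = build_design(tiny_records, trio, MMEConfig(drop_first_htd=False, drop_first_dim=False))
        expected = tiny_records[["herd", "date", "parity"]].drop_duplicates()
        assert len(layout.htd_levels) == len(expected)
        # records sharing (herd, date, parity) share an HTD level
        same = tiny_records.duplicated(subset=["herd", "date", "parity"], keep=False)
        cols = layout.rec_htd_col[same.to_numpy()]
        assert len(np.unique(cols)) < same.sum()

    def test_unknown_cow_rejected(self, trio, tiny_records):
        bad = tiny_records.assign(cow="GHOST")
        with pytest.raises(ValueError, match="absent"):
            build_design(bad, trio)


class TestAssemble:
    def test_lhs_exactly_symmetric(self, trio, tiny_records):
        layout = build_design(tiny_records, trio)
        lhs, _ = assemble_mme(layout, small_cov(), trio.a_inverse())
        assert (abs(lhs - lhs.T) > 0).nnz == 0

    def test_no_records_prior_only(self, trio, tiny_records):
        layout = build_design(tiny_records.iloc[:0], trio)
        cov = small_cov()
        lhs, rhs = assemble_mme(layout, cov, trio.a_inverse())
        expected = np.kron(trio.a_inverse().toarray(), np.linalg.inv(cov.phi))
        assert np.allclose(lhs.toarray(), expected)
        assert np.all(rhs == 0)

    def test_non_pd_covariance_rejected(self, trio, tiny_records):
        layout = build_design(tiny_records, trio)
        cov = small_cov()
        bad = RandomEffectCovariances(phi=cov.phi * 0.0, psi=cov.psi, r_diag=cov.r_diag)
        with pytest.raises(ValueError, match="positive definite"):
            assemble_mme(layout, bad, trio.a_inverse())


class TestGLSOracle:
    def make_layout(self, seed, n_records=24):
        ped, table = simulate_pedigree(n_founders=6, n_generations=1, seed=seed)
        cows = table.loc[table["sex"] == "F", "animal"].tolist()[:4] or table["animal"].tolist()[:4]
        for attempt in range(20):  # skip draws whose fixed design is aliased
            rng = np.random.default_rng(1000 * seed + attempt)
            records = pd.DataFrame(
                {
                    "cow": rng.choice(cows, size=n_records),
                    "parity": rng.integers(1, 4, size=n_records),
                    "herd": rng.choice(["H1", "H2"], size=n_records),
                    "date": rng.choice(["2014-06-01", "2014-07-01"], size=n_records),
                    "dim": rng.integers(30, 70, size=n_records),
                    "outcome": rng.normal(0.35, 0.4, size=n_records),
                    "f_thi": np.where(rng.random(n_records) < 0.5, 0.0, rng.uniform(1, 12, n_records)),
                }
            )
            layout = build_design(records, ped)
            X = layout.design_matrix().toarray()[:, : layout.n_fixed]
            if np.linalg.matrix_rank(X) == layout.n_fixed:
                return ped, layout
        raise AssertionError("could not draw a full-rank fixed design")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_mme_equals_dense_gls(self, seed):
        ped, layout = self.make_layout(seed)
        cov = small_cov(seed)
        lhs, rhs = assemble_mme(layout, cov, ped.a_inverse())
        sol = solve_mme(lhs, rhs, method="dense")
        oracle = gls_oracle(layout, cov, ped.a_matrix())
        assert np.max(np.abs(sol - oracle)) < 1e-6

    def test_single_record_closed_form(self):
        """One founder, one record, no fixed effects: the solutions are the
        classic shrinkage fractions sigma^2/(sigma_a^2+sigma_pe^2+sigma_e^2) y."""
        ped = Pedigree.from_frame(pd.DataFrame({"animal": ["A"], "sire": ["0"], "dam": ["0"]}))
        records = pd.DataFrame(
            {
                "cow": ["A"],
                "parity": [1],
                "herd": ["H1"],
                "date": ["2014-06-01"],
                "dim": [50],
                "outcome": [1.0],
                "f_thi": [0.0],
            }
        )
        layout = build_design(records, ped)
        assert layout.n_fixed == 0  # the only HTD level and DIM class are constrained out
        cov = default_covariances()
        sol = solve_mme(*assemble_mme(layout, cov, ped.a_inverse()), method="dense")
        sa2, spe2, se2 = cov.phi[0, 0], cov.psi[0, 0], cov.r_diag[0]
        denom = sa2 + spe2 + se2
        assert sol[layout.genetic_offset] == pytest.approx(sa2 / denom, rel=1e-10)
        assert sol[layout.pe_offset] == pytest.approx(spe2 / denom, rel=1e-10)

    def test_vanishing_variance_ratio_recovers_weighted_ls(self):
        """With Phi, psi -> 0 the random effects vanish and the fixed-effect
        solutions approach R^-1-weighted least squares."""
        ped, layout = self.make_layout(4)
        cov = small_cov(4, scale=1e-10)
        sol = solve_mme(*assemble_mme(layout, cov, ped.a_inverse()), method="dense")
        W = layout.design_matrix().toarray()[:, : layout.n_fixed]
        rinv = layout.r_inv_per_record(cov.r_diag)
        beta = np.linalg.solve(W.T @ (rinv[:, None] * W), W.T @ (rinv * layout.y))
        assert np.max(np.abs(sol[: layout.n_fixed] - beta)) < 1e-6
        assert np.max(np.abs(sol[layout.n_fixed :])) < 1e-6
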