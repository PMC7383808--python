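"""ssGBLUP solving, SNP back-solving and window variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from thermoherd.genomics import GenotypeData, centered_genotypes
from thermoherd.model_mme import build_design, solve_mme, assemble_mme
from thermoherd.scan import (
    EFFECT_LABELS,
    SnpEffects,
    backsolve_snp_effects,
    solve_ssgblup,
    top_regions,
    window_variance,
)
from thermoherd.simulate import (
    default_covariances,
    simulate_genotypes,
    simulate_pedigree,
    simulate_records,
    simulate_true_effects,
    simulate_weather,
)
from thermoherd.thermal import daily_thi_table


def geno(codes, positions=None, chroms=None):
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    return GenotypeData(
        animals=[f"a{i}" for i in range(n)],
        codes=codes,
        snp_map=pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(m)],
                "chrom": chroms or ["1"] * m,
                "pos_bp": positions or [1000 * (j + 1) for j in range(m)],
            }
        ),
    )


def small_system(seed=0):
    ped, table = simulate_pedigree(n_founders=6, n_generations=1, seed=seed)
    rng = np.random.default_rng(seed + 50)
    cows = table.loc[table["sex"] == "F", "animal"].tolist() or table["animal"].tolist()
    n = 24
    records = pd.DataFrame(
        {
            "cow": rng.choice(cows[:4], size=n),
            "parity": rng.integers(1, 4, size=n),
            "herd": rng.choice(["H1", "H2"], size=n),
            "date": rng.choice(["2014-06-01", "2014-07-01"], size=n),
            "dim": rng.integers(30, 70, size=n),
            "outcome": rng.normal(0.35, 0.4, size=n),
            "f_thi": np.where(rng.random(n) < 0.5, 0.0, rng.uniform(1, 12, n)),
        }
    )
    return ped, build_design(records, ped)


class TestSolve:
    def test_matches_dense_direct_solve(self):
        ped, layout = small_system(1)
        cov = default_covariances()
        bv = solve_ssgblup(layout, cov, ped.a_inverse())
        lhs, rhs = assemble_mme(layout, cov, ped.a_inverse())
        dense = solve_mme(lhs, rhs, method="dense")
        assert np.max(np.abs(bv.solution - dense)) < 1e-8

    def test_zero_phenotypes_zero_gebvs(self):
        ped, layout = small_system(2)
        layout.y[:] = 0.0
        bv = solve_ssgblup(layout, default_covariances(), ped.a_inverse())
        assert np.all(bv.values == 0.0)

    def test_effect_labels_ordering(self):
        ped, layout = small_system(3)
        bv = solve_ssgblup(layout, default_covariances(), ped.a_inverse())
        g0 = layout.genetic_offset
        first = layout.pedigree_ids[0]
        for k, label in enumerate(EFFECT_LABELS):
            assert bv.for_animals([first]).effect(label)[0] == bv.solution[g0 + k]


class TestBacksolve:
    def test_zero_gebv_zero_effects(self, rng):
        g = geno(rng.integers(0, 3, size=(8, 5)))
        s = backsolve_snp_effects(np.zeros(8), g, blend_alpha=1.0)
        assert np.all(s.values == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_recovery_full_column_rank(self, seed):
        """u = Z s0 with full-column-rank Z returns exactly s0."""
        rng = np.random.default_rng(seed)
        n, m = 30, 10
        codes = rng.integers(0, 3, size=(n, m)).astype(float)
        g = geno(codes)
        Z, _, _ = centered_genotypes(g)
        assert np.linalg.matrix_rank(Z) == m
        s0 = rng.standard_normal(m)
        s = backsolve_snp_effects(Z @ s0, g, blend_alpha=1.0)
        assert np.allclose(s.values, s0, atol=1e-8)

    def test_three_by_two_dense_oracle(self):
        codes = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        g = geno(codes)
        Z, _, _ = centered_genotypes(g)
        u = np.array([0.3, -0.1, -0.2])
        s = backsolve_snp_effects(u, g, blend_alpha=1.0)
        oracle = Z.T @ np.linalg.pinv(Z @ Z.T) @ u
        assert np.allclose(s.values, oracle, atol=1e-10)

    def test_blended_matches_manual_formula(self, rng):
        codes = rng.integers(0, 3, size=(6, 4)).astype(float)
        g = geno(codes)
        Z, _, k = centered_genotypes(g)
        u = rng.standard_normal(6)
        a22 = np.eye(6)
        s = backsolve_snp_effects(u, g, blend_alpha=0.9, a22=a22)
        M = 0.9 * Z @ Z.T + 0.1 * k * a22
        assert np.allclose(s.values, Z.T @ np.linalg.solve(M, u), atol=1e-10)

    def test_remultiplication_reproduces_projection(self, rng):
        n, m = 12, 20  # more SNPs than animals: u projects onto row space
        codes = rng.integers(0, 3, size=(n, m)).astype(float)
        g = geno(codes)
        Z, _, _ = centered_genotypes(g)
        u = rng.standard_normal(n)
        s = backsolve_snp_effects(u, g, blend_alpha=1.0)
        P = Z @ np.linalg.pinv(Z)  # projector onto the column space of Z
        assert np.max(np.abs(Z @ s.values - P @ u)) < 1e-6


class TestWindowVariance:
    def test_single_window_explains_everything(self, rng):
        codes = rng.integers(0, 3, size=(20, 6)).astype(float)
        g = geno(codes, positions=[1000 + 100 * j for j in range(6)])
        Z, _, _ = centered_genotypes(g)
        svals = rng.standard_normal(6)
        u = Z @ svals
        s = SnpEffects(effect="v1", values=svals, snp_map=g.snp_map)
        res = window_variance(s, g, window_mb=2.0, u=u)
        assert res["pct_variance"].iloc[0] == pytest.approx(100.0)
        assert res["n_snps"].iloc[0] == 6

    def test_zero_effects_zero_percentage(self, rng):
        codes = rng.integers(0, 3, size=(10, 4)).astype(float)
        g = geno(codes)
        s = SnpEffects(effect="a1", values=np.zeros(4), snp_map=g.snp_map)
        res = window_variance(s, g, sigma_u2=1.0)
        assert np.all(res["pct_variance"] == 0.0)

    def test_orthogonal_windows_sum_to_hundred(self):
        # two distant SNPs with orthogonal centered genotype vectors
        codes = np.array([[0.0, 0.0], [2.0, 1.0], [0.0, 2.0], [2.0, 1.0]])
        g = geno(codes, positions=[1_000_000, 9_000_000])
        Z, _, _ = centered_genotypes(g)
        assert Z[:, 0] @ Z[:, 1] == pytest.approx(0.0)
        svals = np.array([0.7, -1.3])
        u = Z @ svals
        res = window_variance(
            SnpEffects(effect="v1", values=svals, snp_map=g.snp_map), g, window_mb=2.0, u=u, mode="distinct"
        )
        occupied = res[res["n_snps"] > 0]
        assert len(occupied) == 2
        assert occupied["pct_variance"].sum() == pytest.approx(100.0)

    def test_sliding_windows_anchor_at_snps(self, rng):
        codes = rng.integers(0, 3, size=(8, 5)).astype(float)
        positions = [1_000_000, 1_500_000, 4_000_000, 4_100_000, 9_000_000]
        g = geno(codes, positions=positions)
        s = SnpEffects(effect="a1", values=rng.standard_normal(5), snp_map=g.snp_map)
        res = window_variance(s, g, sigma_u2=1.0)
        assert list(res["window_start_bp"]) == positions
        assert res["n_snps"].iloc[0] == 2  # SNPs at 1.0 and 1.5 Mb share a window


class TestTopRegions:
    def test_ties_break_by_position(self):
        df = pd.DataFrame(
            {
                "effect": ["v1"] * 3,
                "chrom": ["2", "1", "1"],
                "window_start_bp": [100, 500, 100],
                "window_end_bp": [200, 600, 200],
                "n_snps": [1, 1, 1],
                "pct_variance": [5.0, 5.0, 5.0],
            }
        )
        ranked = top_regions(df)
        assert list(ranked["chrom"]) == ["1", "1", "2"]
        assert list(ranked["window_start_bp"]) == [100, 500, 100]

    def test_n_larger_than_window_count(self):
        df = pd.DataFrame(
            {
                "effect": ["v1"],
                "chrom": ["1"],
                "window_start_bp": [0],
                "window_end_bp": [10],
                "n_snps": [0],
                "pct_variance": [0.0],
            }
        )
        assert len(top_regions(df, 10)) == 1
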