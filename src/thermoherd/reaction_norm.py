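"""Model/Results interface to the heat-stress reaction-norm evaluation.

:class:`HeatStressReactionNormModel` is built from insemination records, a
pedigree and (optionally) genotypes; :meth:`fit` runs the Gibbs sampler and
returns a :class:`ReactionNormResults` carrying posterior summaries of the
variance components and the derived genetic parameters; :meth:`solve`
produces BLUP/ssGBLUP breeding values at fixed variances as a
:class:`BlupSolution`, from which SNP back-solving and window scans hang.

Example
-------
>>> data = simulate.simulate_dataset(seed=1)
>>> model = HeatStressReactionNormModel(data["records"], data["pedigree"])
>>> res = model.fit(GibbsConfig(n_samples=2000, burn_in=500, thin=5, seed=1))
>>> print(res.summary())
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import simulate  # noqa: F401  (used in the docstring example)
from .genomics import GenotypeData, GMatrixConfig, g_matrix, h_inverse, qc_filter
from .gibbs import GibbsChain, GibbsConfig, diagnostics, run_gibbs
from .model_mme import (
    MMEConfig,
    MMELayout,
    RandomEffectCovariances,
    build_design,
    load_records,
)
from .parameters import cross_parity_corrs, posterior_parameter_summary
from .pedigree import Pedigree
from .scan import BreedingValueSet, backsolve_snp_effects, solve_ssgblup, top_regions, window_variance
from .thermal import ThermalConfig, attach_heat_load, daily_thi_table

logger = logging.getLogger(__name__)

__all__ = ["HeatStressReactionNormModel", "ReactionNormResults", "BlupSolution"]


class HeatStressReactionNormModel:
    """Multitrait (parity 1–3) linear repeatability reaction-norm model of
    insemination outcome on the heat load f(THI).

    Parameters
    ----------
    records : DataFrame
        Validated insemination records with an ``f_thi`` column (pass
        ``weather`` instead to have it attached here).
    pedigree : Pedigree
    genotypes : GenotypeData, optional
        Raw genotypes; SNP quality control is applied on construction.
        Genotypes are used only for single-step solutions and scans, never
        for variance-component estimation.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        pedigree: Pedigree,
        genotypes: GenotypeData | None = None,
        weather: pd.DataFrame | None = None,
        thermal: ThermalConfig = ThermalConfig(),
        mme_config: MMEConfig = MMEConfig(),
        g_config: GMatrixConfig = GMatrixConfig(),
    ) -> None:
        if "f_thi" not in records.columns:
            if weather is None:
                raise ValueError("records lack f_thi and no weather was supplied")
            records = attach_heat_load(records, daily_thi_table(weather, thermal), thermal)
        self.thermal = thermal
        self.mme_config = mme_config
        self.g_config = g_config
        self.pedigree = pedigree
        self.layout: MMELayout = build_design(records, pedigree, mme_config)
        self.a_inv = pedigree.a_inverse()
        self.genotypes = None
        self.qc_report = None
        if genotypes is not None:
            in_ped = [a for a in genotypes.animals if a in pedigree._pos]
            if len(in_ped) < len(genotypes.animals):
                logger.warning(
                    "dropping %d genotyped animal(s) absent from the pedigree",
                    len(genotypes.animals) - len(in_ped),
                )
                genotypes = genotypes.subset_animals(in_ped)
            self.genotypes, self.qc_report = qc_filter(genotypes)

    @classmethod
    def from_files(
        cls,
        records_csv,
        pedigree_csv,
        weather_csv,
        genotype_tsv=None,
        snp_map_tsv=None,
        thermal: ThermalConfig = ThermalConfig(),
        mme_config: MMEConfig = MMEConfig(),
        binary_outcome: bool = True,
    ) -> "HeatStressReactionNormModel":
        from .genomics import read_genotype_tsv
        from .pedigree import read_pedigree
        from .thermal import read_weather

        records = load_records(records_csv, mme_config, binary=binary_outcome)
        records["date"] = pd.to_datetime(records["date"]).dt.date
        ped = read_pedigree(pedigree_csv)
        weather = read_weather(weather_csv)
        genotypes = None
        if genotype_tsv is not None:
            genotypes = read_genotype_tsv(genotype_tsv, snp_map_tsv)
        return cls(records, ped, genotypes=genotypes, weather=weather, thermal=thermal, mme_config=mme_config)

    # ------------------------------------------------------------------ fit
    def _default_init(self) -> RandomEffectCovariances:
        vy = float(np.var(self.layout.y)) or 1.0
        phi = np.diag([0.05 * vy, 1e-3 * vy] * 3)
        psi = np.diag([0.05 * vy, 1e-3 * vy] * 3)
        return RandomEffectCovariances(phi=phi, psi=psi, r_diag=np.full(3, 0.9 * vy))

    def fit(
        self,
        config: GibbsConfig = GibbsConfig(),
        init: RandomEffectCovariances | None = None,
    ) -> "ReactionNormResults":
        """Estimate Φ, ψ and R by Gibbs sampling (pedigree metric A^-1)."""
        chain = run_gibbs(self.layout, self.a_inv, init or self._default_init(), config)
        return ReactionNormResults(self, chain)

    # ---------------------------------------------------------------- solve
    def solve(self, cov: RandomEffectCovariances, genomic: bool = True, rtol: float = 1e-10) -> "BlupSolution":
        """BLUP (or single-step GBLUP when genotypes are present) solutions
        at fixed variance components."""
        if genomic and self.genotypes is not None:
            idx = self.pedigree.indices(self.genotypes.animals)
            a22 = self.pedigree.a22(self.genotypes.animals)
            a22_inv = np.linalg.inv(a22)
            G = g_matrix(self.genotypes, self.g_config, a22)
            g_inv = np.linalg.inv(G)
            rel_inv = h_inverse(self.a_inv, a22_inv, g_inv, idx)
        else:
            rel_inv = self.a_inv
            a22 = None
        bv = solve_ssgblup(self.layout, cov, rel_inv, rtol=rtol)
        return BlupSolution(self, bv, cov, a22=a22)


class ReactionNormResults:
    """Posterior results of a Gibbs fit."""

    def __init__(self, model: HeatStressReactionNormModel, chain: GibbsChain) -> None:
        self.model = model
        self.chain = chain
        self.covariances = chain.posterior_mean_covariances()

    @property
    def phi(self) -> np.ndarray:
        return self.covariances.phi

    @property
    def psi(self) -> np.ndarray:
        return self.covariances.psi

    @property
    def r_diag(self) -> np.ndarray:
        return self.covariances.r_diag

    def parameter_table(self, f: float = 10.0) -> pd.DataFrame:
        """Per-parity genetic parameters at heat load f (posterior mean and
        95% HPD; transform-then-summarize)."""
        return posterior_parameter_summary(self.chain, f=f)

    def cross_parity(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return cross_parity_corrs(self.phi)

    def diagnostics(self, plot_path=None) -> pd.DataFrame:
        return diagnostics(self.chain, plot_path=plot_path)

    def summary(self, f: float = 10.0) -> str:
        table = self.parameter_table(f=f)
        lines = [
            "Heat-stress reaction-norm model — Gibbs posterior summary",
            f"records: {self.model.layout.n_records}  animals: {self.model.layout.n_animals}"
            f"  cows: {self.model.layout.n_cows}  retained samples: {self.chain.n_retained}",
            f"parameters evaluated at heat load f = {f:g} (THI = {f + self.model.thermal.thi_threshold:g})",
            "",
            table.to_string(index=False, float_format=lambda x: f"{x: .5f}"),
        ]
        return "\n".join(lines)

    def solve(self, genomic: bool = True) -> "BlupSolution":
        """BLUP/ssGBLUP solutions at the posterior-mean variances."""
        return self.model.solve(self.covariances, genomic=genomic)


class BlupSolution:
    """Breeding-value solutions at fixed variances, with scan helpers."""

    def __init__(
        self,
        model: HeatStressReactionNormModel,
        breeding_values: BreedingValueSet,
        cov: RandomEffectCovariances,
        a22: np.ndarray | None = None,
    ) -> None:
        self.model = model
        self.breeding_values = breeding_values
        self.cov = cov
        self._a22 = a22

    def genotyped_values(self) -> BreedingValueSet:
        if self.model.genotypes is None:
            raise ValueError("model has no genotypes")
        return self.breeding_values.for_animals(self.model.genotypes.animals)

    def snp_effects(self, effect: str = "v1"):
        g = self.model.genotypes
        if g is None:
            raise ValueError("SNP back-solving requires genotypes")
        u = self.genotyped_values().effect(effect)
        return backsolve_snp_effects(
            u, g, effect=effect, blend_alpha=self.model.g_config.blend_alpha, a22=self._a22
        )

    def window_scan(self, effect: str = "v1", window_mb: float = 2.0, mode: str = "sliding") -> pd.DataFrame:
        s = self.snp_effects(effect)
        u = self.genotyped_values().effect(effect)
        return window_variance(s, self.model.genotypes, window_mb=window_mb, u=u, mode=mode)

    def top_regions(self, effect: str = "v1", n: int = 10, **kwargs) -> pd.DataFrame:
        return top_regions(self.window_scan(effect, **kwargs), n)
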