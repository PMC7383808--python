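"""Genetic parameters as functions of the heat load f.

Scalar components are read from the 6×6 coefficient covariance matrices with
the convention that parity l (1-based) occupies rows/columns (2l-2, 2l-1)
(0-based): intercept variance on the first, slope variance on the second,
their covariance off-diagonal.

Heritability at heat load f is the ratio of the genetic variance of
``a + f v`` to the total variance including permanent-environment and
residual terms; the general-vs-thermotolerance genetic correlation is
``f σ_av / sqrt(σ²_a f² σ²_v)``, which for f > 0 reduces to
``σ_av / (σ_a σ_v)``.  Posterior reports transform each retained draw and
then summarize (transform-then-summarize), which is not the same as
transforming the posterior means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import GibbsChain, hpd_interval
from .model_mme import N_PARITIES, RandomEffectCovariances

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponentSet",
    "extract_components",
    "heritability_at",
    "gen_corr_general_thermo",
    "cross_parity_corrs",
    "posterior_parameter_summary",
]


@dataclass
class VarianceComponentSet:
    """Per-parity scalar variance components.

    sigma_a2/sigma_v2/sigma_av from Φ, sigma_pe2/sigma_q2/sigma_pq from ψ,
    sigma_e2 from R.
    """

    sigma_a2: float
    sigma_v2: float
    sigma_av: float
    sigma_pe2: float
    sigma_q2: float
    sigma_pq: float
    sigma_e2: float


def extract_components(cov: RandomEffectCovariances, parity: int) -> VarianceComponentSet:
    """Scalar components for one parity from Φ/ψ/R."""
    ii, _ = RandomEffectCovariances.sigma_index(parity, "intercept")
    jj, _ = RandomEffectCovariances.sigma_index(parity, "slope")
    return VarianceComponentSet(
        sigma_a2=float(cov.phi[ii, ii]),
        sigma_v2=float(cov.phi[jj, jj]),
        sigma_av=float(cov.phi[ii, jj]),
        sigma_pe2=float(cov.psi[ii, ii]),
        sigma_q2=float(cov.psi[jj, jj]),
        sigma_pq=float(cov.psi[ii, jj]),
        sigma_e2=float(cov.r_diag[parity - 1]),
    )


def heritability_at(v: VarianceComponentSet, f: float) -> float:
    """Heritability of conception at heat load f.

    ``(σ²a + f²σ²v + 2fσav) / (σ²a + f²σ²v + 2fσav + σ²pe + f²σ²q + 2fσpq + σ²e)``

    A negative numerator (possible for strongly negative σav at moderate f)
    is returned as-is with a logged warning, never clipped.
    """
    num = v.sigma_a2 + f**2 * v.sigma_v2 + 2 * f * v.sigma_av
    den = num + v.sigma_pe2 + f**2 * v.sigma_q2 + 2 * f * v.sigma_pq + v.sigma_e2
    if den <= 0:
        raise ValueError("total variance at this heat load is not positive")
    if num < 0:
        logger.warning("negative genetic variance at f=%g (sigma_av=%g)", f, v.sigma_av)
    return num / den


def gen_corr_general_thermo(v: VarianceComponentSet, f: float) -> float:
    """Genetic correlation between the general (intercept) and
    thermotolerance (slope scaled by f) effects: f σav / sqrt(σ²a f² σ²v)."""
    if f == 0:
        raise ValueError("the general/thermotolerance correlation is undefined at f = 0")
    if v.sigma_a2 <= 0 or v.sigma_v2 <= 0:
        raise ValueError("intercept and slope variances must be positive")
    return f * v.sigma_av / np.sqrt(v.sigma_a2 * f**2 * v.sigma_v2)


def cross_parity_corrs(phi: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations among the parities' intercepts (cor_gen) and among their
    slopes (cor_ht).

    Returns two long tables with columns parity_i, parity_j, corr.
    """
    phi = np.asarray(phi, dtype=float)
    out = []
    for kind, offset in (("cor_gen", 0), ("cor_ht", 1)):
        rows = []
        idx = [2 * l + offset for l in range(N_PARITIES)]
        var = phi[idx, idx]
        if np.any(var <= 0):
            raise ValueError(f"zero variance on a coefficient; {kind} undefined")
        for a in range(N_PARITIES):
            for b in range(a + 1, N_PARITIES):
                rows.append(
                    {
                        "parity_i": a + 1,
                        "parity_j": b + 1,
                        "corr": phi[idx[a], idx[b]] / np.sqrt(var[a] * var[b]),
                    }
                )
        out.append(pd.DataFrame(rows))
    return out[0], out[1]


def _draw_components(chain: GibbsChain, k: int, parity: int) -> VarianceComponentSet:
    cov = RandomEffectCovariances(phi=chain.phi[k], psi=chain.psi[k], r_diag=chain.r_diag[k])
    return extract_components(cov, parity)


def posterior_parameter_summary(chain: GibbsChain, f: float = 10.0, prob: float = 0.95) -> pd.DataFrame:
    """Per-parity posterior report of the genetic parameters at heat load f.

    Each retained draw is transformed first (heritability, correlation), then
    the transformed chains are summarized by mean and HPD interval.  Rows use
    the customary scalings: sigma_a2, 100sigma_v2, 10sigma_av, sigma_e2,
    h2_f, r_av.
    """
    if chain.n_retained == 0:
        raise ValueError("empty chain")
    rows = []
    for parity in range(1, N_PARITIES + 1):
        comps = [_draw_components(chain, k, parity) for k in range(chain.n_retained)]
        series = {
            "sigma_a2": np.array([c.sigma_a2 for c in comps]),
            "100sigma_v2": 100 * np.array([c.sigma_v2 for c in comps]),
            "10sigma_av": 10 * np.array([c.sigma_av for c in comps]),
            "sigma_e2": np.array([c.sigma_e2 for c in comps]),
            f"h2_f{f:g}": np.array([heritability_at(c, f) for c in comps]),
            "r_av": np.array([gen_corr_general_thermo(c, f) for c in comps]),
        }
        for name, vals in series.items():
            if len(vals) >= 2:
                lo, hi = hpd_interval(vals, prob)
            else:
                lo = hi = float(vals[0])
            rows.append(
                {
                    "parity": parity,
                    "parameter": name,
                    "mean": float(vals.mean()),
                    "hpd_low": lo,
                    "hpd_high": hi,
                }
            )
    return pd.DataFrame(rows)
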