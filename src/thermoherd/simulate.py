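"""Synthetic herd generator with known truth.

Emulates the statistical structure of a subtropical dairy fertility study:
a multi-generation random-mating pedigree, unlinked biallelic SNPs
gene-dropped through it, hourly weather whose daily mean THI spans the
heat-stress threshold, and per-parity insemination outcomes generated from
herd-day and DIM-class fixed effects plus genetic and permanent-environment
intercept+slope effects with user-specified Φ, ψ and R.

Default variance magnitudes follow the per-parity scale typical of conception
traits: general genetic variances 0.002–0.008, thermotolerance (slope)
variances 5e-5–1.5e-4, negative intercept–slope covariances, residual
variances ≈ 0.2 on the 0/1 outcome scale.  The Gaussian outcome mode is the
default for exact-model recovery experiments; the Bernoulli mode maps the
linear predictor through a clipped-linear probability for realism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenotypeData
from .model_mme import RandomEffectCovariances
from .pedigree import Pedigree
from .thermal import ThermalConfig, daily_thi_table, heat_load, thi

logger = logging.getLogger(__name__)

__all__ = [
    "default_phi",
    "default_psi",
    "default_r",
    "default_covariances",
    "SimulationTruth",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_true_effects",
    "simulate_weather",
    "simulate_records",
    "simulate_annotation",
    "simulate_dataset",
]

DEFAULT_CHROM_LENGTHS = {str(c): 100_000_000 for c in range(1, 6)}


def default_phi() -> np.ndarray:
    """Genetic coefficient covariance with per-parity magnitudes 0.002–0.008
    (intercept), 5e-5–1.5e-4 (slope), negative intercept–slope covariances,
    and the across-parity correlation pattern typical of conception traits."""
    sa2 = np.array([0.002, 0.004, 0.008])
    sv2 = np.array([5e-5, 9e-5, 1.5e-4])
    sav = np.array([-1e-4, -3e-4, -8e-4])
    cor_gen = {(0, 1): 0.58, (0, 2): 0.83, (1, 2): 0.88}
    cor_ht = {(0, 1): 0.17, (0, 2): 0.49, (1, 2): 0.32}
    r_av = sav / np.sqrt(sa2 * sv2)

    def cg(i, j):
        return 1.0 if i == j else cor_gen[(min(i, j), max(i, j))]

    def ch(i, j):
        return 1.0 if i == j else cor_ht[(min(i, j), max(i, j))]

    # cross intercept-slope correlations follow the path rule
    # corr(a_i, v_j) = cor_gen(i, j) * r_av(j), which keeps the matrix PD
    C = np.eye(6)
    for i in range(3):
        for j in range(3):
            C[2 * i, 2 * j] = cg(i, j)
            C[2 * i + 1, 2 * j + 1] = ch(i, j)
            C[2 * i, 2 * j + 1] = C[2 * j + 1, 2 * i] = cg(i, j) * r_av[j]
    sd = np.sqrt(np.concatenate([[sa2[l], sv2[l]] for l in range(3)]))
    phi = C * np.outer(sd, sd)
    assert np.linalg.eigvalsh(phi).min() > 0
    return phi


def default_psi() -> np.ndarray:
    """Permanent-environment coefficient covariance (no across-parity
    covariance; intercept 0.006, slope 5e-5, zero intercept–slope cov)."""
    return np.diag([0.006, 5e-5, 0.006, 5e-5, 0.006, 5e-5]).astype(float)


def default_r() -> np.ndarray:
    return np.array([0.20, 0.19, 0.18])


def default_covariances() -> RandomEffectCovariances:
    return RandomEffectCovariances(phi=default_phi(), psi=default_psi(), r_diag=default_r())


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside a synthetic data set."""

    phi: np.ndarray
    psi: np.ndarray
    r_diag: np.ndarray
    coefficients: np.ndarray  # pedigree-ordered animals × 6 true genetic values
    seed: int
    snp_effects: np.ndarray | None = None  # SNPs × 6, genomic mode only
    qtl_indices: dict = field(default_factory=dict)  # effect label -> SNP indices
    planted_set_id: str | None = None

    def to_json(self, path) -> None:
        payload = {
            "phi": self.phi.tolist(),
            "psi": self.psi.tolist(),
            "r_diag": self.r_diag.tolist(),
            "seed": self.seed,
            "qtl_indices": {k: list(map(int, v)) for k, v in self.qtl_indices.items()},
            "planted_set_id": self.planted_set_id,
            "coefficients": self.coefficients.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ------------------------------------------------------------------ pedigree
def simulate_pedigree(
    n_founders: int = 100,
    n_generations: int = 3,
    offspring_per_mating: int = 2,
    seed: int = 0,
):
    """Random-mating multi-generation pedigree.

    Founders alternate male/female; each later generation makes
    ``n_founders // 2`` matings of a random sire and dam from the previous
    generation (sampled with replacement), each producing
    ``offspring_per_mating`` offspring of random sex.  Total animals =
    ``n_founders + n_generations * (n_founders // 2) * offspring_per_mating``.

    Returns ``(Pedigree, table)`` where the table adds sex ('M'/'F') and
    generation columns.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    rows = []
    next_id = 1
    prev_gen: list[tuple[str, str]] = []  # (id, sex)
    for i in range(n_founders):
        sex = "M" if i % 2 == 0 else "F"
        rows.append({"animal": str(next_id), "sire": "0", "dam": "0", "sex": sex, "generation": 0})
        prev_gen.append((str(next_id), sex))
        next_id += 1
    n_matings = n_founders // 2
    for gen in range(1, n_generations + 1):
        males = [a for a, s in prev_gen if s == "M"]
        females = [a for a, s in prev_gen if s == "F"]
        if not males or not females:
            raise ValueError(f"generation {gen - 1} lacks one sex; cannot mate")
        cur = []
        for _ in range(n_matings):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            for _ in range(offspring_per_mating):
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append({"animal": str(next_id), "sire": sire, "dam": dam, "sex": sex, "generation": gen})
                cur.append((str(next_id), sex))
                next_id += 1
        prev_gen = cur
    table = pd.DataFrame(rows)
    return Pedigree.from_frame(table[["animal", "sire", "dam"]]), table


# ----------------------------------------------------------------- genotypes
def simulate_genotypes(
    ped: Pedigree,
    n_snps: int = 1000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom_lengths: dict | None = None,
    seed: int = 0,
) -> GenotypeData:
    """Unlinked biallelic SNPs gene-dropped through the pedigree.

    Founder alleles are drawn at per-SNP frequencies uniform on
    ``maf_range``; offspring receive one random allele per parent per SNP
    (Mendelian transmission without linkage).  Unknown parents contribute
    population-frequency alleles.  Positions are uniform on the chromosomes,
    allocated proportionally to length.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)
    n = len(ped)
    p = rng.uniform(lo, hi, size=n_snps)

    hap = np.zeros((2, n, n_snps), dtype=np.int8)
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        for h, parent in ((0, s), (1, d)):
            if parent == -1:
                hap[h, i] = rng.random(n_snps) < p
            else:
                pick = rng.integers(0, 2, size=n_snps)
                hap[h, i] = hap[pick, parent, np.arange(n_snps)]
    codes = (hap[0] + hap[1]).astype(float)

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    counts[: n_snps - counts.sum()] += 1
    chrom_col, pos_col = [], []
    for c, cnt in zip(chroms, counts):
        pos = np.sort(rng.integers(1, chrom_lengths[c], size=cnt))
        chrom_col += [c] * cnt
        pos_col += pos.tolist()
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:06d}" for i in range(n_snps)],
            "chrom": chrom_col,
            "pos_bp": pos_col,
        }
    )
    return GenotypeData(animals=list(ped.ids), codes=codes, snp_map=snp_map)


# ------------------------------------------------------------- true effects
def simulate_true_effects(
    ped: Pedigree,
    phi: np.ndarray | None = None,
    seed: int = 0,
    mode: str = "pedigree",
    genotypes: GenotypeData | None = None,
    qtl: dict | None = None,
    qtl_frac: float = 0.3,
) -> SimulationTruth:
    """True genetic intercept/slope coefficients for every pedigree animal.

    ``mode='pedigree'``: founders ~ MVN(0, Φ); offspring = parent average +
    Mendelian deviation with covariance ½Φ (¾Φ / Φ with one / both parents
    unknown; parental inbreeding ignored).

    ``mode='genomic'``: each coefficient is ``Z s`` with a polygenic SNP
    background plus planted QTL blocks (``qtl``: effect label -> SNP index
    array) that carry ``qtl_frac`` of the coefficient's variance; each
    coefficient is rescaled so its realized variance matches the Φ diagonal.
    """
    phi = default_phi() if phi is None else np.asarray(phi, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(ped)
    if mode == "pedigree":
        L = np.linalg.cholesky(phi)
        u = np.zeros((n, 6))
        z = rng.standard_normal((n, 6))
        for i in range(n):
            s, d = int(ped.sire[i]), int(ped.dam[i])
            known = (s != -1) + (d != -1)
            factor = {0: 1.0, 1: 0.75, 2: 0.5}[known]
            mean = np.zeros(6)
            if s != -1:
                mean += 0.5 * u[s]
            if d != -1:
                mean += 0.5 * u[d]
            u[i] = mean + np.sqrt(factor) * (L @ z[i])
        return SimulationTruth(
            phi=phi, psi=default_psi(), r_diag=default_r(), coefficients=u, seed=seed
        )
    if mode != "genomic":
        raise ValueError("mode must be 'pedigree' or 'genomic'")
    if genotypes is None:
        raise ValueError("genomic mode needs genotypes")
    from .genomics import centered_genotypes
    from .scan import EFFECT_LABELS

    Z, _, _ = centered_genotypes(genotypes)
    geno_pos = {a: i for i, a in enumerate(genotypes.animals)}
    m = genotypes.n_snps
    qtl = qtl or {}
    s_all = np.zeros((m, 6))
    u = np.zeros((n, 6))
    for e, label in enumerate(EFFECT_LABELS):
        s_bg = rng.standard_normal(m)
        u_bg = Z @ s_bg
        target = phi[e, e]
        var_bg = float(np.var(u_bg))
        idx = np.asarray(qtl.get(label, []), dtype=int)
        if idx.size:
            s_q = np.zeros(m)
            s_q[idx] = rng.standard_normal(idx.size) + np.sign(rng.standard_normal())
            u_q = Z @ s_q
            var_q = float(np.var(u_q))
            s_e = (
                s_bg * np.sqrt((1 - qtl_frac) * target / max(var_bg, 1e-30))
                + s_q * np.sqrt(qtl_frac * target / max(var_q, 1e-30))
            )
        else:
            s_e = s_bg * np.sqrt(target / max(var_bg, 1e-30))
        u_geno = Z @ s_e
        s_all[:, e] = s_e
        # non-genotyped pedigree animals get zero genetic value in this mode
        for a, gi in geno_pos.items():
            u[ped.index_of(a), e] = u_geno[gi]
    return SimulationTruth(
        phi=phi,
        psi=default_psi(),
        r_diag=default_r(),
        coefficients=u,
        seed=seed,
        snp_effects=s_all,
        qtl_indices={k: np.asarray(v, dtype=int) for k, v in qtl.items()},
    )


# ------------------------------------------------------------------ weather
def simulate_weather(n_days: int = 365, start: str = "2014-01-01", seed: int = 0) -> pd.DataFrame:
    """Hourly weather whose daily mean THI spans roughly 55–85.

    Daily mean temperature follows a seasonal sinusoid (22 ± 8 °C) with
    day-to-day noise and a diurnal cycle; relative humidity varies around
    70%.  About half of the days fall above the THI = 68 threshold,
    mirroring a subtropical climate.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D").date
    rows = []
    for d_i, date in enumerate(dates):
        base = 22.0 + 8.0 * np.sin(2 * np.pi * (d_i - 80) / 365.25) + rng.normal(0, 2.0)
        rh_base = float(np.clip(70.0 + rng.normal(0, 8.0), 30.0, 100.0))
        for hour in range(24):
            temp = base + 4.0 * np.sin(2 * np.pi * (hour - 9) / 24) + rng.normal(0, 0.5)
            rh = float(np.clip(rh_base + rng.normal(0, 3.0), 0.0, 100.0))
            rows.append({"date": date, "hour": hour, "temp_c": round(temp, 2), "rh_pct": round(rh, 1)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ records
def simulate_records(
    ped: Pedigree,
    ped_table: pd.DataFrame,
    truth: SimulationTruth,
    daily_thi: pd.DataFrame,
    n_cows: int = 500,
    n_herds: int = 2,
    records_per_parity: int = 2,
    seed: int = 0,
    outcome_mode: str = "gaussian",
    base_rate: float = 0.35,
    htd_sd: float = 0.05,
    dim_sd: float = 0.02,
    n_insem_dates: int = 52,
    thermal: ThermalConfig = ThermalConfig(),
) -> pd.DataFrame:
    """Per-parity insemination records under the reaction-norm model.

    Cows are the latest-generation females (up to ``n_cows``).  Each cow
    receives ``records_per_parity`` inseminations in each of parities 1–3 at
    random dates drawn from ``n_insem_dates`` evenly spaced insemination
    days (herds inseminate on scheduled days, which keeps herd-date
    contemporary groups to a realistic size); the linear predictor is
    HTD + DIM-class + a + pe + f(THI)(v + q).  Gaussian mode adds N(0, σ²e)
    and emits the continuous value; Bernoulli mode clips the predictor to
    [0, 1] (logging the clipped count) and draws the 0/1 outcome.
    """
    rng = np.random.default_rng(seed)
    females = ped_table.loc[ped_table["sex"] == "F"].sort_values("generation")
    cows = females["animal"].tolist()[-n_cows:]
    if not cows:
        raise ValueError("no female animals available as cows")
    psi = truth.psi
    Lp = np.linalg.cholesky(psi + 1e-14 * np.eye(6))
    pe = {c: Lp @ rng.standard_normal(6) for c in cows}

    day_pool = np.linspace(0, len(daily_thi) - 1, min(n_insem_dates, len(daily_thi))).astype(int)
    dates = [daily_thi["date"].iloc[i] for i in day_pool]
    thi_vals = daily_thi["thi_mean"].to_numpy()[day_pool]
    f_vals = heat_load(thi_vals, thermal)

    htd_effects: dict = {}
    dim_effects: dict = {}
    rows = []
    n_clipped = 0
    for cow in cows:
        ui = truth.coefficients[ped.index_of(cow)]
        for parity in (1, 2, 3):
            for _ in range(records_per_parity):
                di = int(rng.integers(len(dates)))
                herd = f"H{1 + int(rng.integers(n_herds))}"
                dim = int(rng.integers(30, 281))
                dclass = int(np.ceil(dim / 20))
                hkey = (herd, dates[di], parity)
                if hkey not in htd_effects:
                    htd_effects[hkey] = base_rate + rng.normal(0, htd_sd)
                if dclass not in dim_effects:
                    dim_effects[dclass] = rng.normal(0, dim_sd)
                f = float(f_vals[di])
                l0 = 2 * (parity - 1)
                pred = (
                    htd_effects[hkey]
                    + dim_effects[dclass]
                    + ui[l0]
                    + pe[cow][l0]
                    + f * (ui[l0 + 1] + pe[cow][l0 + 1])
                )
                if outcome_mode == "gaussian":
                    y = pred + rng.normal(0, np.sqrt(truth.r_diag[parity - 1]))
                elif outcome_mode == "bernoulli":
                    prob = pred
                    if prob < 0.0 or prob > 1.0:
                        n_clipped += 1
                        prob = min(max(prob, 0.0), 1.0)
                    y = float(rng.random() < prob)
                else:
                    raise ValueError("outcome_mode must be 'gaussian' or 'bernoulli'")
                rows.append(
                    {
                        "cow": cow,
                        "parity": parity,
                        "herd": herd,
                        "date": dates[di],
                        "dim": dim,
                        "outcome": y,
                        "thi_mean": float(thi_vals[di]),
                        "f_thi": f,
                    }
                )
    if n_clipped:
        logger.warning("clipped %d linear predictor(s) outside [0, 1] in bernoulli mode", n_clipped)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- annotation
def simulate_annotation(
    chrom_lengths: dict | None = None,
    n_genes: int = 300,
    n_sets: int = 30,
    planted_set_size: int = 10,
    seed: int = 0,
    qtl_positions: list[tuple[str, int]] | None = None,
    set_size_range: tuple[int, int] = (5, 25),
):
    """Random gene annotation and gene sets, plus one planted set.

    Planted-set genes are placed directly over the supplied QTL SNP
    positions (within the 15 kb assignment flank by construction).  Returns
    ``(genes, sets, planted_set_id)``; ``planted_set_id`` is None when no
    QTL positions are given.
    """
    from .enrichment import GeneModel

    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        c = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(10_000, 60_000))
        start = int(rng.integers(1, max(chrom_lengths[c] - length, 2)))
        genes.append(GeneModel(gene_id=f"gene{i + 1:05d}", chrom=c, start=start, end=start + length))
    planted_ids: list[str] = []
    if qtl_positions:
        for j, (c, pos) in enumerate(qtl_positions[:planted_set_size]):
            start = max(1, int(pos) - 5_000)
            gid = f"qtlgene{j + 1:03d}"
            genes.append(GeneModel(gene_id=gid, chrom=str(c), start=start, end=start + 10_000))
            planted_ids.append(gid)
    all_ids = [g.gene_id for g in genes]
    sets: dict[str, set] = {}
    for k in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = rng.choice(len(all_ids), size=min(size, len(all_ids)), replace=False)
        sets[f"set{k + 1:04d}"] = {all_ids[i] for i in members}
    planted_set_id = None
    if planted_ids:
        planted_set_id = "set_planted"
        sets[planted_set_id] = set(planted_ids)
    return genes, sets, planted_set_id


# -------------------------------------------------------------- orchestrator
def simulate_dataset(out_dir=None, seed: int = 0, n_founders: int = 100, n_generations: int = 3,
                     n_snps: int = 1000, n_cows: int = 200, records_per_parity: int = 2,
                     outcome_mode: str = "bernoulli", n_days: int = 365):
    """Generate a complete synthetic data set; optionally write the standard
    file layout (pedigree.csv, genotypes.tsv, snp_map.tsv, weather.csv,
    records.csv, genes.tsv, sets.gmt, truth.json) to ``out_dir``."""
    from .enrichment import write_gmt

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    ped, table = simulate_pedigree(n_founders, n_generations, 2, seeds[0])
    genotypes = simulate_genotypes(ped, n_snps=n_snps, seed=seeds[1])
    truth = simulate_true_effects(ped, seed=seeds[2])
    weather = simulate_weather(n_days=n_days, seed=seeds[3])
    daily = daily_thi_table(weather)
    records = simulate_records(
        ped, table, truth, daily, n_cows=n_cows, records_per_parity=records_per_parity,
        seed=seeds[4], outcome_mode=outcome_mode,
    )
    genes, sets, planted = simulate_annotation(seed=seeds[5])
    truth.planted_set_id = planted
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        table[["animal", "sire", "dam"]].to_csv(f"{out_dir}/pedigree.csv", index=False)
        geno = pd.DataFrame(genotypes.codes, columns=genotypes.snp_map["snp_id"])
        geno.insert(0, "animal", genotypes.animals)
        geno.to_csv(f"{out_dir}/genotypes.tsv", sep="\t", index=False)
        genotypes.snp_map.to_csv(f"{out_dir}/snp_map.tsv", sep="\t", index=False)
        weather.to_csv(f"{out_dir}/weather.csv", index=False)
        records.drop(columns=["thi_mean", "f_thi"]).to_csv(f"{out_dir}/records.csv", index=False)
        pd.DataFrame(
            [{"chrom": g.chrom, "start": g.start, "end": g.end, "gene_id": g.gene_id} for g in genes]
        ).to_csv(f"{out_dir}/genes.tsv", sep="\t", index=False)
        write_gmt(sets, f"{out_dir}/sets.gmt")
        truth.to_json(f"{out_dir}/truth.json")
    return {
        "pedigree": ped,
        "pedigree_table": table,
        "genotypes": genotypes,
        "truth": truth,
        "weather": weather,
        "daily_thi": daily,
        "records": records,
        "genes": genes,
        "sets": sets,
    }
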