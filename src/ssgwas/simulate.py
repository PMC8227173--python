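"""Synthetic pedigree/genotype/phenotype generator.

Emulates the data structure the single-step evaluation assumes: a
multi-generation pedigree with a genotyped recent subset, biallelic
autosomal SNPs gene-dropped through the pedigree (founder alleles drawn
from a uniform MAF spectrum; cosegregation is the only source of LD —
a stated limitation), a sparse set of QTL windows carrying chosen shares
of the additive variance, and phenotypes built generatively from the
same fixed/random effect structure the models fit (sex, dam-age class,
optional age covariate, herd-year-season, additive and optionally
maternal genetic effects with a negative direct-maternal covariance).

Every stage is driven by one numpy Generator, so a (config, seed) pair
reproduces a dataset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeData
from .pedigree import Pedigree


@dataclass
class SimConfig:
    """Generator settings.  Default magnitudes echo a weaning-weight-like
    beef-cattle trait (mean ~285 kg, h2 ~ 0.4)."""

    n_founders: int = 240
    n_generations: int = 4
    n_per_generation: int = 500
    genotyped_generations: int = 2  # most recent generations are genotyped
    genotyped_fraction: float = 1.0
    n_snps: int = 3000
    chromosomes: dict = field(default_factory=lambda: {c: 100_000_000 for c in range(1, 11)})
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    n_qtl: int = 1
    qtl_variance_share: float = 0.05  # per QTL, as a fraction of sigma2_a
    maternal: bool = False
    sigma2_a: float = 900.0
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_p: float = 400.0
    sigma2_e: float = 950.0
    mean: float = 285.0
    n_herds: int = 15
    n_seasons: int = 4
    n_dam_age_classes: int = 6
    fixed_effect_sd: float = 10.0
    age_covariate: bool = False
    age_mean: float = 210.0
    age_sd: float = 20.0
    age_slope: float = 0.5
    missing_rate: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "n_per_generation", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_qtl * self.qtl_variance_share > 1.0 + 1e-12:
            raise ValueError("QTL variance shares exceed the additive variance")
        if self.maternal:
            s2poly = self.sigma2_a * (1.0 - self.n_qtl * self.qtl_variance_share)
            if self.sigma2_m <= 0:
                raise ValueError("maternal simulation needs sigma2_m > 0")
            if abs(self.sigma_am) >= np.sqrt(s2poly * self.sigma2_m):
                raise ValueError("sigma_am exceeds the polygenic covariance bound")


@dataclass
class SimulationTruth:
    components: dict
    qtl: pd.DataFrame
    u: np.ndarray
    m: np.ndarray | None
    fixed_effects: dict
    hys_effects: dict

    @property
    def qtl_windows(self) -> pd.DataFrame:
        """QTL windows with their total variance shares."""
        if self.qtl.empty:
            return pd.DataFrame(columns=["chrom", "window", "share", "n_snps"])
        return (self.qtl.groupby(["chrom", "window"], sort=False)
                .agg(share=("share", "sum"), n_snps=("share", "size"))
                .reset_index())

    def to_json(self, path) -> None:
        payload = {
            "components": self.components,
            "qtl": self.qtl.to_dict(orient="records"),
            "fixed_effects": {k: (v if np.isscalar(v) else list(np.asarray(v)))
                              for k, v in self.fixed_effects.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


@dataclass
class SimData:
    pedigree: Pedigree
    meta: pd.DataFrame  # individual, generation, sex
    genotypes: GenotypeData  # observed (genotyped subset, with missingness)
    records: pd.DataFrame
    truth: SimulationTruth
    founder_freq: np.ndarray | None = None  # base-population allele freqs
    haplotypes: np.ndarray | None = None  # (n+1, N, 2) full true haplotypes


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator):
    """Discrete-generation random-mating pedigree; returns the Pedigree
    (already parents-first) and a metadata table."""
    n = cfg.n_founders + cfg.n_generations * cfg.n_per_generation
    sire = np.zeros(n + 1, dtype=np.int64)
    dam = np.zeros(n + 1, dtype=np.int64)
    gen = np.zeros(n + 1, dtype=np.int64)
    sex = np.zeros(n + 1, dtype=np.int64)
    sex[1:cfg.n_founders + 1] = 1 + (np.arange(cfg.n_founders) % 2)
    nxt = cfg.n_founders + 1
    prev = np.arange(1, cfg.n_founders + 1)
    for g in range(1, cfg.n_generations + 1):
        males = prev[sex[prev] == 1]
        females = prev[sex[prev] == 2]
        ids = np.arange(nxt, nxt + cfg.n_per_generation)
        sire[ids] = rng.choice(males, size=len(ids))
        dam[ids] = rng.choice(females, size=len(ids))
        sex[ids] = rng.integers(1, 3, size=len(ids))
        # guarantee both sexes so the next generation can mate
        sex[ids[0]] = 1
        if len(ids) > 1:
            sex[ids[1]] = 2
        gen[ids] = g
        prev = ids
        nxt += cfg.n_per_generation
    labels = np.empty(n + 1, dtype=object)
    labels[0] = None
    labels[1:] = [f"ID{i}" for i in range(1, n + 1)]
    ped = Pedigree(sire=sire, dam=dam, labels=labels)
    meta = pd.DataFrame({"individual": labels[1:], "generation": gen[1:], "sex": sex[1:]})
    # genotyping policy: a fraction of the most recent generations
    recent = gen[1:] > cfg.n_generations - cfg.genotyped_generations
    idx = np.flatnonzero(recent) + 1
    keep = rng.random(len(idx)) < cfg.genotyped_fraction
    mask = np.zeros(n + 1, dtype=bool)
    mask[idx[keep]] = True
    ped.genotyped = mask
    meta["genotyped"] = mask[1:]
    return ped, meta


def _snp_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chromosomes.items())
    lengths = np.array([l for _, l in chroms], dtype=float)
    counts = np.floor(cfg.n_snps * lengths / lengths.sum()).astype(int)
    counts[: cfg.n_snps - counts.sum()] += 1
    rows = []
    for (c, length), k in zip(chroms, counts):
        bp = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        for b in bp:
            rows.append((str(c), b))
    df = pd.DataFrame(rows, columns=["chrom", "bp"])
    df["snp_id"] = [f"snp{c}_{b}" for c, b in zip(df.chrom, df.bp)]
    df["cm"] = 0
    df["minor_allele"] = "A"
    df["major_allele"] = "B"
    return df[["chrom", "snp_id", "cm", "bp", "minor_allele", "major_allele"]]


def simulate_genotypes(ped: Pedigree, cfg: SimConfig, rng: np.random.Generator):
    """Gene-drop haplotypes through the pedigree.

    Founder alleles are Bernoulli draws at per-SNP frequencies uniform on
    [founder_maf_low, founder_maf_high]; each offspring inherits one
    randomly chosen allele per parent, independently across SNPs.
    Returns (haplotypes, snp_map, founder_freq).
    """
    smap = _snp_map(cfg, rng)
    N = len(smap)
    p0 = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, size=N)
    hap = np.zeros((ped.n + 1, N, 2), dtype=np.int8)
    # process individuals in waves of equal pedigree depth so transmission
    # vectorizes; parents always sit in an earlier wave
    depth = np.zeros(ped.n + 1, dtype=np.int64)
    for i in range(1, ped.n + 1):
        s, d = ped.sire[i], ped.dam[i]
        depth[i] = max(depth[s] + 1 if s else 0, depth[d] + 1 if d else 0)
    cols = np.arange(N)
    for lev in range(depth.max() + 1):
        ids = np.flatnonzero(depth[1:] == lev) + 1
        founders = ids[(ped.sire[ids] == 0) & (ped.dam[ids] == 0)]
        if founders.size:
            hap[founders] = rng.random((founders.size, N, 2)) < p0[None, :, None]
        kids = ids[(ped.sire[ids] > 0) | (ped.dam[ids] > 0)]
        if kids.size:
            pick_s = rng.integers(0, 2, size=(kids.size, N))
            pick_d = rng.integers(0, 2, size=(kids.size, N))
            hap[kids, :, 0] = hap[ped.sire[kids][:, None], cols[None, :], pick_s]
            hap[kids, :, 1] = hap[ped.dam[kids][:, None], cols[None, :], pick_d]
    return hap, smap, p0


def observed_genotypes(ped: Pedigree, hap: np.ndarray, smap: pd.DataFrame,
                       cfg: SimConfig, rng: np.random.Generator) -> GenotypeData:
    """Dosage matrix for the genotyped subset, with random missingness."""
    ids = np.flatnonzero(ped.genotyped)
    dos = hap[ids].sum(axis=2).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = np.nan
    return GenotypeData(dosages=dos, snp_map=smap.copy(),
                        sample_ids=ped.labels[ids].copy())


_QTL_COLS = ["snp_index", "chrom", "bp", "window", "effect", "share", "freq"]


def _pick_qtl(hap: np.ndarray, smap: pd.DataFrame, cfg: SimConfig,
              rng: np.random.Generator) -> pd.DataFrame:
    """Pick ``n_qtl`` distinct 1-Mb QTL windows; each window's variance
    share is spread evenly over its well-segregating SNPs (random effect
    signs)."""
    dose = hap[1:].sum(axis=2)
    freq = dose.mean(axis=0) / 2.0
    ok = (freq > 0.1) & (freq < 0.9)
    win = (smap.bp.to_numpy(np.int64) - 1) // 1_000_000
    eligible = {}
    for j in np.flatnonzero(ok):
        eligible.setdefault((smap.chrom.iloc[j], int(win[j])), []).append(j)
    candidates = [k for k, v in eligible.items() if len(v) >= 2]
    if cfg.n_qtl > len(candidates):
        raise ValueError("not enough windows with segregating SNPs to place the QTL")
    chosen = [candidates[i] for i in
              rng.choice(len(candidates), size=cfg.n_qtl, replace=False)]
    rows = []
    for chrom, w in chosen:
        snps = eligible[(chrom, w)]
        k = len(snps)
        for j in snps:
            p = freq[j]
            beta = np.sqrt(cfg.qtl_variance_share * cfg.sigma2_a
                           / (k * 2.0 * p * (1.0 - p)))
            rows.append(dict(snp_index=int(j), chrom=chrom,
                             bp=int(smap.bp.iloc[j]), window=w,
                             effect=float(beta * rng.choice([-1.0, 1.0])),
                             share=float(cfg.qtl_variance_share / k),
                             freq=float(p)))
    return pd.DataFrame(rows, columns=_QTL_COLS)


def simulate_phenotypes(ped: Pedigree, meta: pd.DataFrame, hap: np.ndarray,
                        smap: pd.DataFrame, cfg: SimConfig,
                        rng: np.random.Generator):
    """Breeding values (QTL + pedigree-transmitted polygenic part, plus a
    correlated maternal effect when requested) and phenotype records for
    all non-founder individuals."""
    n = ped.n
    ped.with_inbreeding()
    qtl = _pick_qtl(hap, smap, cfg, rng) if cfg.n_qtl > 0 else pd.DataFrame(
        columns=["snp_index", "chrom", "bp", "window", "effect", "share", "freq"])

    # genetic effects are marker-determined: a planted QTL plus a dense
    # polygenic background of small effects on every other SNP, so the
    # marker-based G is the correct covariance among genotyped animals
    dose = hap.sum(axis=2).astype(float)  # (n+1, N); row 0 unused
    freq = dose[1:].mean(axis=0) / 2.0
    Zc = dose - 2.0 * freq  # centered true dosages
    nonf = slice(1, n + 1)

    u_qtl = np.zeros(n + 1)
    for _, q in qtl.iterrows():
        u_qtl += q.effect * Zc[:, int(q.snp_index)]
    target_qtl = cfg.sigma2_a * cfg.n_qtl * cfg.qtl_variance_share
    if cfg.n_qtl > 0:
        u_qtl *= np.sqrt(target_qtl / np.var(u_qtl[nonf]))

    s2poly = cfg.sigma2_a - target_qtl
    bg = np.ones(Zc.shape[1], dtype=bool)
    if len(qtl):
        bg[qtl["snp_index"].to_numpy()] = False
    t = 2 if cfg.maternal else 1
    S0 = np.array([[s2poly]]) if t == 1 else np.array(
        [[s2poly, cfg.sigma_am], [cfg.sigma_am, cfg.sigma2_m]])
    beta = rng.multivariate_normal(np.zeros(t), S0, size=int(bg.sum()))
    poly = Zc[:, bg] @ beta  # (n+1, t)
    # rescale so the realized non-founder (co)variances match S0 exactly
    C = np.cov(poly[nonf], rowvar=False).reshape(t, t)
    T = np.linalg.cholesky(S0) @ np.linalg.inv(np.linalg.cholesky(C))
    poly = poly @ T.T
    u = u_qtl + poly[:, 0]
    m = poly[:, 1] if cfg.maternal else None

    rec = meta[meta["generation"] > 0].copy().reset_index(drop=True)
    ids = ped.ids_of(rec["individual"])
    nr = len(rec)

    sex_eff = np.array([0.0, rng.normal(0, cfg.fixed_effect_sd)])
    dam_age_eff = rng.normal(0, cfg.fixed_effect_sd, size=cfg.n_dam_age_classes)
    dam_age_eff[0] = 0.0
    rec["dam_age"] = rng.integers(1, cfg.n_dam_age_classes + 1, size=nr)

    herd = rng.integers(1, cfg.n_herds + 1, size=nr)
    season = rng.integers(1, cfg.n_seasons + 1, size=nr)
    year = rec["generation"].to_numpy()
    rec["hys"] = [f"h{h}_y{y}_s{s}" for h, y, s in zip(herd, year, season)]
    levels = sorted(set(rec["hys"]))
    hys_eff = {l: rng.normal(0, np.sqrt(cfg.sigma2_p)) for l in levels}

    y = (cfg.mean
         + sex_eff[rec["sex"].to_numpy() - 1]
         + dam_age_eff[rec["dam_age"].to_numpy() - 1]
         + u[ids]
         + np.array([hys_eff[l] for l in rec["hys"]])
         + rng.normal(0, np.sqrt(cfg.sigma2_e), size=nr))
    fixed = {"mean": cfg.mean, "sex": sex_eff, "dam_age": dam_age_eff}
    if cfg.maternal:
        dams = ped.dam[ids]
        y += m[dams]
    if cfg.age_covariate:
        age = rng.normal(cfg.age_mean, cfg.age_sd, size=nr)
        rec["age"] = age
        y += cfg.age_slope * age
        fixed["age_slope"] = cfg.age_slope
    rec["y"] = y
    rec = rec[[c for c in ("individual", "y", "sex", "dam_age", "age", "hys") if c in rec]]

    components = {"sigma2_a": cfg.sigma2_a, "sigma2_p": cfg.sigma2_p,
                  "sigma2_e": cfg.sigma2_e}
    if cfg.maternal:
        components.update(sigma2_m=cfg.sigma2_m, sigma_am=cfg.sigma_am)
    truth = SimulationTruth(components=components, qtl=qtl, u=u, m=m,
                            fixed_effects=fixed, hys_effects=hys_eff)
    return rec, truth


def simulate_dataset(cfg: SimConfig, seed: int | None = None,
                     keep_haplotypes: bool = False) -> SimData:
    """Run the whole generator: pedigree, gene-dropped genotypes, QTL and
    phenotypes, returning everything plus the ground truth."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ped, meta = simulate_pedigree(cfg, rng)
    hap, smap, p0 = simulate_genotypes(ped, cfg, rng)
    geno = observed_genotypes(ped, hap, smap, cfg, rng)
    records, truth = simulate_phenotypes(ped, meta, hap, smap, cfg, rng)
    return SimData(pedigree=ped, meta=meta, genotypes=geno, records=records,
                   truth=truth, founder_freq=p0,
                   haplotypes=hap if keep_haplotypes else None)


def write_dataset(data: SimData, outdir) -> dict:
    """Write the generated dataset in the formats the readers consume."""
    from pathlib import Path

    from .io import write_pedigree, write_plink_text

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    write_pedigree(data.pedigree, paths["pedigree"])
    write_plink_text(data.genotypes, paths["ped"], paths["map"])
    data.records.to_csv(paths["phenotypes"], index=False)
    data.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# study regimes used by the validation suite

def direct_study_regime(**overrides) -> SimConfig:
    """Direct-model recovery regime: ~2,000 records, 1,000 genotyped,
    3,000 SNPs, h2 = 0.4, one QTL window at 5% of the additive variance."""
    base = dict(n_founders=240, n_generations=4, n_per_generation=500,
                genotyped_generations=2, n_snps=3000, n_qtl=1,
                qtl_variance_share=0.05, sigma2_a=900.0, sigma2_p=400.0,
                sigma2_e=950.0, maternal=False)
    base.update(overrides)
    return SimConfig(**base)


def maternal_study_regime(**overrides) -> SimConfig:
    """Maternal-model recovery regime: ~1,600 records, 400 genotyped,
    1,000 SNPs, r_a,mat = -0.7, no QTL (component recovery, not mapping)."""
    s2a, s2m = 900.0, 300.0
    base = dict(n_founders=200, n_generations=4, n_per_generation=400,
                genotyped_generations=1, n_snps=1000, n_qtl=0,
                maternal=True, sigma2_a=s2a, sigma2_m=s2m,
                sigma_am=-0.7 * np.sqrt(s2a * s2m), sigma2_p=400.0,
                sigma2_e=950.0)
    base.update(overrides)
    return SimConfig(**base)
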