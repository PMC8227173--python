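"""Replicated self-validation runs: simulate under the study-like
regimes, fit the single-step models, and collect recovery/detection
summaries.  Used by the test suite and the reproduction script."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import qc_genotypes
from .model import SingleStepGBLUP
from .simulate import direct_study_regime, maternal_study_regime, simulate_dataset


@dataclass
class DirectReplicate:
    sigma2_a: float
    sigma2_p: float
    sigma2_e: float
    h2: float
    qtl_window_pct: float | None
    n_windows_above: int
    n_regions: int
    window_pct_sum: float
    n_records: int
    n_genotyped: int
    truth: dict


@dataclass
class MaternalReplicate:
    sigma2_a: float
    sigma2_m: float
    sigma_am: float
    sigma2_p: float
    sigma2_e: float
    h2: float
    h2_mat: float
    r_a_mat: float
    n_records: int
    truth: dict


def direct_replicate(seed: int, n_qtl: int = 1, em_rounds: int = 2,
                     tol: float = 1e-4, threshold_pct: float = 0.5) -> DirectReplicate:
    """One direct-model study replicate: simulate, QC, REML fit, backsolve
    and window scan; returns the recovery and detection summary."""
    cfg = direct_study_regime(n_qtl=n_qtl)
    data = simulate_dataset(cfg, seed=seed)
    geno, _ = qc_genotypes(data.genotypes)
    model = SingleStepGBLUP(data.records, data.pedigree, geno)
    res = model.fit(em_rounds=em_rounds, tol=tol)
    g = res.gwas(threshold_pct=threshold_pct)
    qtl_pct = None
    if n_qtl > 0:
        qw = data.truth.qtl_windows.iloc[0]
        hit = g.windows[(g.windows.chrom == qw.chrom) &
                        (g.windows.window == qw.window)]
        qtl_pct = float(hit.pct_var.iloc[0]) if len(hit) else 0.0
    vc = res.varcomp
    return DirectReplicate(
        sigma2_a=vc.sigma2_a, sigma2_p=vc.sigma2_p, sigma2_e=vc.sigma2_e,
        h2=res.genetic_parameters.h2, qtl_window_pct=qtl_pct,
        n_windows_above=int((g.windows.pct_var >= threshold_pct).sum()),
        n_regions=len(g.regions),
        window_pct_sum=float(g.windows.pct_var.sum()),
        n_records=len(data.records), n_genotyped=geno.n_individuals,
        truth=dict(data.truth.components))


def maternal_replicate(seed: int, em_rounds: int = 2,
                       tol: float = 1e-4) -> MaternalReplicate:
    """One maternal-model study replicate (component recovery only)."""
    cfg = maternal_study_regime()
    data = simulate_dataset(cfg, seed=seed)
    geno, _ = qc_genotypes(data.genotypes)
    model = SingleStepGBLUP(data.records, data.pedigree, geno, maternal=True)
    res = model.fit(em_rounds=em_rounds, tol=tol)
    vc = res.varcomp
    gp = res.genetic_parameters
    return MaternalReplicate(
        sigma2_a=vc.sigma2_a, sigma2_m=vc.sigma2_m, sigma_am=vc.sigma_am,
        sigma2_p=vc.sigma2_p, sigma2_e=vc.sigma2_e,
        h2=gp.h2, h2_mat=gp.h2_mat, r_a_mat=gp.r_a_mat,
        n_records=len(data.records), truth=dict(data.truth.components))


def replicate_seeds(base_seed: int, n: int, tag: str) -> list[int]:
    """Independent child seeds (< 2^31) derived from one base seed."""
    import zlib

    ss = np.random.SeedSequence([base_seed, zlib.crc32(tag.encode()) % (2 ** 31)])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def within_3se(estimates: np.ndarray, truth: float) -> bool:
    """Mean estimate within 3 empirical standard errors of the truth."""
    est = np.asarray(estimates, dtype=float)
    se = est.std(ddof=1) / np.sqrt(len(est))
    return abs(est.mean() - truth) <= 3.0 * se
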