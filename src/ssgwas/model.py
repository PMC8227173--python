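"""Model/results objects tying the pipeline together.

:class:`SingleStepGBLUP` is built from a phenotype table, a pedigree and
(optionally) genotypes; ``fit()`` estimates variance components by
EM/AI-REML and solves the mixed-model equations, returning a
:class:`SingleStepResults` that carries the estimates, their standard
errors, the effect solutions, and the downstream GWAS methods
(``backsolve``, ``gwas``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .genotypes import GenotypeData, RelationshipSet, build_relationships, impute_and_center
from .gwas import (SnpEffects, backsolve_snp_effects, select_regions,
                   window_bv_variances, window_variances)
from .mme import TraitModelSpec, build_incidence
from .pedigree import Pedigree, build_A_inverse
from .reml import (GeneticParameters, RemlEngine, VarianceComponents,
                   derive_parameters, logdet_sparse_spd)


class SingleStepGBLUP:
    """Single-step genomic BLUP model for one trait.

    Parameters
    ----------
    records : DataFrame with columns 'individual', the trait, the fixed
        factors/covariates and the herd-year-season label.
    pedigree : renumbered Pedigree covering every phenotyped individual.
    genotypes : GenotypeData for the genotyped subset (already through
        QC), or None for a pedigree-only (H = A) evaluation.
    maternal : include the dam's additive maternal effect (weaning-
        weight-type model) with a direct-maternal covariance.
    blend_weight : weight w of A22 in G_b = (1-w) G + w A22; w = 0 keeps
        the raw marker G (required for the exact backsolving identity).
    """

    def __init__(self, records: pd.DataFrame, pedigree: Pedigree,
                 genotypes: GenotypeData | None = None, trait: str = "y",
                 factors=("sex", "dam_age"), covariates=(), hys: str = "hys",
                 maternal: bool = False, blend_weight: float = 0.05,
                 tune_g_to_a22: bool = False):
        self.records = records
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.spec = TraitModelSpec(trait=trait, factors=tuple(factors),
                                   covariates=tuple(covariates), hys=hys,
                                   maternal=maternal)
        self.blend_weight = blend_weight
        if genotypes is not None:
            genotypes.with_frequencies()
            self.relationships: RelationshipSet | None = build_relationships(
                pedigree, genotypes, blend_weight=blend_weight,
                tune_to_a22=tune_g_to_a22)
            kinv = self.relationships.hinv
        else:
            self.relationships = None
            kinv = build_A_inverse(pedigree)
        logdet_K = -logdet_sparse_spd(kinv)  # log|H| = -log|H^-1|
        self.system = build_incidence(records, self.spec, pedigree, kinv, logdet_K)
        self._engine: RemlEngine | None = None

    @classmethod
    def from_files(cls, pedigree_path, pheno_path, ped_path=None, map_path=None,
                   config: RunConfig | None = None):
        """Build from a pedigree CSV, phenotype CSV and optional PLINK
        text genotypes, applying the configured QC."""
        from .genotypes import qc_genotypes
        from .io import read_pedigree, read_phenotypes, read_plink_text, validate_phenotypes

        cfg = config or RunConfig()
        ped = read_pedigree(pedigree_path, id_policy="add_missing_founders")
        records = read_phenotypes(pheno_path)
        validate_phenotypes(records, ped, cfg.trait_name,
                            [*cfg.fixed_effects, *cfg.covariates, cfg.hys_column])
        geno = None
        if ped_path is not None:
            raw = read_plink_text(ped_path, map_path)
            geno, _ = qc_genotypes(raw, snp_missing_max=cfg.snp_missing_max,
                                   maf_min=cfg.maf_min,
                                   indiv_callrate_min=cfg.indiv_callrate_min)
        return cls(records, ped, geno, trait=cfg.trait_name,
                   factors=tuple(cfg.fixed_effects), covariates=tuple(cfg.covariates),
                   hys=cfg.hys_column, maternal=cfg.model_kind == "maternal",
                   blend_weight=cfg.blend_weight)

    @property
    def engine(self) -> RemlEngine:
        if self._engine is None:
            self._engine = RemlEngine(self.system)
        return self._engine

    def fit(self, start: dict = None, em_rounds: int = 3, tol: float = 1e-6,
            max_iter: int = 50, verbose: bool = False) -> "SingleStepResults":
        """Estimate variance components (EM warm-up + AI-REML) and solve
        the MME at the estimates."""
        reml = self.engine.fit(start=start, em_rounds=em_rounds, tol=tol,
                               max_iter=max_iter, verbose=verbose)
        return self._results(reml.components, reml)

    def solve(self, varcomp: VarianceComponents | dict) -> "SingleStepResults":
        """Solve the MME at fixed, known variance components (no REML)."""
        if isinstance(varcomp, dict):
            k0 = {t.name: np.atleast_2d(np.asarray(varcomp[t.name], float))
                  for t in self.system.terms}
            varcomp = VarianceComponents(k0=k0, sigma2_e=float(varcomp["sigma2_e"]))
        return self._results(varcomp, None)

    def _results(self, vc: VarianceComponents, reml) -> "SingleStepResults":
        state = self.engine._decompose(vc.as_dict())
        sol = state["sol"]
        solutions = {"fixed": dict(zip(self.system.x_labels,
                                       sol[: self.system.X.shape[1]]))}
        for t in self.system.terms:
            for a, name in enumerate(t.effect_names):
                solutions[name] = sol[self.engine._slices[(t.name, a)]]
        solutions["hys"] = dict(zip(self.system.hys_levels, solutions.pop("hys")))
        return SingleStepResults(model=self, varcomp=vc, solutions=solutions,
                                 loglik=self.engine.reml_loglik(vc.as_dict(), state),
                                 reml=reml)


@dataclass
class SingleStepResults:
    """Fitted single-step evaluation."""

    model: SingleStepGBLUP
    varcomp: VarianceComponents
    solutions: dict
    loglik: float
    reml: object | None = None

    @property
    def genetic_parameters(self) -> GeneticParameters:
        return derive_parameters(self.varcomp)

    @property
    def gebv(self) -> np.ndarray:
        """Additive solutions for every pedigree individual."""
        return self.solutions["additive"]

    @property
    def gebv_genotyped(self) -> np.ndarray:
        rel = self.model.relationships
        if rel is None:
            raise ValueError("no genotypes attached to this model")
        return self.gebv[rel.genotyped_ids - 1]

    def backsolve(self) -> SnpEffects:
        """SNP allele-substitution effects from the genotyped GEBVs.

        Uses the raw marker G when blend_weight = 0 (exact projection),
        otherwise the blended G that actually entered H."""
        rel = self.model.relationships
        if rel is None:
            raise ValueError("backsolving requires genotypes")
        geno = self.model.genotypes
        Z = impute_and_center(geno)
        G = rel.g_raw if self.model.blend_weight == 0 else rel.g_blended
        return backsolve_snp_effects(self.gebv_genotyped, Z, G, geno.p_hat)

    def gwas(self, window_size_bp: int = 1_000_000, threshold_pct: float = 0.5,
             window_stat: str = "snp_variance") -> "GwasResult":
        """Windowed-variance association scan from the backsolved SNP
        effects."""
        eff = self.backsolve()
        geno = self.model.genotypes
        if window_stat == "snp_variance":
            windows = window_variances(eff.var_snp, geno.snp_map, window_size_bp)
        elif window_stat == "bv_variance":
            windows = window_bv_variances(eff.g_hat, impute_and_center(geno),
                                          geno.snp_map, window_size_bp)
        else:
            raise ValueError(f"unknown window_stat {window_stat!r}")
        regions = select_regions(windows, threshold_pct)
        return GwasResult(snp_effects=eff, windows=windows, regions=regions,
                          window_size_bp=window_size_bp, threshold_pct=threshold_pct,
                          trait=self.model.spec.trait)

    def summary(self) -> str:
        """Text summary in the layout of a variance-component report:
        estimates (SE), then the derived genetic parameters."""
        vc, lines = self.varcomp, []
        spec = self.model.spec
        kind = "maternal" if spec.maternal else "direct"
        lines.append(f"Single-step GBLUP ({kind} model), trait {spec.trait!r}")
        lines.append(f"records: {self.model.system.n_records}   "
                     f"pedigree: {self.model.pedigree.n}   "
                     f"genotyped: {0 if self.model.relationships is None else len(self.model.relationships.genotyped_ids)}")
        lines.append(f"REML log-likelihood: {self.loglik:.4f}")
        lines.append("")
        lines.append(f"{'component':<12}{'estimate':>14}{'SE':>12}")

        def se_of(term, a, b):
            S = vc.se.get(term)
            return "" if S is None else f"{S[a, b]:.4g}"

        lines.append(f"{'sigma2_p':<12}{vc.sigma2_p:>14.4f}{se_of('hys', 0, 0):>12}")
        lines.append(f"{'sigma2_a':<12}{vc.sigma2_a:>14.4f}{se_of('genetic', 0, 0):>12}")
        if vc.sigma2_m is not None:
            lines.append(f"{'sigma2_m':<12}{vc.sigma2_m:>14.4f}{se_of('genetic', 1, 1):>12}")
            lines.append(f"{'sigma_am':<12}{vc.sigma_am:>14.4f}{se_of('genetic', 0, 1):>12}")
        se_e = "" if vc.se_sigma2_e is None else f"{vc.se_sigma2_e:.4g}"
        lines.append(f"{'sigma2_e':<12}{vc.sigma2_e:>14.4f}{se_e:>12}")
        gp = self.genetic_parameters.rounded()
        lines.append("")
        lines.append(f"h2       = {gp.h2:.3f}")
        if gp.h2_mat is not None:
            lines.append(f"h2_mat   = {gp.h2_mat:.3f}")
            lines.append(f"r_a,mat  = {gp.r_a_mat:.3f}")
        return "\n".join(lines)


@dataclass
class GwasResult:
    """Window-variance scan for one trait."""

    snp_effects: SnpEffects
    windows: pd.DataFrame
    regions: pd.DataFrame
    window_size_bp: int
    threshold_pct: float
    trait: str

    def to_tsv(self, path) -> None:
        from .io import write_window_report
        write_window_report(self.windows, path)

    def to_bed(self, path) -> None:
        from .io import write_regions_bed
        write_regions_bed(self.regions, path)

    def plot_manhattan(self, ax=None):
        """Per-window percent-of-variance Manhattan plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        x0, ticks = 0, []
        for chrom, sub in self.windows.groupby("chrom", sort=True):
            x = x0 + np.arange(len(sub))
            ax.scatter(x, sub["pct_var"], s=8)
            ticks.append((x0 + len(sub) / 2, str(chrom)))
            x0 += len(sub)
        ax.axhline(self.threshold_pct, color="red", ls="--", lw=0.8)
        ax.set_xticks([t for t, _ in ticks])
        ax.set_xticklabels([l for _, l in ticks])
        ax.set_xlabel("chromosome")
        ax.set_ylabel("% additive variance / window")
        ax.set_title(self.trait)
        return ax
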