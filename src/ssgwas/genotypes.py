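"""Genotype QC, allele frequencies, the genomic relationship matrix G and
assembly of the single-step H inverse.

G follows VanRaden's first method: dosages centered by twice the observed
allele frequency, cross-products scaled by sum(2 p (1-p)).  H^-1 adds the
genotyped-block correction G_b^-1 - A22^-1 to the sparse pedigree A^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree, build_A22, build_A_inverse


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Dosage matrix (individuals x SNPs) with its SNP map.

    ``dosages`` counts copies of the minor allele in {0,1,2}; missing is
    ``nan``.  ``snp_map`` has columns chrom, snp_id, cm, bp (1-based) and,
    when read from or written to PLINK text, minor_allele / major_allele.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: np.ndarray
    p_hat: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed counted-allele frequency per SNP, missing excluded."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def with_frequencies(self) -> "GenotypeData":
        if self.p_hat is None:
            self.p_hat = self.allele_frequencies()
        return self


def _is_autosome(chrom) -> bool:
    s = str(chrom)
    return s.isdigit() and int(s) > 0


def qc_genotypes(
    raw: GenotypeData,
    snp_missing_max: float = 0.05,
    maf_min: float = 0.01,
    indiv_callrate_min: float = 0.95,
    autosomes_only: bool = True,
):
    """Quality control in the fixed order: individual call rate, SNP
    missingness, MAF, autosomes.  Returns the filtered data and a report
    table (step, n_removed, n_remaining)."""
    dos = raw.dosages
    report = []

    callrate = 1.0 - np.mean(np.isnan(dos), axis=1)
    keep_ind = callrate >= indiv_callrate_min
    dos = dos[keep_ind]
    report.append(("individual_callrate", int((~keep_ind).sum()), int(keep_ind.sum())))
    if dos.shape[0] == 0:
        raise GenotypeError("all individuals removed by call-rate filter")

    miss = np.mean(np.isnan(dos), axis=0)
    keep = miss <= snp_missing_max
    report.append(("snp_missingness", int((~keep).sum()), int(keep.sum())))

    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep2 = keep & ~np.isnan(maf) & (maf >= maf_min)
    report.append(("maf", int(keep.sum() - keep2.sum()), int(keep2.sum())))

    if autosomes_only:
        auto = raw.snp_map["chrom"].map(_is_autosome).to_numpy()
        keep3 = keep2 & auto
    else:
        keep3 = keep2
    report.append(("autosomes", int(keep2.sum() - keep3.sum()), int(keep3.sum())))
    if keep3.sum() == 0:
        raise GenotypeError("all SNPs removed by QC")

    out = GenotypeData(
        dosages=dos[:, keep3],
        snp_map=raw.snp_map.loc[keep3].reset_index(drop=True),
        sample_ids=raw.sample_ids[keep_ind],
    )
    # re-estimate frequencies in the post-QC sample and re-orient so the
    # counted allele is the minor one (frequencies can cross 0.5 after
    # dropping individuals; ties at 0.5 keep the current orientation,
    # which the reader fixed lexicographically)
    p = out.allele_frequencies()
    flip = p > 0.5
    if flip.any():
        out.dosages[:, flip] = 2.0 - out.dosages[:, flip]
        smap = out.snp_map
        if "minor_allele" in smap.columns:
            mi = smap.loc[flip, "minor_allele"].copy()
            smap.loc[flip, "minor_allele"] = smap.loc[flip, "major_allele"]
            smap.loc[flip, "major_allele"] = mi
        p = np.where(flip, 1.0 - p, p)
    out.p_hat = p
    rep = pd.DataFrame(report, columns=["step", "n_removed", "n_remaining"])
    return out, rep


def impute_and_center(geno: GenotypeData) -> np.ndarray:
    """Marker matrix Z: missing dosages replaced by 2 p_hat, columns
    centered by 2 p_hat (so imputation is null after centering)."""
    geno.with_frequencies()
    p = geno.p_hat
    if np.any((p <= 0) | (p >= 1)):
        bad = geno.snp_map["snp_id"].iloc[int(np.argmax((p <= 0) | (p >= 1)))]
        raise GenotypeError(f"monomorphic SNP {bad!r} reached centering; run QC first")
    Z = geno.dosages - 2.0 * p
    return np.where(np.isnan(Z), 0.0, Z)


def build_G(Z: np.ndarray, p_hat: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix Z Z' / sum 2p(1-p)."""
    denom = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    if denom <= 0:
        raise GenotypeError("zero scaling denominator: all SNPs monomorphic")
    G = Z @ Z.T / denom
    return 0.5 * (G + G.T)


def blend_G(G: np.ndarray, A22: np.ndarray, blend_weight: float = 0.05) -> np.ndarray:
    """G_b = (1-w) G + w A22, the standard fix for a singular marker G."""
    if G.shape != A22.shape:
        raise GenotypeError(f"dimension mismatch: G {G.shape} vs A22 {A22.shape}")
    w = float(blend_weight)
    if not 0.0 <= w <= 1.0:
        raise ValueError("blend_weight must lie in [0, 1]")
    return (1.0 - w) * G + w * A22


def build_H_inverse(
    ainv: sp.spmatrix,
    G_b: np.ndarray,
    A22: np.ndarray,
    genotyped_ids: np.ndarray,
) -> sp.csc_matrix:
    """H^-1 = A^-1 plus (G_b^-1 - A22^-1) scattered on the genotyped block."""
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    n = ainv.shape[0]
    if genotyped_ids.size == 0:
        return ainv.tocsc()
    corr = np.linalg.inv(G_b) - np.linalg.inv(A22)
    corr = 0.5 * (corr + corr.T)
    rows = np.repeat(genotyped_ids - 1, genotyped_ids.size)
    cols = np.tile(genotyped_ids - 1, genotyped_ids.size)
    scatter = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    return (ainv.tocsc() + scatter.tocsc()).tocsc()


@dataclass
class RelationshipSet:
    """All relationship matrices one single-step evaluation needs."""

    ainv: sp.csc_matrix
    a22: np.ndarray
    g_raw: np.ndarray
    g_blended: np.ndarray
    hinv: sp.csc_matrix
    genotyped_ids: np.ndarray  # pedigree ids (1-based), row order of G/A22
    logdet_hinv: float | None = None


def build_relationships(
    ped: Pedigree,
    geno: GenotypeData,
    blend_weight: float = 0.05,
    tune_to_a22: bool = False,
) -> RelationshipSet:
    """Assemble A^-1, A22, G (optionally tuned to A22's mean diagonal and
    off-diagonal), the blended G and H^-1 for the genotyped samples found
    in the pedigree."""
    genotyped_ids = ped.ids_of(geno.sample_ids)
    ainv = build_A_inverse(ped)
    a22 = build_A22(ped, genotyped_ids)
    Z = impute_and_center(geno)
    G = build_G(Z, geno.p_hat)
    if tune_to_a22:
        # solve mean(diag G)*b + a = mean(diag A22); mean(offdiag) likewise
        dG, dA = np.mean(np.diag(G)), np.mean(np.diag(a22))
        oG = (G.sum() - np.trace(G)) / (G.size - len(G))
        oA = (a22.sum() - np.trace(a22)) / (a22.size - len(a22))
        b = (dA - oA) / (dG - oG) if abs(dG - oG) > 1e-12 else 1.0
        a = dA - b * dG
        G = a * np.ones_like(G) + b * G
    Gb = blend_G(G, a22, blend_weight)
    hinv = build_H_inverse(ainv, Gb, a22, genotyped_ids)
    return RelationshipSet(
        ainv=ainv, a22=a22, g_raw=G, g_blended=Gb, hinv=hinv, genotyped_ids=genotyped_ids
    )
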