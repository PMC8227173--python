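"""Readers and writers for the external formats the pipeline touches:
pedigree tables, PLINK text genotypes (.ped/.map), phenotype CSVs and the
window/region report files.

Coordinates are 1-based inclusive internally (the SNP-chip .map
convention); the BED export is the single 0-based half-open conversion
point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeData
from .pedigree import Pedigree, renumber


# ---------------------------------------------------------------------------
# pedigree

def read_pedigree(path, id_policy: str = "strict") -> Pedigree:
    """Read a 3-column (individual, sire, dam) table, comma- or
    whitespace-separated; unknown parents coded 0 or empty.  Output is
    renumbered parents-first."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     skip_blank_lines=True, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"pedigree file {path} needs 3 columns, found {df.shape[1]}")
    first = [str(x).lower() for x in df.iloc[0, :3]]
    if any(k in first for k in ("id", "individual", "animal")):  # header row
        df = df.iloc[1:]
    trip = df.iloc[:, :3].fillna("0").astype(str)
    return renumber(list(trip.itertuples(index=False, name=None)), id_policy=id_policy)


def write_pedigree(ped: Pedigree, path) -> None:
    lab = ped.labels
    with open(path, "w") as fh:
        fh.write("individual,sire,dam\n")
        for i in range(1, ped.n + 1):
            s = lab[ped.sire[i]] if ped.sire[i] else 0
            d = lab[ped.dam[i]] if ped.dam[i] else 0
            fh.write(f"{lab[i]},{s},{d}\n")


# ---------------------------------------------------------------------------
# PLINK text genotypes

def read_plink_text(ped_path, map_path) -> GenotypeData:
    """Read PLINK .ped/.map text files into minor-allele dosages.

    The minor allele of each SNP is determined from the observed sample
    frequencies (ties at 0.5 broken by lexicographic allele order);
    missing genotypes are the PLINK ``0`` code.  Non-biallelic SNPs raise.
    """
    smap = pd.read_csv(map_path, sep=r"\s+", header=None,
                       names=["chrom", "snp_id", "cm", "bp"], dtype={"chrom": str})
    n_snps = len(smap)
    sample_ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, map lists {n_snps} SNPs"
                )
            sample_ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype=object).reshape(len(rows), n_snps, 2)

    dosages = np.full((len(rows), n_snps), np.nan)
    minor = np.empty(n_snps, dtype=object)
    major = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"SNP {smap.snp_id[j]!r} is not biallelic: alleles {list(uniq)}")
        if len(uniq) == 0:
            minor[j], major[j] = "?", "?"
            continue
        if len(uniq) == 1:
            minor[j], major[j] = uniq[0], uniq[0]
        else:
            order = np.argsort(counts, kind="stable")
            if counts[0] == counts[1]:  # tie: lexicographically smaller allele is minor
                a, b = sorted(uniq)
                minor[j], major[j] = a, b
            else:
                minor[j], major[j] = uniq[order[0]], uniq[order[1]]
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        dos = (col[:, 0] == minor[j]).astype(float) + (col[:, 1] == minor[j]).astype(float)
        dos[miss] = np.nan
        dosages[:, j] = dos
    smap["minor_allele"] = minor
    smap["major_allele"] = major
    return GenotypeData(dosages=dosages, snp_map=smap,
                        sample_ids=np.asarray(sample_ids, dtype=object))


def write_plink_text(geno: GenotypeData, ped_path, map_path) -> None:
    """Write .ped/.map; requires minor/major allele labels in the map
    (synthesized as A/B when absent)."""
    smap = geno.snp_map.copy()
    if "minor_allele" not in smap.columns:
        smap["minor_allele"] = "A"
        smap["major_allele"] = "B"
    if "cm" not in smap.columns:
        smap["cm"] = 0
    smap[["chrom", "snp_id", "cm", "bp"]].to_csv(map_path, sep="\t", header=False, index=False)
    mi, ma = smap["minor_allele"].to_numpy(), smap["major_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            fields = ["FAM", str(sid), "0", "0", "0", "-9"]
            d = geno.dosages[i]
            for j in range(geno.n_snps):
                if np.isnan(d[j]):
                    fields += ["0", "0"]
                elif d[j] == 2:
                    fields += [mi[j], mi[j]]
                elif d[j] == 1:
                    fields += [mi[j], ma[j]]
                else:
                    fields += [ma[j], ma[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotypes

SEASON_OF_MONTH = {m: (m - 1) // 3 + 1 for m in range(1, 13)}  # quarters: 1=Jan-Mar


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "individual" not in df.columns:
        raise ValueError("phenotype file must have an 'individual' column")
    return df


def validate_phenotypes(df: pd.DataFrame, ped: Pedigree, trait: str, columns) -> None:
    missing = [c for c in [trait, *columns] if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    unknown = [x for x in df["individual"] if x not in ped._label_index]
    if unknown:
        raise ValueError(f"{len(unknown)} phenotyped individuals absent from pedigree, "
                         f"e.g. {unknown[:5]}")


# ---------------------------------------------------------------------------
# reports

def write_window_report(table: pd.DataFrame, path) -> None:
    """TSV with chromosome, 1-based inclusive window bounds, SNP count and
    percent of SNP-explained additive variance."""
    cols = ["chrom", "window_start_bp", "window_end_bp", "n_snps", "pct_var"]
    table[cols].to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Regions as BED (0-based half-open): start_bp-1, end_bp."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start_bp']) - 1}\t{int(r['end_bp'])}\n")


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_varcomp_report(vc, genetic_parameters, path) -> None:
    """Variance components and derived parameters as TSV (component,
    estimate, SE) in the layout of a published component table."""
    def se(term, a, b):
        S = vc.se.get(term)
        return "" if S is None else f"{S[a, b]:.6g}"

    rows = [("sigma2_p", vc.sigma2_p, se("hys", 0, 0)),
            ("sigma2_a", vc.sigma2_a, se("genetic", 0, 0))]
    if vc.sigma2_m is not None:
        rows += [("sigma2_m", vc.sigma2_m, se("genetic", 1, 1)),
                 ("sigma_am", vc.sigma_am, se("genetic", 0, 1))]
    rows.append(("sigma2_e", vc.sigma2_e,
                 "" if vc.se_sigma2_e is None else f"{vc.se_sigma2_e:.6g}"))
    gp = genetic_parameters.rounded()
    rows.append(("h2", gp.h2, ""))
    if gp.h2_mat is not None:
        rows += [("h2_mat", gp.h2_mat, ""), ("r_a_mat", gp.r_a_mat, "")]
    with open(path, "w") as fh:
        fh.write("component\testimate\tse\n")
        for name, val, s in rows:
            fh.write(f"{name}\t{val:.6g}\t{s}\n")


def write_solutions(solutions: dict, ped: Pedigree, path) -> None:
    """Effect solutions as TSV (effect, level, estimate)."""
    with open(path, "w") as fh:
        fh.write("effect\tlevel\testimate\n")
        for eff, block in solutions.items():
            if isinstance(block, dict):
                for lev, val in block.items():
                    fh.write(f"{eff}\t{lev}\t{val:.10g}\n")
            else:
                for i, val in enumerate(np.asarray(block).ravel(), start=1):
                    lev = ped.labels[i] if eff in ("additive", "maternal") else i
                    fh.write(f"{eff}\t{lev}\t{val:.10g}\n")
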