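"""From genomic breeding values to SNP effects, window variances and
significant regions.

The GEBVs of the genotyped animals are a linear transform of SNP
effects, so those effects can be recovered by backsolving:
g_hat = Z' G^-1 u_hat / sum_i 2 p_i (1 - p_i), which for the unblended
marker G equals the projection Z'(Z Z')^-1 u_hat.  Each SNP's variance
contribution is 2 p_i (1 - p_i) g_hat_i^2; contributions are summed in
fixed non-overlapping 1-Mb windows and expressed as percent of the
genome-wide sum.  Windows at or above the reporting threshold (default
0.5%) are merged into regions when consecutive, and regions shared by
two or more traits are flagged as pleiotropic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _chrom_key(c):
    """Natural chromosome ordering: numeric labels first, then others."""
    s = str(c)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class SnpEffects:
    """Backsolved allele-substitution effects and their variances."""

    g_hat: np.ndarray
    var_snp: np.ndarray
    p_hat: np.ndarray


def backsolve_snp_effects(u_hat: np.ndarray, Z: np.ndarray, G: np.ndarray,
                          p_hat: np.ndarray) -> SnpEffects:
    """Backsolve SNP effects from genotyped animals' GEBVs.

    ``u_hat`` must be restricted to and ordered as G's rows; ``Z`` is the
    centered marker matrix; ``G`` the matrix actually used in H (the raw
    marker G gives the exact projection identity, a blended G remains
    well-defined).
    """
    n, N = Z.shape
    if u_hat.shape[0] != n or G.shape != (n, n):
        raise ValueError(f"order mismatch: u_hat {u_hat.shape}, Z {Z.shape}, G {G.shape}")
    denom = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    x = np.linalg.solve(G, u_hat)
    g_hat = Z.T @ x / denom
    return SnpEffects(g_hat=g_hat, var_snp=per_snp_variance(g_hat, p_hat), p_hat=p_hat)


def per_snp_variance(g_hat: np.ndarray, p_hat: np.ndarray) -> np.ndarray:
    """Additive variance attributed to each SNP: 2 p (1-p) g_hat^2."""
    return 2.0 * p_hat * (1.0 - p_hat) * g_hat ** 2


def window_variances(var_snp: np.ndarray, snp_map: pd.DataFrame,
                     window_size_bp: int = 1_000_000) -> pd.DataFrame:
    """Sum per-SNP variances in fixed non-overlapping windows and
    standardize to percent of the genome-wide total.

    Windows are indexed floor((bp-1)/size) per chromosome; empty windows
    are omitted.  Reported bounds are 1-based inclusive.
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    df = snp_map.copy()
    df["var_snp"] = var_snp
    keys = [(_chrom_key(c), b) for c, b in zip(df["chrom"], df["bp"])]
    order = sorted(range(len(df)), key=keys.__getitem__)
    if order != list(range(len(df))):
        warnings.warn("SNP map not sorted by (chromosome, bp); sorting internally")
        df = df.iloc[order]
    df["window"] = (df["bp"].to_numpy(np.int64) - 1) // window_size_bp
    total = df["var_snp"].sum()
    if total <= 0:
        raise ValueError("total SNP variance is zero; nothing to standardize")
    grp = df.groupby(["chrom", "window"], sort=True).agg(
        n_snps=("var_snp", "size"), var_sum=("var_snp", "sum")).reset_index()
    grp["pct_var"] = 100.0 * grp["var_sum"] / total
    grp["window_start_bp"] = grp["window"] * window_size_bp + 1
    grp["window_end_bp"] = (grp["window"] + 1) * window_size_bp
    return grp[["chrom", "window", "window_start_bp", "window_end_bp",
                "n_snps", "pct_var"]]


def window_bv_variances(g_hat: np.ndarray, Z: np.ndarray, snp_map: pd.DataFrame,
                        window_size_bp: int = 1_000_000) -> pd.DataFrame:
    """Alternative window statistic: variance across genotyped animals of
    each window's summed marker breeding values, as percent of the total
    over windows."""
    df = snp_map.copy().reset_index(drop=True)
    df["window"] = (df["bp"].to_numpy(np.int64) - 1) // window_size_bp
    rows = []
    for (chrom, win), idx in df.groupby(["chrom", "window"], sort=True).groups.items():
        cols = np.asarray(idx)
        bv = Z[:, cols] @ g_hat[cols]
        rows.append((chrom, win, len(cols), float(np.var(bv))))
    out = pd.DataFrame(rows, columns=["chrom", "window", "n_snps", "var_sum"])
    out["pct_var"] = 100.0 * out["var_sum"] / out["var_sum"].sum()
    out["window_start_bp"] = out["window"] * window_size_bp + 1
    out["window_end_bp"] = (out["window"] + 1) * window_size_bp
    return out[["chrom", "window", "window_start_bp", "window_end_bp",
                "n_snps", "pct_var"]]


def _merge_consecutive(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge windows with consecutive indices on a chromosome into
    regions (chrom, start_bp, end_bp, peak_pct, window indices)."""
    regions = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        sub = sub.sort_values("window")
        start = prev = None
        members = []
        for _, r in sub.iterrows():
            if prev is not None and r["window"] == prev + 1:
                members.append(r)
            else:
                if members:
                    regions.append(_region_row(chrom, members))
                members = [r]
            prev = r["window"]
        if members:
            regions.append(_region_row(chrom, members))
    return pd.DataFrame(regions, columns=["chrom", "start_bp", "end_bp",
                                          "start_window", "end_window", "peak_pct"])


def _region_row(chrom, members):
    return dict(chrom=chrom,
                start_bp=int(members[0]["window_start_bp"]),
                end_bp=int(members[-1]["window_end_bp"]),
                start_window=int(members[0]["window"]),
                end_window=int(members[-1]["window"]),
                peak_pct=float(max(m["pct_var"] for m in members)))


def select_regions(window_table: pd.DataFrame, threshold_pct: float = 0.5) -> pd.DataFrame:
    """Windows explaining >= threshold percent of variance, merged into
    regions where consecutive.  Raw (unrounded) percentages are compared."""
    sig = window_table[window_table["pct_var"] >= threshold_pct]
    return _merge_consecutive(sig)


def pleiotropy_table(window_tables: dict, threshold_pct: float = 0.5) -> pd.DataFrame:
    """Cross-trait region table.

    Significant windows are pooled over traits; consecutive pooled
    windows form the candidate regions (the union of the per-trait
    spans), and each trait is marked 'X' where at least one of its own
    significant windows falls inside.  ``pleiotropic`` flags regions
    marked for two or more traits.
    """
    traits = list(window_tables)
    sig = {tr: t[t["pct_var"] >= threshold_pct] for tr, t in window_tables.items()}
    pooled = pd.concat(sig.values(), ignore_index=True)
    if pooled.empty:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "start_Mb", "end_Mb",
                                     *traits, "n_traits", "pleiotropic", "candidate_genes"])
    pooled = pooled.drop_duplicates(subset=["chrom", "window"])
    regions = _merge_consecutive(pooled)
    rows = []
    for _, reg in regions.iterrows():
        marks = {}
        for tr in traits:
            s = sig[tr]
            inside = s[(s["chrom"] == reg["chrom"]) &
                       (s["window"] >= reg["start_window"]) &
                       (s["window"] <= reg["end_window"])]
            marks[tr] = "X" if len(inside) else "-"
        n_tr = sum(v == "X" for v in marks.values())
        rows.append(dict(chrom=reg["chrom"], start_bp=reg["start_bp"], end_bp=reg["end_bp"],
                         start_Mb=(reg["start_bp"] - 1) // 1_000_000,
                         end_Mb=reg["end_bp"] // 1_000_000,
                         **marks, n_traits=n_tr, pleiotropic=n_tr >= 2,
                         candidate_genes=""))
    return pd.DataFrame(rows)
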