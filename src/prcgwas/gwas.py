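"""Per-SNP additive association, cross-layer min-p meta, locus selection.

The association model is ordinary least squares of the phenotype on the
additive dosage of the effect allele A1 plus covariates (age, weight, sex,
height, OCT machine ID one-hot, genotype PCs) and an intercept; two-sided
p-values come from the t distribution with the residual degrees of freedom.
SNPs with complete dosages are fitted by the Frisch-Waugh-Lovell shortcut —
phenotype and dosages are residualized on the covariate block once, then
each SNP needs one scalar regression — which is algebraically identical to
the full per-SNP fit and keeps genome-wide scans vectorized.

Layer results are combined by the min-p rule (the smallest p across the ONL,
IS and OS scans is the meta p), and independent loci are selected greedily
by distance: take the most significant SNP, suppress significant SNPs within
10 Mb on the same chromosome, repeat; selected leads within 1.5 Mb share a
locus group label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._core import (
    ConfigError,
    GenotypeMatrix,
    design_matrix,
    logger,
    ols_fit,
)

GENOME_WIDE_P = 5e-8

RESULT_COLUMNS = ["ID", "CHR", "POS", "A0", "A1", "AF_A1", "BETA", "SE",
                  "P", "N", "monomorphic", "degenerate"]


def run_additive_gwas(phenotype: pd.Series,
                      genotypes: GenotypeMatrix,
                      covariates: pd.DataFrame | None = None,
                      mean_impute: bool = False) -> pd.DataFrame:
    """Per-SNP OLS association of one phenotype.

    Individuals present in the phenotype, the genotype panel and (if given)
    the covariate table with finite values enter the analysis; individuals
    with a missing dosage at a SNP are dropped for that SNP only
    (``mean_impute=True`` fills them with the mean dosage instead).
    Monomorphic SNPs are flagged with p = 1 by convention; zero-residual
    fits are flagged degenerate.
    """
    ids = phenotype.index.intersection(genotypes.individuals)
    if covariates is not None:
        ids = ids.intersection(covariates.index)
    y_all = phenotype.loc[ids]
    keep = np.isfinite(y_all.to_numpy(dtype=float))
    C, names = design_matrix(covariates, ids)
    keep &= np.isfinite(C).all(axis=1)
    ids = ids[keep]
    if len(ids) == 0:
        raise ConfigError("no analyzable individuals (empty overlap)")
    y = y_all.loc[ids].to_numpy(dtype=float)
    C = C[keep]
    G = genotypes.subset_individuals(ids).dosages.copy()
    n, k = C.shape
    if n <= k + 1:
        raise ConfigError(
            f"{n} individuals for {k + 1} parameters: underdetermined")

    if mean_impute:
        col_mean = np.nanmean(G, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(G))
        G[nan_r, nan_c] = col_mean[nan_c]

    # FWL: residualize y and dosages on the covariate block once
    coef_y, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
    y_t = y - C @ coef_y
    complete = ~np.isnan(G).any(axis=0)
    beta = np.full(genotypes.n_snps, np.nan)
    se = np.full(genotypes.n_snps, np.nan)
    pval = np.full(genotypes.n_snps, np.nan)
    n_used = np.full(genotypes.n_snps, n)
    mono = np.zeros(genotypes.n_snps, dtype=bool)
    degen = np.zeros(genotypes.n_snps, dtype=bool)

    if complete.any():
        Gc = G[:, complete]
        coef_g, _, _, _ = np.linalg.lstsq(C, Gc, rcond=None)
        Gt = Gc - C @ coef_g
        gg = np.einsum("ij,ij->j", Gt, Gt)
        gy = Gt.T @ y_t
        df = n - k - 1
        yy = float(y_t @ y_t)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = gy / gg
            rss = np.maximum(yy - b * gy, 0.0)
            s = np.sqrt(rss / df / gg)
            t = np.where(s > 0, b / s, np.inf * np.sign(b))
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df),
                    np.finfo(float).tiny, 1.0)
        # rss comes from cancellation of two O(yy) terms: tolerance scales
        # with yy and stays far below any non-degenerate residual
        is_mono = gg <= n * 1e-20
        is_degen = (~is_mono) & (rss <= max(yy, 1.0) * 1e-12)
        b[is_mono], s[is_mono], p[is_mono] = 0.0, np.nan, 1.0
        s[is_degen] = 0.0
        idx = np.nonzero(complete)[0]
        beta[idx], se[idx], pval[idx] = b, s, p
        mono[idx], degen[idx] = is_mono, is_degen

    for j in np.nonzero(~complete)[0]:
        g = G[:, j]
        ok = ~np.isnan(g)
        n_used[j] = int(ok.sum())
        if n_used[j] <= k + 1:
            mono[j] = True
            beta[j], pval[j] = 0.0, 1.0
            continue
        if np.ptp(g[ok]) == 0:
            mono[j] = True
            beta[j], pval[j] = 0.0, 1.0
            continue
        fit = ols_fit(y[ok], np.column_stack([C[ok], g[ok]]),
                      names=names + ["dosage"])
        beta[j], se[j], pval[j] = fit.beta[-1], fit.se[-1], fit.p[-1]
        degen[j] = fit.degenerate

    snps = genotypes.snps
    with np.errstate(invalid="ignore"):
        af = np.nanmean(G, axis=0) / 2.0
    return pd.DataFrame({
        "ID": snps["ID"].to_numpy(),
        "CHR": snps["CHR"].to_numpy(),
        "POS": snps["POS"].to_numpy(),
        "A0": snps["REF"].to_numpy(),
        "A1": snps["ALT"].to_numpy(),
        "AF_A1": af,
        "BETA": beta,
        "SE": se,
        "P": pval,
        "N": n_used,
        "monomorphic": mono,
        "degenerate": degen,
    })


def meta_min_p(onl: pd.DataFrame, is_: pd.DataFrame,
               os: pd.DataFrame) -> pd.DataFrame:
    """Min-p meta across layer scans; records the source layer.

    SNPs missing from a layer use the available layers; ties break to the
    first layer in (ONL, IS, OS) order.
    """
    layers = {"ONL": onl, "IS": is_, "OS": os}
    pieces = []
    for name, df in layers.items():
        piece = df[["ID", "CHR", "POS", "P", "BETA", "SE"]].copy()
        piece["layer"] = name
        pieces.append(piece)
    stacked = pd.concat(pieces, ignore_index=True)
    stacked = stacked.dropna(subset=["P"])
    order = pd.CategoricalDtype(["ONL", "IS", "OS"], ordered=True)
    stacked["layer"] = stacked["layer"].astype(order)
    stacked = stacked.sort_values(["ID", "P", "layer"], kind="mergesort")
    best = stacked.drop_duplicates("ID", keep="first")
    best = best.rename(columns={"P": "P_META", "layer": "SOURCE_LAYER"})
    best["SOURCE_LAYER"] = best["SOURCE_LAYER"].astype(str)
    return best.sort_values(["CHR", "POS"]).reset_index(drop=True)


def select_independent_loci(results: pd.DataFrame,
                            p_threshold: float = GENOME_WIDE_P,
                            min_sep: int = 10_000_000,
                            group_window: int = 1_500_000,
                            p_col: str | None = None) -> pd.DataFrame:
    """Greedy distance-based selection of independent lead SNPs.

    Repeatedly take the most significant remaining SNP below ``p_threshold``
    and suppress all significant SNPs within ``min_sep`` bp on the same
    chromosome; afterwards, leads within ``group_window`` of each other share
    a locus group label.  Deterministic: ties in p break by (CHR, POS, ID).
    """
    if p_col is None:
        p_col = "P_META" if "P_META" in results.columns else "P"
    sig = results[results[p_col] < p_threshold].copy()
    if sig.empty:
        out = sig.copy()
        out["locus_group"] = pd.Series(dtype=int)
        return out
    sig = sig.sort_values([p_col, "CHR", "POS", "ID"],
                          kind="mergesort").reset_index(drop=True)
    alive = np.ones(len(sig), dtype=bool)
    chrv = sig["CHR"].to_numpy()
    posv = sig["POS"].to_numpy()
    leads = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        leads.append(i)
        alive &= ~((chrv == chrv[i]) & (np.abs(posv - posv[i]) <= min_sep))
    out = sig.iloc[leads].sort_values(["CHR", "POS"]).reset_index(drop=True)

    group = np.zeros(len(out), dtype=int)
    gid = 0
    for i in range(1, len(out)):
        same = (out.at[i, "CHR"] == out.at[i - 1, "CHR"]
                and out.at[i, "POS"] - out.at[i - 1, "POS"] <= group_window)
        if not same:
            gid += 1
        group[i] = gid
    out["locus_group"] = group
    logger.info("selected %d independent leads in %d locus groups",
                len(out), gid + 1)
    return out


def compute_lambda_gc(p_values) -> float:
    """Genomic-inflation lambda: median association chi-square over its
    null median (chi-square with 1 df)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ConfigError("compute_lambda_gc needs at least one p-value")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Summary-statistics TSV: CHR, POS, ID, A0, A1, AF_A1, BETA, SE, P, N."""
    cols = ["CHR", "POS", "ID", "A0", "A1", "AF_A1", "BETA", "SE", "P", "N"]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
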