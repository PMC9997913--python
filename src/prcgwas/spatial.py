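"""Concentric-field differential-effect analysis and spatial effect maps.

For each layer, per-field genome-wide scans (foveal, intermediate,
peripheral) are compared pairwise with the standardized effect-difference
statistic

    Z = |beta_0 - beta_1| / sqrt(SE_0^2 + SE_1^2),

with a two-sided standard-normal p-value and Bonferroni correction over the
z-tests actually performed in the comparison.  The statistic treats the two
field estimates as independent; because both fields are measured on the same
individuals and are correlated, this is an approximation — an optional
covariance-corrected variant (regression on the between-field difference
phenotype) is provided for comparison, but the simple form is the default.

Significant SNPs are clumped by LD: each is annotated with companions at
r^2 above a threshold within a window, annotation groups are merged into
connected components, and the lowest-p SNP per component is kept as lead.
Per-segment effect maps refit the additive model on each of the nine ETDRS
segment phenotypes and can be rendered as a bullseye heatmap with a
per-SNP-normalized diverging scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._core import (
    FIELDS,
    SEGMENTS,
    ConfigError,
    GenotypeMatrix,
    ThicknessCube,
    logger,
)
from .gwas import GENOME_WIDE_P, run_additive_gwas
from .phenotypes import aggregate_field_mean, phenotype_series

COMPARISONS: tuple[tuple[str, str], ...] = (
    ("foveal", "intermediate"),
    ("foveal", "peripheral"),
    ("intermediate", "peripheral"),
)

DIFF_COLUMNS = ["ID", "LAYER", "COMPARISON", "BETA_F1", "SE_F1", "BETA_F2",
                "SE_F2", "Z", "P", "P_BONF", "SIGNIFICANT"]


def differential_z_test(beta0, se0, beta1, se1):
    """Standardized absolute difference of two effect estimates.

    Returns ``(Z, p)`` with Z = |beta0 - beta1| / sqrt(se0^2 + se1^2) and p
    the two-sided standard-normal tail probability.  Vectorized; symmetric
    under swapping the two estimates.
    """
    se0 = np.asarray(se0, dtype=float)
    se1 = np.asarray(se1, dtype=float)
    if np.any(se0 <= 0) or np.any(se1 <= 0):
        raise ConfigError("standard errors must be positive")
    z = np.abs(np.asarray(beta0, dtype=float)
               - np.asarray(beta1, dtype=float)) / np.hypot(se0, se1)
    p = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def compare_concentric_fields(results_f1: pd.DataFrame,
                              results_f2: pd.DataFrame,
                              layer: str = "",
                              comparison: str = "",
                              selection_threshold: float = GENOME_WIDE_P,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Differential z-tests for SNPs significant in either field scan.

    SNPs genome-wide significant in field 1 OR field 2 are tested; the
    Bonferroni family is the number of z-tests actually performed within
    this comparison.  Mismatched SNP universes are reduced to their
    intersection with a log message.
    """
    f1 = results_f1.set_index("ID")
    f2 = results_f2.set_index("ID")
    common = f1.index.intersection(f2.index)
    if len(common) != len(f1) or len(common) != len(f2):
        logger.info("field scans share %d of %d/%d SNPs; testing the "
                    "intersection", len(common), len(f1), len(f2))
    f1, f2 = f1.loc[common], f2.loc[common]
    sel = (f1["P"] < selection_threshold) | (f2["P"] < selection_threshold)
    sel &= (f1["SE"] > 0) & (f2["SE"] > 0)
    f1, f2 = f1[sel], f2[sel]
    if f1.empty:
        return pd.DataFrame(columns=DIFF_COLUMNS)
    z, p = differential_z_test(f1["BETA"].to_numpy(), f1["SE"].to_numpy(),
                               f2["BETA"].to_numpy(), f2["SE"].to_numpy())
    m = len(f1)
    p_bonf = np.minimum(p * m, 1.0)
    out = pd.DataFrame({
        "ID": f1.index,
        "LAYER": layer,
        "COMPARISON": comparison,
        "BETA_F1": f1["BETA"].to_numpy(),
        "SE_F1": f1["SE"].to_numpy(),
        "BETA_F2": f2["BETA"].to_numpy(),
        "SE_F2": f2["SE"].to_numpy(),
        "Z": z,
        "P": p,
        "P_BONF": p_bonf,
        "SIGNIFICANT": p < alpha / m,
    })
    return out.reset_index(drop=True)


def differential_difference_test(phenotype_f1: pd.Series,
                                 phenotype_f2: pd.Series,
                                 genotypes: GenotypeMatrix,
                                 covariates: pd.DataFrame | None = None
                                 ) -> pd.DataFrame:
    """Covariance-corrected alternative: regress the within-individual
    between-field difference on dosage.

    Accounts for the correlation between field estimates computed on the
    same individuals, which the simple z statistic ignores.
    """
    diff = (phenotype_f1 - phenotype_f2).dropna()
    return run_additive_gwas(diff, genotypes, covariates)


def dosage_r2(genotypes: GenotypeMatrix, id_a: str, id_b: str) -> float:
    """Squared Pearson correlation of dosages at two SNPs."""
    a = genotypes.dosage(id_a).to_numpy()
    b = genotypes.dosage(id_b).to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return np.nan
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r * r)


def clump_by_ld(results: pd.DataFrame,
                genotypes: GenotypeMatrix,
                r2_min: float = 0.05,
                window: int = 1_000_000,
                p_col: str = "P") -> pd.DataFrame:
    """Reduce correlated SNPs to one lead per LD-connected component.

    Each input SNP is annotated with companions at r^2 > ``r2_min`` within
    +/- ``window`` bp; overlapping annotation groups are merged (connected
    components) and the lowest-p SNP per component is flagged ``LEAD``.
    Ties break by position then ID.  SNPs absent from the genotype panel
    cannot be correlated with anything and are retained as their own
    component with a warning.
    """
    out = results.copy().reset_index(drop=True)
    if out.empty:
        out["CLUMP"] = pd.Series(dtype=int)
        out["LEAD"] = pd.Series(dtype=bool)
        return out
    snp_meta = genotypes.snps.set_index("ID")
    known = out["ID"].isin(snp_meta.index).to_numpy()
    for missing_id in out.loc[~known, "ID"]:
        logger.warning("SNP %s absent from genotype panel: retained "
                       "unclumped", missing_id)
    n = len(out)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    idx_known = np.nonzero(known)[0]
    chrs = {i: snp_meta.at[out.at[i, "ID"], "CHR"] for i in idx_known}
    poss = {i: snp_meta.at[out.at[i, "ID"], "POS"] for i in idx_known}
    for ai in range(len(idx_known)):
        i = idx_known[ai]
        for bi in range(ai + 1, len(idx_known)):
            j = idx_known[bi]
            if chrs[i] != chrs[j] or abs(poss[i] - poss[j]) > window:
                continue
            r2 = dosage_r2(genotypes, out.at[i, "ID"], out.at[j, "ID"])
            if np.isfinite(r2) and r2 > r2_min:
                union(i, j)

    comp = np.array([find(i) for i in range(n)])
    out["CLUMP"] = pd.factorize(comp)[0]
    lead = np.zeros(n, dtype=bool)
    for c in np.unique(out["CLUMP"]):
        members = out[out["CLUMP"] == c]
        pos_key = [poss.get(i, np.inf) for i in members.index]
        order = members.assign(_pos=pos_key).sort_values(
            [p_col, "_pos", "ID"], kind="mergesort")
        lead[order.index[0]] = True
    out["LEAD"] = lead
    return out


def segment_effect_map(snp_id: str,
                       cube: ThicknessCube,
                       covariates: pd.DataFrame,
                       genotypes: GenotypeMatrix,
                       layer: str,
                       assoc_covariates: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """Per-segment additive effects of one SNP on one layer.

    Fits the same additive linear model on each of the nine residualized,
    eye-averaged segment phenotypes.  ``covariates`` supplies the eye-level
    residualization columns; ``assoc_covariates`` the association-model
    covariates (defaults to none).  Returns a frame with SEGMENT, BETA, SE,
    P rows in grid order.
    """
    rows = []
    for seg in SEGMENTS:
        pheno_tbl = aggregate_field_mean(cube, layer, seg, covariates)
        pheno = phenotype_series(pheno_tbl, layer, seg)
        res = run_additive_gwas(pheno, genotypes, assoc_covariates)
        row = res[res["ID"] == snp_id]
        if row.empty:
            raise ConfigError(f"SNP {snp_id!r} not in genotype panel")
        rows.append(dict(SEGMENT=seg, BETA=row["BETA"].iloc[0],
                         SE=row["SE"].iloc[0], P=row["P"].iloc[0]))
    out = pd.DataFrame(rows)
    out.insert(0, "LAYER", layer)
    out.insert(0, "ID", snp_id)
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def plot_segment_map(effect_map: pd.DataFrame, ax=None, cmap="RdBu_r"):
    """Render a per-segment effect map as an ETDRS bullseye heatmap.

    The diverging colour scale is normalized per SNP (symmetric about zero
    at the largest absolute effect).  Ring radii follow the 1/3/6 mm ETDRS
    geometry.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Wedge

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    betas = effect_map.set_index("SEGMENT")["BETA"]
    vmax = float(np.nanmax(np.abs(betas.to_numpy()))) or 1.0
    norm = plt.Normalize(-vmax, vmax)
    colours = plt.get_cmap(cmap)
    # wedge angles: ring segments 1-4 = superior, nasal, inferior, temporal
    angles = [(45, 135), (135, 225), (225, 315), (315, 405)]
    for ring, radius_in, radius_out in (("IS", 0.5, 1.5), ("OS", 1.5, 3.0)):
        for k, (a0, a1) in enumerate(angles, start=1):
            beta = betas[f"{ring}{k}"]
            ax.add_patch(Wedge((0, 0), radius_out, a0, a1,
                               width=radius_out - radius_in,
                               facecolor=colours(norm(beta)),
                               edgecolor="black", linewidth=0.5))
    ax.add_patch(Circle((0, 0), 0.5, facecolor=colours(norm(betas["C"])),
                        edgecolor="black", linewidth=0.5))
    ax.set_xlim(-3.2, 3.2)
    ax.set_ylim(-3.2, 3.2)
    ax.set_aspect("equal")
    ax.axis("off")
    sm = plt.cm.ScalarMappable(norm=norm, cmap=colours)
    plt.colorbar(sm, ax=ax, shrink=0.7, label="effect size (um per A1 copy)")
    snp = effect_map["ID"].iloc[0] if "ID" in effect_map else ""
    layer = effect_map["LAYER"].iloc[0] if "LAYER" in effect_map else ""
    ax.set_title(f"{snp} {layer}".strip())
    return ax
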