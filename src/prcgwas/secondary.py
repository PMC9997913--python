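"""Interaction battery, disease-gene enrichment, stratified grid means.

Interaction tests are OLS fits of the phenotype on g1 + g2 + g1*g2 plus the
standard covariates, reporting the product-term coefficient.  A battery run
executes the configured pair categories (anchor SNP x significant SNPs,
pairwise within a set, all loci x genetically defined sex, gene-burden
levels x nearby common SNPs), pools all categories into one
Benjamini-Hochberg family and flags discoveries at FDR < 0.15.

Disease-gene overlap is an exact upper-tail hypergeometric test: drawing n
tested loci from a universe of N, of which K overlap the disease list, what
is P(X >= k)?

Stratified grid means reproduce the two-SNP visualization: within each
anchor-SNP genotype stratum, per-(partner genotype, segment) mean thickness
is computed and the stratum grand mean subtracted, so panels show deviation
in micrometres from that stratum's average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._core import (
    EYES,
    LAYERS,
    SEGMENTS,
    ConfigError,
    ThicknessCube,
    design_matrix,
    logger,
    ols_fit,
)

FDR_THRESHOLD = 0.15


@dataclass
class InteractionPair:
    """One interaction term to test: two named interactor vectors."""

    term1: str
    values1: pd.Series
    term2: str
    values2: pd.Series
    category: str = ""


def interaction_test(g1: pd.Series, g2: pd.Series,
                     phenotype: pd.Series,
                     covariates: pd.DataFrame | None = None) -> dict:
    """Product-term coefficient from y ~ g1 + g2 + g1*g2 + covariates.

    ``g1`` may be a dosage, a collapsed burden genotype or a 0/1 sex code.
    Constant interactors make the product term untestable (flagged).
    """
    ids = phenotype.index.intersection(g1.index).intersection(g2.index)
    if covariates is not None:
        ids = ids.intersection(covariates.index)
    y = phenotype.loc[ids].to_numpy(dtype=float)
    a = g1.loc[ids].to_numpy(dtype=float)
    b = g2.loc[ids].to_numpy(dtype=float)
    C, names = design_matrix(covariates, ids)
    ok = (np.isfinite(y) & np.isfinite(a) & np.isfinite(b)
          & np.isfinite(C).all(axis=1))
    y, a, b, C = y[ok], a[ok], b[ok], C[ok]
    if len(y) == 0 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return dict(beta_int=np.nan, se_int=np.nan, p=np.nan, n=int(len(y)),
                    testable=False)
    X = np.column_stack([C, a, b, a * b])
    fit = ols_fit(y, X, names=names + ["g1", "g2", "g1:g2"])
    testable = not np.isnan(fit.beta[-1])
    return dict(beta_int=fit.beta[-1], se_int=fit.se[-1], p=fit.p[-1],
                n=fit.n, testable=testable)


def run_interaction_battery(pairs: list[InteractionPair],
                            phenotype: pd.Series,
                            covariates: pd.DataFrame | None = None,
                            fdr: float = FDR_THRESHOLD,
                            layer: str = "") -> pd.DataFrame:
    """Execute all configured pairs and BH-adjust across the battery.

    Untestable pairs (constant interactor, no overlap) are reported but
    excluded from the BH family.  Returns TERM1, TERM2, CATEGORY, LAYER,
    BETA_INT, SE, P, Q, DISCOVERY.
    """
    rows = []
    for pair in pairs:
        res = interaction_test(pair.values1, pair.values2, phenotype,
                               covariates)
        rows.append(dict(TERM1=pair.term1, TERM2=pair.term2,
                         CATEGORY=pair.category, LAYER=layer,
                         BETA_INT=res["beta_int"], SE=res["se_int"],
                         P=res["p"], N=res["n"], TESTABLE=res["testable"]))
    out = pd.DataFrame(rows)
    out["Q"] = np.nan
    out["DISCOVERY"] = False
    if out.empty:
        return out
    testable = out["TESTABLE"] & np.isfinite(out["P"])
    if testable.any():
        reject, q, _, _ = multipletests(out.loc[testable, "P"],
                                        alpha=fdr, method="fdr_bh")
        out.loc[testable, "Q"] = q
        out.loc[testable, "DISCOVERY"] = reject
    n_disc = int(out["DISCOVERY"].sum())
    logger.info("interaction battery: %d pairs, %d testable, %d discoveries "
                "at FDR < %g", len(out), int(testable.sum()), n_disc, fdr)
    return out


def build_battery(genotypes, lead_ids: list[str],
                  anchor: str | None = None,
                  sets: dict[str, list[str]] | None = None,
                  sex: pd.Series | None = None,
                  burden_genotypes: dict | None = None,
                  burden_partners: dict[str, list[str]] | None = None,
                  ) -> list[InteractionPair]:
    """Assemble the standard interaction categories.

    1. anchor SNP x every other lead SNP;
    2. pairwise within each named SNP set (e.g. retinoid-cycle loci);
    3. every lead SNP x genetically defined sex;
    4. gene-burden genotype x nearby common SNPs.

    Empty categories are skipped with a log entry.
    """
    pairs: list[InteractionPair] = []

    def dosage(sid):
        return genotypes.dosage(sid)

    if anchor is not None:
        partners = [s for s in lead_ids if s != anchor]
        if not partners:
            logger.info("anchor category empty: skipped")
        for sid in partners:
            pairs.append(InteractionPair(anchor, dosage(anchor), sid,
                                         dosage(sid), "anchor"))
    for name, members in (sets or {}).items():
        if len(members) < 2:
            logger.info("pairwise category %r has <2 members: skipped", name)
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append(InteractionPair(
                    members[i], dosage(members[i]),
                    members[j], dosage(members[j]), f"pairwise:{name}"))
    if sex is not None:
        if not lead_ids:
            logger.info("sex category empty: skipped")
        for sid in lead_ids:
            pairs.append(InteractionPair("sex", sex, sid, dosage(sid),
                                         "sex"))
    for gene, partners in (burden_partners or {}).items():
        geno = (burden_genotypes or {}).get(gene)
        if geno is None or not partners:
            logger.info("burden category for %r empty: skipped", gene)
            continue
        for sid in partners:
            pairs.append(InteractionPair(
                f"burden:{gene}", geno.astype(float), sid, dosage(sid),
                "burden"))
    return pairs


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail (inclusive) hypergeometric overlap p-value.

    N items, K of them disease-listed, n tested; probability of observing
    at least ``k`` overlaps by chance.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ConfigError(
            f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.finfo(float).tiny), 1.0)


def stratified_segment_means(cube: ThicknessCube,
                             dosage_a: pd.Series,
                             dosage_b: pd.Series,
                             layer: str = "ONL") -> pd.DataFrame:
    """Mean-normalized per-segment thickness in a 3x3 genotype grid.

    Rounds dosages to genotype classes 0/1/2.  Within each anchor (SNP a)
    stratum the per-(SNP b genotype, segment) mean raw thickness (averaged
    over eyes) is computed and the stratum grand mean over all its
    individuals x segments subtracted.  Empty cells are NaN with
    ``N = 0``.  Returns GENO_A, GENO_B, SEGMENT, MEAN_UM, N.
    """
    if layer not in LAYERS:
        raise ConfigError(f"unknown layer {layer!r}")
    ids = cube.individuals.intersection(dosage_a.index).intersection(
        dosage_b.index)
    sub = cube.subset_individuals(ids)
    li = LAYERS.index(layer)
    with np.errstate(invalid="ignore"):
        eye_avg = np.nanmean(sub.values[:, li, :, :], axis=2)  # (n, 9)
    ga = np.round(dosage_a.loc[ids].to_numpy(dtype=float)).astype(int)
    gb = np.round(dosage_b.loc[ids].to_numpy(dtype=float)).astype(int)
    rows = []
    for a in (0, 1, 2):
        in_a = ga == a
        stratum = eye_avg[in_a]
        grand = np.nanmean(stratum) if in_a.any() else np.nan
        for b in (0, 1, 2):
            cell = eye_avg[in_a & (gb == b)]
            n_cell = cell.shape[0]
            for si, seg in enumerate(SEGMENTS):
                mean = (np.nanmean(cell[:, si]) - grand if n_cell else np.nan)
                rows.append(dict(GENO_A=a, GENO_B=b, SEGMENT=seg,
                                 MEAN_UM=mean, N=n_cell))
    return pd.DataFrame(rows)


def plot_stratified_grid(strat: pd.DataFrame, axes=None, cmap="RdBu_r"):
    """Render the 3x3 genotype panel of mean-normalized ETDRS grids."""
    import matplotlib.pyplot as plt

    from .spatial import plot_segment_map

    if axes is None:
        _, axes = plt.subplots(3, 3, figsize=(10, 10))
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            ax = axes[a][b]
            cell = strat[(strat["GENO_A"] == a) & (strat["GENO_B"] == b)]
            if cell["MEAN_UM"].isna().all():
                ax.text(0.5, 0.5, "no individuals", ha="center",
                        va="center", transform=ax.transAxes)
                ax.axis("off")
                continue
            fake = cell.rename(columns={"MEAN_UM": "BETA"})[
                ["SEGMENT", "BETA"]].copy()
            fake["ID"] = ""
            fake["LAYER"] = ""
            plot_segment_map(fake, ax=ax, cmap=cmap)
            ax.set_title(f"a={a}, b={b}", fontsize=9)
    return axes
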