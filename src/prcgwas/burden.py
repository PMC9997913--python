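"""Rare-variant gene-burden analysis.

Variants are filtered into two qualifying classes per gene — high-confidence
loss-of-function, and missense carrying both the SIFT "deleterious" and
PolyPhen "probably_damaging" flags — each restricted to minor allele
frequency strictly below 1%.  Per gene and class, an individual's qualifying
variants collapse to a single 0/1/2 genotype: 0 with no qualifying variant,
1 with at least one but all heterozygous, 2 if any qualifying variant is
homozygous for the rare allele.  Phase is ignored and compound
heterozygotes are not modelled.  The collapsed genotype then enters the
same additive linear model used for common-variant association, with a
suggested exome-wide significance threshold of 5e-5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._core import GenotypeMatrix, SchemaError, logger
from .gwas import run_additive_gwas

EXOME_WIDE_P = 5e-5

ANNOTATION_COLUMNS = ("VARIANT_ID", "GENE", "CONSEQUENCE", "LOF_HC",
                      "SIFT", "POLYPHEN", "AF")


def classify_rare_variants(annotations: pd.DataFrame,
                           maf_max: float = 0.01,
                           cohort_af: pd.Series | None = None
                           ) -> dict[str, dict[str, set]]:
    """Qualifying variant sets per gene: {gene: {"LoF": set, "missense": set}}.

    LoF = high-confidence loss of function; missense = both deleteriousness
    flags.  The MAF filter is strict (< ``maf_max``) and uses the minor
    allele frequency.  ``cohort_af`` overrides the annotation AF column with
    frequencies observed in the analysis cohort.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise SchemaError(f"annotation table missing columns {missing}")
    af = annotations["AF"].astype(float)
    if cohort_af is not None:
        af = annotations["VARIANT_ID"].map(cohort_af).fillna(af)
    maf = np.minimum(af, 1.0 - af)
    rare = maf < maf_max
    is_lof = (annotations["LOF_HC"].astype(int) == 1) & rare
    is_mis = ((annotations["SIFT"] == "deleterious")
              & (annotations["POLYPHEN"] == "probably_damaging") & rare)
    out: dict[str, dict[str, set]] = {}
    for gene, grp in annotations.groupby("GENE"):
        out[gene] = {
            "LoF": set(grp.loc[is_lof.loc[grp.index], "VARIANT_ID"]),
            "missense": set(grp.loc[is_mis.loc[grp.index], "VARIANT_ID"]),
        }
    return out


def collapse_gene_genotypes(variant_set,
                            carriers: pd.DataFrame) -> pd.Series:
    """Collapse qualifying variant genotypes to the per-gene 0/1/2 code.

    ``carriers`` holds per-variant genotypes (columns = variant ids, values
    0/1/2) indexed by individual.  Variants in the set but absent from the
    carrier table are ignored with a warning; adding a qualifying variant to
    an individual can only raise their collapsed genotype.
    """
    variant_set = set(variant_set)
    present = [v for v in variant_set if v in carriers.columns]
    absent = variant_set - set(present)
    if absent:
        logger.warning("%d qualifying variants missing from carrier table: "
                       "ignored", len(absent))
    if not present:
        return pd.Series(0, index=carriers.index, dtype=np.int8)
    block = carriers[present].to_numpy()
    any_hom = (block >= 2).any(axis=1)
    any_var = (block >= 1).any(axis=1)
    geno = np.where(any_hom, 2, np.where(any_var, 1, 0)).astype(np.int8)
    return pd.Series(geno, index=carriers.index)


def burden_association(gene_genotypes: dict[tuple[str, str], pd.Series],
                       phenotype: pd.Series,
                       covariates: pd.DataFrame | None = None,
                       threshold: float = EXOME_WIDE_P) -> pd.DataFrame:
    """Per-gene linear-model association of collapsed genotypes.

    ``gene_genotypes`` maps (gene, model) to the collapsed 0/1/2 Series.
    Genes with no carriers among analyzed individuals are flagged untestable
    and excluded from the multiple-testing count.  Returns a frame with
    GENE, MODEL, N0, N1, N2, BETA, SE, P, SIGNIFICANT, TESTABLE.
    """
    rows = []
    for (gene, model), geno in gene_genotypes.items():
        ids = phenotype.index.intersection(geno.index)
        if covariates is not None:
            ids = ids.intersection(covariates.index)
        g = geno.loc[ids]
        counts = g.value_counts()
        n1, n2 = int(counts.get(1, 0)), int(counts.get(2, 0))
        n0 = int(counts.get(0, 0))
        testable = (n1 + n2) > 0 and n0 > 0
        beta = se = p = np.nan
        if testable:
            panel = GenotypeMatrix(
                g.to_numpy(dtype=float)[:, None],
                pd.DataFrame({"CHR": [0], "POS": [0], "ID": [gene],
                              "REF": ["-"], "ALT": ["burden"],
                              "AF": [g.mean() / 2.0]}),
                ids)
            res = run_additive_gwas(phenotype.loc[ids], panel, covariates)
            beta, se, p = (res["BETA"].iloc[0], res["SE"].iloc[0],
                           res["P"].iloc[0])
        rows.append(dict(GENE=gene, MODEL=model, N0=n0, N1=n1, N2=n2,
                         BETA=beta, SE=se, P=p, TESTABLE=testable))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["SIGNIFICANT"] = out["TESTABLE"] & (out["P"] < threshold)
    return out


def run_burden_scan(annotations: pd.DataFrame,
                    carriers: pd.DataFrame,
                    phenotype: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    threshold: float = EXOME_WIDE_P,
                    maf_max: float = 0.01,
                    use_cohort_af: bool = True) -> pd.DataFrame:
    """Classify, collapse and test every (gene, model) in one call."""
    cohort_af = None
    if use_cohort_af:
        ids = phenotype.index.intersection(carriers.index)
        cohort_af = carriers.loc[ids].mean(axis=0) / 2.0
    classes = classify_rare_variants(annotations, maf_max=maf_max,
                                     cohort_af=cohort_af)
    gene_genotypes = {}
    for gene, models in classes.items():
        for model, vset in models.items():
            if vset:
                gene_genotypes[(gene, model)] = collapse_gene_genotypes(
                    vset, carriers)
    return burden_association(gene_genotypes, phenotype, covariates,
                              threshold)
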