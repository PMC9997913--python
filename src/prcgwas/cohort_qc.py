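"""Cohort-selection workflow: ancestry cluster, relatedness, image quality.

Filters run in a fixed order — ancestry cluster in PC1-PC2 space, precomputed
relatedness exclusions, OCT image-quality score, per-indicator worst-quantile
cuts, refractive-error outliers — and each excluded individual is attributed
to the first filter that removed them.  The report serialises to JSON with
one ``{filter, n_before, n_excluded, n_after}`` record per step.

The quantile rule removes individuals strictly worse than the empirical
quantile value, so fully tied populations are never decimated and a second
application of the whole workflow to its own survivors removes nobody.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import (
    EYES,
    INDICATORS,
    ConfigError,
    GenotypeMatrix,
    SchemaError,
    logger,
)
from .phenotypes import compute_refractive_error


@dataclass
class QCThresholds:
    """Tunable cut-offs of the cohort-selection workflow."""

    image_quality_min: float = 45.0
    indicator_quantile: float = 0.20
    ancestry_centroid: tuple[float, float] = (7.52e-4, -4.66e-4)
    ancestry_radius: float = 1.45e-3
    refraction_iqr_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.indicator_quantile < 1.0:
            raise ConfigError("indicator_quantile must be in [0, 1)")
        if self.ancestry_radius <= 0:
            raise ConfigError("ancestry_radius must be positive")


@dataclass
class QCReport:
    """Ordered per-filter exclusion log."""

    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, n_before: int, n_after: int) -> None:
        self.steps.append(dict(filter=name, n_before=int(n_before),
                               n_excluded=int(n_before - n_after),
                               n_after=int(n_after)))

    @property
    def n_final(self) -> int:
        return self.steps[-1]["n_after"] if self.steps else 0

    def excluded(self, name: str) -> int:
        return sum(s["n_excluded"] for s in self.steps if s["filter"] == name)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.steps, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def select_ancestry(pcs: pd.DataFrame,
                    thresholds: QCThresholds | None = None) -> pd.Index:
    """Individuals within the ancestry-cluster radius of the centroid.

    Distance is Euclidean in PC1-PC2 space; the boundary is inclusive
    (distance == radius is kept).
    """
    thresholds = thresholds or QCThresholds()
    for col in ("PC1", "PC2"):
        if col not in pcs.columns:
            raise SchemaError(f"PC table missing column {col!r}")
    cx, cy = thresholds.ancestry_centroid
    dist = np.hypot(pcs["PC1"] - cx, pcs["PC2"] - cy)
    return pcs.index[dist <= thresholds.ancestry_radius]


def exclude_related(ids: pd.Index, exclusion_list) -> pd.Index:
    """Drop precomputed relatedness exclusions; order-stable set difference."""
    ids = pd.Index(ids)
    excl = set(exclusion_list)
    unknown = excl - set(ids)
    if unknown:
        logger.info("%d relatedness exclusions not in cohort (ignored)",
                    len(unknown))
    kept = ids[~ids.isin(excl)]
    if len(kept) == 0 and len(ids) > 0:
        logger.warning("relatedness exclusion removed the entire cohort")
    return kept


def _worst_eye_value(cov: pd.DataFrame, name: str, direction: str
                     ) -> pd.Series:
    """Per-individual worst value of a per-eye column across imaged eyes."""
    cols = [f"{name}_{eye}" for eye in EYES if f"{name}_{eye}" in cov.columns]
    if not cols:
        raise SchemaError(f"covariate table missing per-eye columns for "
                          f"{name!r}")
    block = cov[cols]
    # worst = min where low values are bad, max where high values are bad
    return block.min(axis=1) if direction == "low" else block.max(axis=1)


def filter_image_quality(covariates: pd.DataFrame,
                         thresholds: QCThresholds | None = None,
                         report: QCReport | None = None) -> pd.Index:
    """Image-quality score, segmentation-indicator and refraction filters.

    1. Remove individuals with any imaged eye's quality score strictly below
       ``image_quality_min`` (eyes with missing scores are ignored).
    2. For each segmentation indicator, remove individuals strictly worse
       than the ``indicator_quantile`` empirical quantile of the surviving
       population (low tail for ILM indicator, valid count and minimum
       motion correlation; high tail for maximum motion delta/factor).
    3. Remove refractive-error outliers: any eye's mean spherical equivalent
       outside median +/- multiplier x IQR of the surviving population
       (median/IQR pooled over eyes).
    """
    thresholds = thresholds or QCThresholds()
    report = report if report is not None else QCReport()
    cov = covariates

    quality = _worst_eye_value(cov, "quality", "low")
    kept = cov.index[~(quality < thresholds.image_quality_min)]
    report.record("image_quality_score", len(cov), len(kept))

    q = thresholds.indicator_quantile
    for name, direction in INDICATORS.items():
        values = _worst_eye_value(cov.loc[kept], name, direction)
        n_before = len(kept)
        if q > 0 and len(values):
            if direction == "low":
                cut = np.nanquantile(values, q)
                kept = kept[~(values < cut).to_numpy()]
            else:
                cut = np.nanquantile(values, 1.0 - q)
                kept = kept[~(values > cut).to_numpy()]
        report.record(f"indicator_{name}", n_before, len(kept))

    refr = []
    for eye in EYES:
        sph, cyl = f"spherical_{eye}", f"cylindrical_{eye}"
        if sph not in cov.columns or cyl not in cov.columns:
            raise SchemaError(f"covariate table missing {sph!r}/{cyl!r}")
        refr.append(compute_refractive_error(cov.loc[kept, sph],
                                             cov.loc[kept, cyl]))
    refr_mat = pd.concat(refr, axis=1)
    pooled = refr_mat.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    n_before = len(kept)
    if pooled.size and np.isfinite(thresholds.refraction_iqr_multiplier):
        med = np.median(pooled)
        q1, q3 = np.percentile(pooled, [25, 75])
        half = thresholds.refraction_iqr_multiplier * (q3 - q1)
        outside = ((refr_mat < med - half) | (refr_mat > med + half)).any(
            axis=1)
        kept = kept[~outside.to_numpy()]
    report.record("refractive_error", n_before, len(kept))
    return kept


def apply_cohort_qc(pcs: pd.DataFrame,
                    covariates: pd.DataFrame,
                    exclusion_list=(),
                    thresholds: QCThresholds | None = None,
                    ) -> tuple[pd.Index, QCReport]:
    """Run the full workflow: ancestry -> relatedness -> image quality.

    Individuals must appear in both the PC and covariate tables to enter the
    cohort; the report logs every step's exclusion count in order.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    ids = pcs.index.intersection(covariates.index)
    report.record("input", len(ids), len(ids))

    in_cluster = select_ancestry(pcs.loc[ids], thresholds)
    report.record("ancestry_cluster", len(ids), len(in_cluster))

    unrelated = exclude_related(in_cluster, exclusion_list)
    report.record("relatedness", len(in_cluster), len(unrelated))

    final = filter_image_quality(covariates.loc[unrelated], thresholds,
                                 report)
    return final, report


# ---------------------------------------------------------------------------
# PCA utility for synthetic genotypes
# ---------------------------------------------------------------------------

def ld_prune(genotypes: GenotypeMatrix, window_bp: int = 50_000,
             step: int = 1, r2_max: float = 0.8,
             maf_min: float = 0.1) -> list[int]:
    """Greedy LD pruning: sliding window, drop one of each pair r^2 > cut.

    Returns indices of retained SNPs.  Intended for computing genotype PCs on
    synthetic panels; the primary QC path consumes precomputed PCs.
    """
    snps = genotypes.snps
    af = snps["AF"].to_numpy()
    maf = np.minimum(af, 1 - af)
    candidates = [j for j in range(genotypes.n_snps) if maf[j] > maf_min]
    kept: list[int] = []
    for j in candidates:
        ok = True
        for k in reversed(kept):
            if (snps.at[k, "CHR"] != snps.at[j, "CHR"]
                    or snps.at[j, "POS"] - snps.at[k, "POS"] > window_bp):
                break
            r = np.corrcoef(genotypes.dosages[:, k],
                            genotypes.dosages[:, j])[0, 1]
            if np.isfinite(r) and r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


def compute_pcs(genotypes: GenotypeMatrix, n_pcs: int = 10,
                prune: bool = True) -> pd.DataFrame:
    """Genotype PCA: standardized dosages, SVD, top components."""
    cols = (ld_prune(genotypes) if prune
            else list(range(genotypes.n_snps)))
    X = genotypes.dosages[:, cols]
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (np.where(np.isnan(X), mu, X) - mu) / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    k = min(n_pcs, S.size)
    pcs = U[:, :k] * S[:k] / np.sqrt(len(Z))
    return pd.DataFrame(pcs, index=genotypes.individuals,
                        columns=[f"PC{i + 1}" for i in range(k)])
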