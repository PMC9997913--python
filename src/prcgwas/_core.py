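"""Shared containers, constants, IO and the linear-model engine.

Everything downstream works on two in-memory containers:

* :class:`GenotypeMatrix` — individuals x biallelic SNPs, additive dosage of
  the effect allele (A1 = ALT), with per-SNP metadata.
* :class:`ThicknessCube` — per-individual retinal thickness in micrometres
  indexed by (layer, ETDRS segment, eye).

The ordinary-least-squares helpers here are the single association engine the
whole package uses (per-SNP GWAS, gene-burden tests, interaction terms and
per-segment effect maps all reduce to the same fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("prcgwas")

# ---------------------------------------------------------------------------
# Constants: layers, ETDRS grid, covariate schema
# ---------------------------------------------------------------------------

#: Photoreceptor-cell component layers: outer nuclear layer, inner segment,
#: outer segment.
LAYERS: tuple[str, ...] = ("ONL", "IS", "OS")

#: ETDRS grid segments: central subfield, inner ring (IS1-IS4), outer ring
#: (OS1-OS4).  Ring labels follow scan order (superior, nasal, inferior,
#: temporal); no laterality-aware nasal/temporal flip is applied between eyes.
SEGMENTS: tuple[str, ...] = (
    "C", "IS1", "IS2", "IS3", "IS4", "OS1", "OS2", "OS3", "OS4"
)

EYES: tuple[str, ...] = ("L", "R")

#: Concentric fields partitioning the grid (foveal = central subfield,
#: intermediate = inner ring, peripheral = outer ring).
FIELDS: dict[str, tuple[str, ...]] = {
    "foveal": ("C",),
    "intermediate": ("IS1", "IS2", "IS3", "IS4"),
    "peripheral": ("OS1", "OS2", "OS3", "OS4"),
}

#: Whole-grid scope plus the three concentric fields plus single segments.
GRID_SCOPE = "grid"

#: OCT segmentation-quality indicators and the direction in which quality is
#: poor ("low" = small values are bad, "high" = large values are bad).
INDICATORS: dict[str, str] = {
    "ilm_indicator": "low",
    "valid_count": "low",
    "min_motion_corr": "low",
    "max_motion_delta": "high",
    "max_motion_factor": "high",
}

#: Per-eye covariate columns expected in a covariate table ("{name}_{eye}").
EYE_COVARIATES: tuple[str, ...] = (
    "quality",
    "ilm_indicator",
    "valid_count",
    "min_motion_corr",
    "max_motion_delta",
    "max_motion_factor",
    "spherical",
    "cylindrical",
)

#: Individual-level covariates used in every association model.
BASE_COVARIATES: tuple[str, ...] = ("age", "sex", "height", "weight")


class ConfigError(ValueError):
    """Invalid configuration (non-positive sizes, out-of-range rates ...)."""


class SchemaError(ValueError):
    """An input table is missing required columns."""


class UnknownSNPError(KeyError):
    """A referenced SNP id is absent from the genotype panel."""


def segment_index(segment: str) -> int:
    try:
        return SEGMENTS.index(segment)
    except ValueError:
        raise ConfigError(f"unknown ETDRS segment {segment!r}; "
                          f"expected one of {SEGMENTS}") from None


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Additive dosages (individuals x SNPs) with SNP metadata.

    ``dosages[i, j]`` is the count (0-2, NaN if missing) of the effect allele
    A1 (= ALT) carried by individual ``i`` at SNP ``j``.  ``snps`` has one row
    per SNP with columns CHR, POS (1-based), ID, REF, ALT, AF (A1 frequency).
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    individuals: pd.Index

    def __post_init__(self) -> None:
        self.individuals = pd.Index(self.individuals, name="individual_id")
        n, m = self.dosages.shape
        if n != len(self.individuals) or m != len(self.snps):
            raise ConfigError("dosage matrix shape does not match labels")
        self.snps = self.snps.reset_index(drop=True)
        self._snp_pos = pd.Index(self.snps["ID"])

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosage(self, snp_id: str) -> pd.Series:
        """Dosage vector for one SNP, indexed by individual id."""
        j = self._snp_pos.get_indexer([snp_id])[0]
        if j < 0:
            raise UnknownSNPError(snp_id)
        return pd.Series(self.dosages[:, j], index=self.individuals,
                         name=snp_id)

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = self.individuals.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown individual ids in subset")
        return GenotypeMatrix(self.dosages[idx], self.snps.copy(),
                              pd.Index(ids))

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Dosage-matrix TSV: one row per SNP, metadata then individuals."""
        df = self.snps[["CHR", "POS", "ID", "REF", "ALT"]].copy()
        mat = pd.DataFrame(self.dosages.T, columns=self.individuals)
        pd.concat([df, mat.set_axis(df.index)], axis=1).to_csv(
            path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["CHR", "POS", "ID", "REF", "ALT"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"dosage TSV missing columns {missing}")
        ids = [c for c in df.columns if c not in meta_cols]
        dosages = df[ids].to_numpy(dtype=float).T
        snps = df[meta_cols].copy()
        with np.errstate(invalid="ignore"):
            snps["AF"] = np.nanmean(dosages, axis=0) / 2.0
        return cls(dosages, snps, pd.Index(ids))

    def to_vcf(self, path) -> None:
        """Write a minimal GT-coded biallelic VCF (uncompressed text)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            for chrom in pd.unique(self.snps["CHR"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                     "FORMAT\t" + "\t".join(map(str, self.individuals))
                     + "\n")
            codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, row in self.snps.iterrows():
                gts = [
                    "./." if np.isnan(d) else codes[int(round(d))]
                    for d in self.dosages[:, j]
                ]
                fh.write(f"{row.CHR}\t{row.POS}\t{row.ID}\t{row.REF}\t"
                         f"{row.ALT}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read GT dosages from a biallelic VCF via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = pd.Index(vcf.samples)
        rows, meta = [], []
        for var in vcf:
            gts = np.asarray(var.gt_types, dtype=float)  # 0,1,3=hom-alt,2=unk
            dos = np.where(gts == 3, 2.0, gts)
            dos[gts == 2] = np.nan
            rows.append(dos)
            meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                         var.REF, var.ALT[0] if var.ALT else "."))
        dosages = np.asarray(rows).T if rows else np.empty((len(ids), 0))
        snps = pd.DataFrame(meta, columns=["CHR", "POS", "ID", "REF", "ALT"])
        with np.errstate(invalid="ignore"):
            snps["AF"] = (np.nanmean(dosages, axis=0) / 2.0
                          if len(meta) else np.array([]))
        return cls(dosages, snps, ids)


# ---------------------------------------------------------------------------
# ThicknessCube
# ---------------------------------------------------------------------------

@dataclass
class ThicknessCube:
    """Thickness in micrometres, shape (individuals, layer, segment, eye).

    Missing eyes are NaN across all layers/segments for that eye.
    """

    values: np.ndarray
    individuals: pd.Index

    def __post_init__(self) -> None:
        self.individuals = pd.Index(self.individuals, name="individual_id")
        expected = (len(self.individuals), len(LAYERS), len(SEGMENTS),
                    len(EYES))
        if self.values.shape != expected:
            raise ConfigError(
                f"thickness cube shape {self.values.shape} != {expected}")

    def layer_eye(self, layer: str, eye: str) -> np.ndarray:
        """(n, 9) view for one layer and eye."""
        return self.values[:, LAYERS.index(layer), :, EYES.index(eye)]

    def subset_individuals(self, ids) -> "ThicknessCube":
        idx = self.individuals.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown individual ids in subset")
        return ThicknessCube(self.values[idx], pd.Index(ids))

    def to_tsv(self, path) -> None:
        recs = []
        for li, layer in enumerate(LAYERS):
            for si, seg in enumerate(SEGMENTS):
                for ei, eye in enumerate(EYES):
                    col = self.values[:, li, si, ei]
                    recs.append(pd.DataFrame({
                        "individual_id": self.individuals,
                        "eye": eye, "layer": layer, "segment": seg,
                        "thickness_um": col,
                    }))
        out = pd.concat(recs, ignore_index=True).dropna(
            subset=["thickness_um"])
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ThicknessCube":
        df = pd.read_csv(path, sep="\t")
        need = {"individual_id", "eye", "layer", "segment", "thickness_um"}
        if not need.issubset(df.columns):
            raise SchemaError(
                f"thickness TSV missing columns {sorted(need - set(df.columns))}")
        ids = pd.Index(pd.unique(df["individual_id"]))
        values = np.full((len(ids), len(LAYERS), len(SEGMENTS), len(EYES)),
                         np.nan)
        ii = ids.get_indexer(df["individual_id"])
        li = pd.Index(LAYERS).get_indexer(df["layer"])
        si = pd.Index(SEGMENTS).get_indexer(df["segment"])
        ei = pd.Index(EYES).get_indexer(df["eye"])
        if (li < 0).any() or (si < 0).any() or (ei < 0).any():
            raise SchemaError("thickness TSV has unknown layer/segment/eye")
        values[ii, li, si, ei] = df["thickness_um"].to_numpy()
        return cls(values, ids)


# ---------------------------------------------------------------------------
# OLS engine
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    """Coefficients, standard errors and t-based p-values for one OLS fit."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df_resid: int
    rss: float
    n: int
    degenerate: bool = False
    dropped: list = field(default_factory=list)


def ols_fit(y: np.ndarray, X: np.ndarray, names=None) -> OLSFit:
    """OLS of ``y`` on ``X`` (caller includes the intercept column).

    Collinear columns are dropped (coefficient, SE and p reported as NaN)
    with a warning, mirroring how rank-deficient covariate sets are handled
    throughout the pipeline.  A zero-residual fit is flagged degenerate; its
    SEs are 0 and its p-values collapse to the smallest positive float so the
    p in (0, 1] contract holds.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    keep = _independent_columns(X)
    dropped = [i for i in range(k) if i not in keep]
    if dropped:
        labels = ([names[i] for i in dropped] if names is not None
                  else dropped)
        logger.warning("dropping collinear design columns: %s", labels)
    Xk = X[:, keep]
    if n <= Xk.shape[1]:
        raise ConfigError(
            f"{n} observations for {Xk.shape[1]} parameters: underdetermined")
    coef, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ coef
    rss = float(resid @ resid)
    df = n - Xk.shape[1]
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss <= max(tss, 1.0) * 1e-24
    XtX_inv = np.linalg.pinv(Xk.T @ Xk)
    if degenerate:
        se_k = np.zeros(Xk.shape[1])
    else:
        sigma2 = rss / df
        se_k = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    p = np.full(k, np.nan)
    beta[list(keep)] = coef
    se[list(keep)] = se_k
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pk = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[:] = np.clip(pk, np.finfo(float).tiny, 1.0)
    p[np.isnan(beta)] = np.nan
    return OLSFit(beta=beta, se=se, p=p, df_resid=df, rss=rss, n=n,
                  degenerate=degenerate, dropped=dropped)


def _independent_columns(X: np.ndarray) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return keep


def design_matrix(covariates: pd.DataFrame | None,
                  index: pd.Index) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates aligned to ``index``; machine_id one-hot coded.

    Non-numeric columns are treated as categorical and dummy-coded with the
    first level as reference.
    """
    cols = [np.ones(len(index))]
    names = ["intercept"]
    if covariates is not None and len(covariates.columns):
        cov = covariates.loc[index]
        for c in cov.columns:
            col = cov[c]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
            else:
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    names.append(dc)
    return np.column_stack(cols), names
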