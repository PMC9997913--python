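"""Synthetic cohort generation with planted genetic effects.

Emulates the statistical structure of a biobank-scale retinal-OCT study:
biallelic SNPs in Hardy-Weinberg proportions with blockwise LD, three
photoreceptor layers (ONL, IS, OS) measured on the 9-segment ETDRS grid in
both eyes, standard covariates (age, sex, anthropometry, OCT machine,
refraction, image-quality indicators), genotype-PC population structure with
a dense main cluster, and rare LoF/missense variants with plantable
gene-burden effects.  Every downstream stage of the pipeline is testable on
these cohorts without any external download.

The LD model is deliberately simple: within a block each haplotype copies the
previous SNP's allele with probability ``ld_rho`` and otherwise redraws from
that SNP's allele frequency.  Haplotypes stay independent, so marginal
genotypes remain in Hardy-Weinberg proportions at any ``ld_rho``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import (
    EYES,
    LAYERS,
    SEGMENTS,
    ConfigError,
    GenotypeMatrix,
    ThicknessCube,
    UnknownSNPError,
    logger,
    segment_index,
)

# Ancestry-cluster geometry used as generator defaults: the dense main
# cluster sits at the reference centroid used by cohort QC.
DEFAULT_CENTROID = (7.52e-4, -4.66e-4)
DEFAULT_RADIUS = 1.45e-3

#: Baseline thickness (micrometres) per (layer, segment): the outer nuclear
#: layer peaks at the fovea, inner/outer segments are flatter.
DEFAULT_BASELINE: dict[tuple[str, str], float] = {}
for _seg in SEGMENTS:
    ring = "C" if _seg == "C" else ("inner" if _seg.startswith("IS") else "outer")
    DEFAULT_BASELINE[("ONL", _seg)] = {"C": 95.0, "inner": 72.0, "outer": 62.0}[ring]
    DEFAULT_BASELINE[("IS", _seg)] = {"C": 32.0, "inner": 29.0, "outer": 27.0}[ring]
    DEFAULT_BASELINE[("OS", _seg)] = {"C": 45.0, "inner": 33.0, "outer": 30.0}[ring]

DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.05,       # um per year
    "sex": 0.8,         # um, male (1) vs female (0)
    "height": 0.02,     # um per cm
    "weight": -0.01,    # um per kg
    "refraction": 0.3,  # um per diopter of mean spherical equivalent
    "machine": 0.5,     # um per machine index step
}

MACHINES = ("M1", "M2", "M3")


@dataclass
class PlantedEffect:
    """Additive per-copy effect of one SNP on one layer, per ETDRS segment."""

    snp_id: str
    layer: str
    beta_per_segment: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigError(f"unknown layer {self.layer!r}")
        self.beta_per_segment = tuple(float(b) for b in self.beta_per_segment)
        if len(self.beta_per_segment) != len(SEGMENTS):
            raise ConfigError("beta_per_segment needs exactly 9 entries")

    @classmethod
    def uniform(cls, snp_id: str, layer: str, beta: float) -> "PlantedEffect":
        return cls(snp_id, layer, (beta,) * 9)

    @classmethod
    def foveal_only(cls, snp_id: str, layer: str, beta: float) -> "PlantedEffect":
        betas = [0.0] * 9
        betas[segment_index("C")] = beta
        return cls(snp_id, layer, tuple(betas))


@dataclass
class RareGeneConfig:
    """Rare-variant content of one gene, optionally with a burden effect."""

    gene: str
    n_variants: int = 3
    var_class: str = "LoF"           # "LoF" or "missense"
    carrier_freq: float = 0.003      # per-variant alt-allele frequency
    burden_beta: float = 0.0         # um per collapsed-genotype unit
    layer: str = "ONL"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if not 0.0 < self.carrier_freq < 0.01:
            raise ConfigError(
                "carrier_freq must be in (0, 0.01): rare variants are "
                "defined by MAF < 1%")
        if self.var_class not in ("LoF", "missense"):
            raise ConfigError("var_class must be 'LoF' or 'missense'")
        if self.layer not in LAYERS:
            raise ConfigError(f"unknown layer {self.layer!r}")


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort."""

    n_individuals: int = 2000
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_overrides: dict[str, float] = field(default_factory=dict)
    ld_block_size: int = 10
    ld_rho: float = 0.3
    n_chromosomes: int = 2
    pos_start: int = 1_000_000
    pos_step: int = 50_000
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    interaction_pair: tuple[str, str, float] | None = None
    interaction_layer: str = "ONL"
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    segment_baseline: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE))
    noise_sd_individual: float = 2.0
    noise_sd_eye: float = 1.0
    poor_quality_frac: float = 0.0
    missing_eye_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ConfigError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("maf_range must lie within (0, 1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError("ld_rho must be in [0, 1)")
        if self.noise_sd_individual < 0 or self.noise_sd_eye < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        missing = [(l, s) for l in LAYERS for s in SEGMENTS
                   if (l, s) not in self.segment_baseline]
        if missing:
            raise ConfigError(
                f"segment_baseline missing {len(missing)} (layer, segment) "
                f"entries, e.g. {missing[0]}")


def _ids(n: int) -> pd.Index:
    return pd.Index([f"ind{i:06d}" for i in range(1, n + 1)],
                    name="individual_id")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Draw biallelic dosages with blockwise haplotype-copy LD.

    Two haplotypes per individual are simulated independently, so each SNP's
    genotype distribution is Hardy-Weinberg at its marginal allele frequency
    regardless of LD strength.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    ids_by_index = {f"snp{j + 1:05d}": j for j in range(m)}
    for sid, maf in config.maf_overrides.items():
        if sid not in ids_by_index:
            raise ConfigError(f"maf_overrides references unknown SNP {sid!r}")
        p[ids_by_index[sid]] = maf
    haps = np.empty((2 * n, m), dtype=np.int8)
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        haps[:, start] = rng.random(2 * n) < p[start]
        for j in range(start + 1, stop):
            fresh = rng.random(2 * n) < p[j]
            copy = rng.random(2 * n) < config.ld_rho
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    dosages = (haps[0::2] + haps[1::2]).astype(float)

    per_chr = -(-m // config.n_chromosomes)
    chrom = 1 + np.arange(m) // per_chr
    pos = config.pos_start + (np.arange(m) % per_chr) * config.pos_step
    snps = pd.DataFrame({
        "CHR": chrom.astype(int),
        "POS": pos.astype(int),
        "ID": [f"snp{j + 1:05d}" for j in range(m)],
        "REF": "A",
        "ALT": "G",
        "AF": dosages.mean(axis=0) / 2.0,
    })
    return GenotypeMatrix(dosages, snps, _ids(n))


# ---------------------------------------------------------------------------
# Population structure
# ---------------------------------------------------------------------------

def simulate_population_pcs(n_main: int,
                            n_outlier: int,
                            centroid: tuple[float, float] = DEFAULT_CENTROID,
                            radius: float = DEFAULT_RADIUS,
                            seed: int | np.random.Generator = 0,
                            n_pcs: int = 10,
                            individuals: pd.Index | None = None
                            ) -> pd.DataFrame:
    """PC coordinates with a dense main cluster and distant outliers.

    Main-cluster points are placed strictly inside ``radius`` of
    ``centroid`` in PC1-PC2 space; outliers at distance > 2 x ``radius``.
    Higher PCs are small isotropic noise.
    """
    if n_main < 0 or n_outlier < 0:
        raise ConfigError("counts must be non-negative")
    if radius <= 0:
        raise ConfigError("radius must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = n_main + n_outlier
    r_main = 0.9 * radius * np.sqrt(rng.random(n_main))
    r_out = radius * rng.uniform(2.2, 4.0, size=n_outlier)
    r = np.concatenate([r_main, r_out])
    theta = rng.uniform(0, 2 * np.pi, size=n)
    pcs = pd.DataFrame({
        "PC1": centroid[0] + r * np.cos(theta),
        "PC2": centroid[1] + r * np.sin(theta),
    })
    for k in range(3, n_pcs + 1):
        pcs[f"PC{k}"] = rng.normal(0.0, radius / 10.0, size=n)
    pcs.index = _ids(n) if individuals is None else pd.Index(individuals)
    pcs.index.name = "individual_id"
    return pcs


# ---------------------------------------------------------------------------
# Phenotypes and covariates
# ---------------------------------------------------------------------------

def _simulate_covariates(n: int, config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    ids = _ids(n)
    sex = rng.integers(0, 2, size=n)  # 1 = male
    cov = pd.DataFrame({
        "age": rng.integers(40, 70, size=n).astype(float),
        "sex": sex.astype(float),
        "height": np.where(sex == 1, rng.normal(175, 7, n),
                           rng.normal(162, 6, n)),
        "weight": np.where(sex == 1, rng.normal(85, 14, n),
                           rng.normal(72, 12, n)),
        "machine_id": rng.choice(MACHINES, size=n),
    }, index=ids)
    poor = rng.random(n) < config.poor_quality_frac
    for eye in EYES:
        cov[f"quality_{eye}"] = np.where(poor, rng.normal(38, 4, n),
                                         rng.normal(60, 6, n))
        cov[f"ilm_indicator_{eye}"] = np.where(poor, rng.normal(70, 8, n),
                                               rng.normal(100, 8, n))
        cov[f"valid_count_{eye}"] = np.where(poor, rng.normal(850, 40, n),
                                             rng.normal(1000, 40, n))
        cov[f"min_motion_corr_{eye}"] = np.where(
            poor, rng.normal(0.80, 0.03, n), rng.normal(0.95, 0.02, n))
        cov[f"max_motion_delta_{eye}"] = np.where(
            poor, rng.normal(9.0, 1.0, n), rng.normal(5.0, 1.0, n))
        cov[f"max_motion_factor_{eye}"] = np.where(
            poor, rng.normal(16.0, 2.0, n), rng.normal(10.0, 2.0, n))
        cov[f"spherical_{eye}"] = rng.normal(0.0, 1.5, n)
        cov[f"cylindrical_{eye}"] = rng.normal(-0.25, 0.5, n)
    return cov


def simulate_phenotypes(genotypes: GenotypeMatrix,
                        config: SimConfig,
                        seed: int | np.random.Generator | None = None,
                        extra_layer_offsets: dict[str, np.ndarray] | None = None,
                        ) -> tuple[ThicknessCube, pd.DataFrame]:
    """Generate the thickness cube and covariate table.

    thickness(i, layer, seg, eye) =
        baseline(layer, seg)
        + covariate effects (individual-level, plus eye-level refraction)
        + sum over planted effects of dosage_i x beta_seg   (matching layer)
        + beta_int x dosage_a x dosage_b                    (interaction layer)
        + extra layer offsets (e.g. rare-variant burden effects)
        + individual noise (shared across eyes) + eye noise

    ``extra_layer_offsets`` maps layer -> per-individual offset in um applied
    uniformly over segments (used to plant gene-burden effects).
    """
    if seed is None:
        seed = config.seed + 1
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = genotypes.n_individuals
    cov = _simulate_covariates(n, config, rng)
    eff = config.covariate_effect_sizes

    base_shift = np.zeros(n)
    for key in ("age", "sex", "height", "weight"):
        if key in eff:
            base_shift += eff[key] * cov[key].to_numpy()
    if "machine" in eff:
        base_shift += eff["machine"] * pd.Index(MACHINES).get_indexer(
            cov["machine_id"])

    values = np.zeros((n, len(LAYERS), len(SEGMENTS), len(EYES)))
    for li, layer in enumerate(LAYERS):
        for si, seg in enumerate(SEGMENTS):
            values[:, li, si, :] = config.segment_baseline[(layer, seg)]
    values += base_shift[:, None, None, None]

    if "refraction" in eff:
        for ei, eye in enumerate(EYES):
            refraction = (cov[f"spherical_{eye}"]
                          + 0.5 * cov[f"cylindrical_{eye}"]).to_numpy()
            values[:, :, :, ei] += (eff["refraction"]
                                    * refraction[:, None, None])

    for planted in config.planted_effects:
        try:
            dos = genotypes.dosage(planted.snp_id).to_numpy()
        except UnknownSNPError:
            raise UnknownSNPError(
                f"planted effect references unknown SNP {planted.snp_id!r}")
        li = LAYERS.index(planted.layer)
        betas = np.asarray(planted.beta_per_segment)
        values[:, li, :, :] += (dos[:, None] * betas[None, :])[:, :, None]

    if config.interaction_pair is not None:
        id_a, id_b, beta_int = config.interaction_pair
        prod = (genotypes.dosage(id_a).to_numpy()
                * genotypes.dosage(id_b).to_numpy())
        li = LAYERS.index(config.interaction_layer)
        values[:, li, :, :] += beta_int * prod[:, None, None]

    if extra_layer_offsets:
        for layer, offsets in extra_layer_offsets.items():
            values[:, LAYERS.index(layer), :, :] += \
                np.asarray(offsets, dtype=float)[:, None, None]

    shape_ind = (n, len(LAYERS), len(SEGMENTS))
    values += rng.normal(0.0, config.noise_sd_individual,
                         size=shape_ind)[..., None]
    values += rng.normal(0.0, config.noise_sd_eye, size=values.shape)

    if config.missing_eye_frac > 0:
        drop = rng.random(n) < config.missing_eye_frac
        which = rng.integers(0, 2, size=n)
        for i in np.nonzero(drop)[0]:
            values[i, :, :, which[i]] = np.nan

    return ThicknessCube(values, genotypes.individuals), cov


# ---------------------------------------------------------------------------
# Rare variants
# ---------------------------------------------------------------------------

def simulate_rare_variants(configs: list[RareGeneConfig],
                           n_individuals: int,
                           seed: int | np.random.Generator = 0,
                           n_decoys: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw rare carrier genotypes and a VEP/LOFTEE-style annotation table.

    Carrier genotypes are binomial(2, carrier_freq) per variant (HW).  With
    ``n_decoys`` > 0, additional non-qualifying variants (tolerated/benign
    missense, or too common) are appended per gene so consequence-class
    filtering has something to reject.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = _ids(n_individuals)
    carriers: dict[str, np.ndarray] = {}
    annot_rows = []

    def add_variant(vid, gene, cls, freq, qualifying=True, common=False):
        af = freq if not common else rng.uniform(0.02, 0.05)
        carriers[vid] = rng.binomial(2, af, size=n_individuals).astype(np.int8)
        if cls == "LoF":
            row = dict(VARIANT_ID=vid, GENE=gene, CONSEQUENCE="stop_gained",
                       LOF_HC=1 if qualifying else 0, SIFT=".",
                       POLYPHEN=".", AF=af)
        else:
            row = dict(VARIANT_ID=vid, GENE=gene,
                       CONSEQUENCE="missense_variant", LOF_HC=0,
                       SIFT="deleterious" if qualifying else "tolerated",
                       POLYPHEN=("probably_damaging" if qualifying
                                 else "benign"),
                       AF=af)
        annot_rows.append(row)

    for cfg in configs:
        for v in range(cfg.n_variants):
            add_variant(f"{cfg.gene}_rv{v + 1}", cfg.gene, cfg.var_class,
                        cfg.carrier_freq)
        for d in range(n_decoys):
            kind = d % 3
            vid = f"{cfg.gene}_decoy{d + 1}"
            if kind == 0:     # benign missense, rare
                add_variant(vid, cfg.gene, "missense", cfg.carrier_freq,
                            qualifying=False)
            elif kind == 1:   # low-confidence LoF, rare
                add_variant(vid, cfg.gene, "LoF", cfg.carrier_freq,
                            qualifying=False)
            else:             # qualifying class but too common
                add_variant(vid, cfg.gene, cfg.var_class, 0.0,
                            qualifying=True, common=True)

    carrier_df = pd.DataFrame(carriers, index=ids, dtype=np.int8)
    annot_df = pd.DataFrame(
        annot_rows, columns=["VARIANT_ID", "GENE", "CONSEQUENCE", "LOF_HC",
                             "SIFT", "POLYPHEN", "AF"])
    return carrier_df, annot_df


def burden_offsets(configs: list[RareGeneConfig],
                   carrier_df: pd.DataFrame,
                   annot_df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-layer phenotype offsets implied by planted burden effects.

    Collapses each configured gene's qualifying variants to the 0/1/2 burden
    genotype and multiplies by its ``burden_beta``.
    """
    from .burden import classify_rare_variants, collapse_gene_genotypes

    n = len(carrier_df)
    offsets = {layer: np.zeros(n) for layer in LAYERS}
    if annot_df.empty:
        return offsets
    classes = classify_rare_variants(annot_df)
    for cfg in configs:
        if cfg.burden_beta == 0.0:
            continue
        model = "LoF" if cfg.var_class == "LoF" else "missense"
        vset = classes.get(cfg.gene, {}).get(model, set())
        geno = collapse_gene_genotypes(vset, carrier_df)
        offsets[cfg.layer] += cfg.burden_beta * geno.to_numpy(dtype=float)
    return offsets


# ---------------------------------------------------------------------------
# Fixture presets
# ---------------------------------------------------------------------------

DEFAULT_DISEASE_GENES = (
    "ABCA4", "MYO7A", "NR2E3", "RDH5", "RLBP1", "RBP3", "SAG", "GRK1",
    "OCA2", "PRPH2", "CDHR1", "RAX2",
)


def _default_rare_genes(planted: bool) -> list[RareGeneConfig]:
    genes = []
    # two disease genes with planted burden effects (only when requested)
    genes.append(RareGeneConfig("ABCA4", n_variants=4, var_class="LoF",
                                carrier_freq=0.008,
                                burden_beta=2.0 if planted else 0.0))
    genes.append(RareGeneConfig("NR2E3", n_variants=3, var_class="missense",
                                carrier_freq=0.008,
                                burden_beta=-1.5 if planted else 0.0))
    # null genes, one disease-listed and three not
    genes.append(RareGeneConfig("MYO7A", n_variants=3, var_class="LoF",
                                carrier_freq=0.006))
    for g in ("GENE_A", "GENE_B", "GENE_C"):
        genes.append(RareGeneConfig(g, n_variants=3, var_class="missense",
                                    carrier_freq=0.006))
    return genes


def _preset_null(seed: int) -> dict:
    return dict(config=SimConfig(seed=seed),
                rare=_default_rare_genes(planted=False), truth={})


def _preset_differential(seed: int) -> dict:
    cfg = SimConfig(
        seed=seed,
        planted_effects=[
            PlantedEffect.foveal_only("snp00101", "ONL", 1.2),
            PlantedEffect.uniform("snp00301", "ONL", 0.6),
        ],
        maf_overrides={"snp00101": 0.3, "snp00301": 0.3},
    )
    truth = dict(differential_snp="snp00101", uniform_snp="snp00301")
    return dict(config=cfg, rare=_default_rare_genes(planted=True),
                truth=truth)


def _preset_interaction(seed: int) -> dict:
    cfg = SimConfig(
        seed=seed,
        planted_effects=[
            PlantedEffect.uniform("snp00101", "ONL", 0.5),
            PlantedEffect.uniform("snp00301", "ONL", 0.4),
        ],
        interaction_pair=("snp00101", "snp00301", 0.6),
        maf_overrides={"snp00101": 0.3, "snp00301": 0.3},
    )
    truth = dict(interaction_pair=["snp00101", "snp00301"],
                 interaction_beta=0.6)
    return dict(config=cfg, rare=_default_rare_genes(planted=False),
                truth=truth)


def _preset_burden(seed: int) -> dict:
    cfg = SimConfig(seed=seed, n_snps=200)
    truth = dict(burden_genes={"ABCA4": 2.0, "NR2E3": -1.5})
    return dict(config=cfg, rare=_default_rare_genes(planted=True),
                truth=truth)


PRESETS = {
    "null": _preset_null,
    "differential": _preset_differential,
    "interaction": _preset_interaction,
    "burden": _preset_burden,
    "qc_mixed": None,  # handled separately: hand-constructed QC failures
}


def make_fixture_cohort(preset: str, seed: int, outdir) -> dict:
    """Write a full synthetic input bundle to ``outdir``; returns a manifest.

    Files: genotypes.vcf, dosages.tsv, thickness.tsv, covariates.tsv,
    pcs.tsv, rare_carriers.tsv, rare_annotations.tsv, disease_genes.txt,
    related_exclude.txt, truth.json.  Deterministic per (preset, seed).
    """
    if preset not in PRESETS:
        raise ConfigError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "qc_mixed":
        return _make_qc_mixed(seed, outdir)

    spec = PRESETS[preset](seed)
    config: SimConfig = spec["config"]
    rng = np.random.default_rng(seed)
    genotypes = simulate_genotypes(config, rng)
    carriers, annotations = simulate_rare_variants(
        spec["rare"], config.n_individuals, rng, n_decoys=3)
    offsets = burden_offsets(spec["rare"], carriers, annotations)
    cube, cov = simulate_phenotypes(genotypes, config, rng,
                                    extra_layer_offsets=offsets)
    pcs = simulate_population_pcs(config.n_individuals, 0, seed=rng,
                                  individuals=genotypes.individuals)

    genotypes.to_vcf(outdir / "genotypes.vcf")
    genotypes.to_tsv(outdir / "dosages.tsv")
    cube.to_tsv(outdir / "thickness.tsv")
    cov.to_csv(outdir / "covariates.tsv", sep="\t", float_format="%.6f")
    pcs.to_csv(outdir / "pcs.tsv", sep="\t", float_format="%.8g")
    carriers.to_csv(outdir / "rare_carriers.tsv", sep="\t")
    annotations.to_csv(outdir / "rare_annotations.tsv", sep="\t", index=False,
                       float_format="%.6g")
    (outdir / "disease_genes.txt").write_text(
        "\n".join(DEFAULT_DISEASE_GENES) + "\n")
    (outdir / "related_exclude.txt").write_text("")
    truth = dict(preset=preset, seed=seed,
                 n_individuals=config.n_individuals,
                 n_snps=config.n_snps, **spec["truth"])
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    logger.info("fixture preset %r written to %s", preset, outdir)
    return truth


def _make_qc_mixed(seed: int, outdir: Path) -> dict:
    """Cohort with known planted QC failures, one filter each.

    Group sizes (in filter order): 30 ancestry outliers, 15 related, 12
    low-image-quality, 10 poor on every segmentation indicator, 8 refractive
    outliers; 475 clean survivors.  Clean individuals share constant
    indicator values so the 20%-quantile rule (strictly-worse-than-quantile,
    ties retained) removes exactly the planted group and is idempotent.
    """
    rng = np.random.default_rng(seed)
    counts = dict(ancestry=30, related=15, quality=12, indicator=10,
                  refraction=8)
    n_clean = 475
    n = n_clean + sum(counts.values())  # 550
    config = SimConfig(n_individuals=n, n_snps=100, seed=seed)
    genotypes = simulate_genotypes(config, rng)
    cube, cov = simulate_phenotypes(genotypes, config, rng)
    ids = genotypes.individuals

    # assign disjoint failure groups deterministically by position
    cursor = 0
    groups = {}
    for name, k in counts.items():
        groups[name] = ids[cursor:cursor + k]
        cursor += k
    clean = ids[cursor:]

    pcs = simulate_population_pcs(n - counts["ancestry"], counts["ancestry"],
                                  seed=rng)
    # reorder: outliers are generated last by simulate_population_pcs; map
    # them onto the ancestry group
    order = np.concatenate([
        np.arange(n - counts["ancestry"], n),          # outliers -> ancestry
        np.arange(0, n - counts["ancestry"]),
    ])
    pcs = pcs.iloc[order].set_axis(ids)
    pcs.index.name = "individual_id"

    # overwrite QC covariates with constructed values
    good_vals = dict(quality=60.0, ilm_indicator=100.0, valid_count=1000.0,
                     min_motion_corr=0.95, max_motion_delta=5.0,
                     max_motion_factor=10.0)
    bad_vals = dict(ilm_indicator=70.0, valid_count=850.0,
                    min_motion_corr=0.80, max_motion_delta=9.0,
                    max_motion_factor=16.0)
    for eye in EYES:
        for key, val in good_vals.items():
            cov[f"{key}_{eye}"] = val
        cov.loc[groups["quality"], f"quality_{eye}"] = 40.0
        for key, val in bad_vals.items():
            cov.loc[groups["indicator"], f"{key}_{eye}"] = val
        # refraction: clean spread on a fixed grid, outliers far outside
        grid = np.linspace(-1.0, 1.0, n)
        cov[f"spherical_{eye}"] = grid
        cov[f"cylindrical_{eye}"] = 0.0
        cov.loc[groups["refraction"], f"spherical_{eye}"] = \
            np.where(np.arange(counts["refraction"]) % 2 == 0, 9.0, -9.0)

    genotypes.to_vcf(outdir / "genotypes.vcf")
    genotypes.to_tsv(outdir / "dosages.tsv")
    cube.to_tsv(outdir / "thickness.tsv")
    cov.to_csv(outdir / "covariates.tsv", sep="\t", float_format="%.6f")
    pcs.to_csv(outdir / "pcs.tsv", sep="\t", float_format="%.8g")
    carriers, annotations = simulate_rare_variants(
        _default_rare_genes(planted=False), n, rng)
    carriers.to_csv(outdir / "rare_carriers.tsv", sep="\t")
    annotations.to_csv(outdir / "rare_annotations.tsv", sep="\t", index=False,
                       float_format="%.6g")
    (outdir / "disease_genes.txt").write_text(
        "\n".join(DEFAULT_DISEASE_GENES) + "\n")
    (outdir / "related_exclude.txt").write_text(
        "\n".join(groups["related"]) + "\n")
    truth = dict(preset="qc_mixed", seed=seed, n_individuals=n,
                 n_snps=100, planted_exclusions=counts,
                 n_surviving=n_clean)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
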