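"""End-to-end orchestration and the ``prcgwas`` command-line interface.

Stages run in the order the analysis is defined: synthetic-cohort
generation (optional), cohort QC, phenotype construction, per-layer GWAS
with min-p meta and locus selection, concentric-field differential analysis
with LD clumping and segment effect maps, rare-variant gene-burden testing,
and the secondary battery (interactions, disease-gene enrichment,
stratified grid means).  Every stage persists its outputs under the run
directory and appends to a JSON manifest (seed, per-stage row counts, wall
order), so stages can also be run individually from the CLI against a
previous stage's files.

All randomness flows from one master seed, split per stage with
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import cohort_qc, gwas, phenotypes, secondary, spatial, synthio
from ._core import (
    FIELDS,
    LAYERS,
    ConfigError,
    GenotypeMatrix,
    ThicknessCube,
    logger,
)

STAGES = ("simulate", "qc", "pheno", "gwas", "spatial", "burden",
          "secondary")


@dataclass
class RunConfig:
    """Paths, thresholds and per-stage parameter blocks for one run."""

    outdir: str = "prcgwas_run"
    seed: int = 0
    preset: str = "differential"
    # input paths; None means "use the file the simulate stage wrote"
    genotypes: str | None = None
    thickness: str | None = None
    covariates: str | None = None
    pcs: str | None = None
    related: str | None = None
    rare_carriers: str | None = None
    rare_annotations: str | None = None
    disease_genes: str | None = None
    qc: dict = dc_field(default_factory=dict)
    gwas: dict = dc_field(default_factory=lambda: dict(
        p_threshold=5e-8, min_sep=10_000_000, group_window=1_500_000,
        n_pcs=20))
    spatial: dict = dc_field(default_factory=lambda: dict(
        r2_min=0.05, window=1_000_000, max_maps=4))
    burden: dict = dc_field(default_factory=lambda: dict(
        threshold=5e-5, maf_max=0.01))
    secondary: dict = dc_field(default_factory=lambda: dict(
        fdr=0.15, max_partners=20))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("genotypes", "thickness", "covariates", "pcs",
                    "related", "rare_carriers", "rare_annotations",
                    "disease_genes"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"configured input {key}={val!r} "
                                  "does not exist")
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class PipelineRun:
    """Stateful runner: each stage reads persisted outputs of earlier ones."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists()
                         else {"seed": config.seed, "stages": []})
        seq = np.random.SeedSequence(config.seed)
        self._stage_seeds = {
            name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGES, seq.spawn(len(STAGES)))
        }

    # -- manifest helpers ---------------------------------------------------

    def _log_stage(self, name: str, counts: dict) -> None:
        self.manifest["stages"] = [s for s in self.manifest["stages"]
                                   if s["stage"] != name]
        self.manifest["stages"].append(
            dict(stage=name, time=time.time(), **counts))
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _input(self, key: str, default_name: str) -> Path:
        configured = getattr(self.config, key)
        path = Path(configured) if configured else self.outdir / default_name
        if not path.exists():
            raise ConfigError(
                f"stage input {key} not found at {path}; run the earlier "
                "stages or configure the path")
        return path

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> dict:
        truth = synthio.make_fixture_cohort(
            self.config.preset, self._stage_seeds["simulate"], self.outdir)
        self._log_stage("simulate", dict(
            n_individuals=truth["n_individuals"], n_snps=truth["n_snps"]))
        return truth

    def _load_genotypes(self) -> GenotypeMatrix:
        path = self._input("genotypes", "dosages.tsv")
        if path.suffix == ".vcf":
            return GenotypeMatrix.from_vcf(path)
        return GenotypeMatrix.from_tsv(path)

    def _load_covariates(self) -> pd.DataFrame:
        return pd.read_csv(self._input("covariates", "covariates.tsv"),
                           sep="\t", index_col="individual_id")

    def stage_qc(self) -> pd.Index:
        pcs = pd.read_csv(self._input("pcs", "pcs.tsv"), sep="\t",
                          index_col="individual_id")
        cov = self._load_covariates()
        related_path = self._input("related", "related_exclude.txt")
        related = [line.strip() for line in
                   related_path.read_text().splitlines() if line.strip()]
        thresholds = cohort_qc.QCThresholds(**self.config.qc)
        cohort, report = cohort_qc.apply_cohort_qc(pcs, cov, related,
                                                   thresholds)
        report.to_json(self.outdir / "qc_report.json")
        pd.Series(cohort, name="individual_id").to_csv(
            self.outdir / "cohort_ids.txt", index=False, header=False)
        self._log_stage("qc", dict(n_input=len(pcs), n_cohort=len(cohort)))
        return cohort

    def _cohort(self) -> pd.Index:
        path = self.outdir / "cohort_ids.txt"
        if not path.exists():
            raise ConfigError("cohort_ids.txt not found: run the qc stage")
        return pd.Index([ln.strip() for ln in path.read_text().splitlines()
                         if ln.strip()], name="individual_id")

    def stage_pheno(self) -> pd.DataFrame:
        cohort = self._cohort()
        cube = ThicknessCube.from_tsv(
            self._input("thickness", "thickness.tsv")).subset_individuals(
            cohort)
        cov = self._load_covariates().loc[cohort]
        table = phenotypes.build_phenotypes(cube, cov)
        table.to_csv(self.outdir / "phenotypes.tsv", sep="\t", index=False,
                     float_format="%.6f")
        self._log_stage("pheno", dict(n_rows=len(table)))
        return table

    def _phenotype_table(self) -> pd.DataFrame:
        path = self.outdir / "phenotypes.tsv"
        if not path.exists():
            raise ConfigError("phenotypes.tsv not found: run pheno stage")
        return pd.read_csv(path, sep="\t")

    def _assoc_covariates(self, ids: pd.Index) -> pd.DataFrame:
        """Association-model covariates: age, weight, sex, height, machine
        ID (one-hot in the design) and the first genotype PCs."""
        cov = self._load_covariates().loc[ids]
        pcs = pd.read_csv(self._input("pcs", "pcs.tsv"), sep="\t",
                          index_col="individual_id").loc[ids]
        n_pcs = min(self.config.gwas.get("n_pcs", 20), pcs.shape[1])
        keep = cov[["age", "weight", "sex", "height", "machine_id"]]
        return pd.concat([keep, pcs.iloc[:, :n_pcs]], axis=1)

    def stage_gwas(self) -> dict:
        table = self._phenotype_table()
        genotypes = self._load_genotypes()
        cohort = self._cohort()
        acov = self._assoc_covariates(cohort)
        params = self.config.gwas
        results = {}
        lambdas = {}
        for layer in LAYERS:
            pheno = phenotypes.phenotype_series(table, layer, "grid")
            res = gwas.run_additive_gwas(pheno, genotypes, acov)
            gwas.write_summary_stats(res, self.outdir / f"gwas_{layer}.tsv")
            results[layer] = res
            lambdas[layer] = gwas.compute_lambda_gc(res["P"].dropna())
        meta = gwas.meta_min_p(results["ONL"], results["IS"], results["OS"])
        meta.to_csv(self.outdir / "gwas_meta.tsv", sep="\t", index=False,
                    float_format="%.6g")
        loci = gwas.select_independent_loci(
            meta, p_threshold=params.get("p_threshold", 5e-8),
            min_sep=params.get("min_sep", 10_000_000),
            group_window=params.get("group_window", 1_500_000))
        loci.to_csv(self.outdir / "loci.tsv", sep="\t", index=False,
                    float_format="%.6g")
        (self.outdir / "lambda_gc.json").write_text(json.dumps(
            {k: round(v, 4) for k, v in lambdas.items()}, indent=2))
        self._log_stage("gwas", dict(n_snps=len(meta), n_loci=len(loci),
                                     lambda_gc=lambdas))
        return dict(results=results, meta=meta, loci=loci, lambdas=lambdas)

    def stage_spatial(self) -> pd.DataFrame:
        table = self._phenotype_table()
        genotypes = self._load_genotypes()
        cohort = self._cohort()
        acov = self._assoc_covariates(cohort)
        params = self.config.spatial
        all_diff = []
        field_scans: dict[tuple[str, str], pd.DataFrame] = {}
        for layer in LAYERS:
            for fld in FIELDS:
                pheno = phenotypes.phenotype_series(table, layer, fld)
                field_scans[(layer, fld)] = gwas.run_additive_gwas(
                    pheno, genotypes, acov)
        for layer in LAYERS:
            for f1, f2 in spatial.COMPARISONS:
                diff = spatial.compare_concentric_fields(
                    field_scans[(layer, f1)], field_scans[(layer, f2)],
                    layer=layer, comparison=f"{f1}-{f2}")
                if not diff.empty:
                    all_diff.append(diff)
        diff = (pd.concat(all_diff, ignore_index=True) if all_diff
                else pd.DataFrame(columns=spatial.DIFF_COLUMNS))
        sig = diff[diff["SIGNIFICANT"]] if not diff.empty else diff
        clumped = spatial.clump_by_ld(
            sig, genotypes, r2_min=params.get("r2_min", 0.05),
            window=params.get("window", 1_000_000))
        diff.to_csv(self.outdir / "differential.tsv", sep="\t", index=False,
                    float_format="%.6g")
        clumped.to_csv(self.outdir / "differential_leads.tsv", sep="\t",
                       index=False, float_format="%.6g")

        # segment effect maps for the lead SNPs (bounded count)
        cube = ThicknessCube.from_tsv(
            self._input("thickness", "thickness.tsv")).subset_individuals(
            self._cohort())
        cov = self._load_covariates().loc[self._cohort()]
        leads = (clumped[clumped["LEAD"]] if not clumped.empty else clumped)
        maps = []
        for _, row in leads.head(params.get("max_maps", 4)).iterrows():
            emap = spatial.segment_effect_map(
                row["ID"], cube, cov, genotypes, row["LAYER"],
                assoc_covariates=acov)
            maps.append(emap)
            try:
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt
                ax = spatial.plot_segment_map(emap)
                ax.figure.savefig(
                    self.outdir / f"map_{row['ID']}_{row['LAYER']}.png",
                    dpi=100)
                plt.close(ax.figure)
            except Exception as exc:  # rendering must not kill the run
                logger.warning("segment-map rendering failed: %s", exc)
        if maps:
            pd.concat(maps, ignore_index=True).to_csv(
                self.outdir / "segment_effects.tsv", sep="\t", index=False,
                float_format="%.6g")
        self._log_stage("spatial", dict(
            n_tests=len(diff), n_significant=int(len(sig)),
            n_leads=int(clumped["LEAD"].sum()) if not clumped.empty else 0))
        return diff

    def stage_burden(self) -> pd.DataFrame:
        cohort = self._cohort()
        table = self._phenotype_table()
        acov = self._assoc_covariates(cohort)
        carriers = pd.read_csv(
            self._input("rare_carriers", "rare_carriers.tsv"), sep="\t",
            index_col="individual_id")
        annotations = pd.read_csv(
            self._input("rare_annotations", "rare_annotations.tsv"),
            sep="\t")
        params = self.config.burden
        frames = []
        for layer in LAYERS:
            pheno = phenotypes.phenotype_series(table, layer, "grid")
            res = burden_mod.run_burden_scan(
                annotations, carriers.loc[carriers.index.intersection(
                    cohort)], pheno, acov,
                threshold=params.get("threshold", 5e-5),
                maf_max=params.get("maf_max", 0.01))
            res.insert(0, "LAYER", layer)
            frames.append(res)
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(self.outdir / "burden.tsv", sep="\t", index=False,
                   float_format="%.6g")
        self._log_stage("burden", dict(
            n_tests=int(out["TESTABLE"].sum()),
            n_significant=int(out["SIGNIFICANT"].sum())))
        return out

    def stage_secondary(self) -> dict:
        cohort = self._cohort()
        table = self._phenotype_table()
        genotypes = self._load_genotypes()
        acov = self._assoc_covariates(cohort)
        cov = self._load_covariates().loc[cohort]
        params = self.config.secondary
        loci_path = self.outdir / "loci.tsv"
        loci = (pd.read_csv(loci_path, sep="\t") if loci_path.exists()
                and loci_path.stat().st_size > 0 else pd.DataFrame())
        lead_ids = list(loci["ID"]) if "ID" in loci else []
        cap = params.get("max_partners", 20)
        lead_ids = lead_ids[:cap]

        burden_path = self.outdir / "burden.tsv"
        burden_df = (pd.read_csv(burden_path, sep="\t")
                     if burden_path.exists() else pd.DataFrame())

        # interaction battery on the ONL whole-grid phenotype
        pheno = phenotypes.phenotype_series(table, "ONL", "grid")
        sex = cov["sex"]
        burden_genos = {}
        burden_partners = {}
        if not burden_df.empty:
            carriers = pd.read_csv(
                self._input("rare_carriers", "rare_carriers.tsv"), sep="\t",
                index_col="individual_id")
            annotations = pd.read_csv(
                self._input("rare_annotations", "rare_annotations.tsv"),
                sep="\t")
            classes = burden_mod.classify_rare_variants(annotations)
            sig_genes = burden_df.loc[
                burden_df.get("SIGNIFICANT", pd.Series(dtype=bool)).fillna(
                    False), ["GENE", "MODEL"]].drop_duplicates()
            for _, row in sig_genes.iterrows():
                vset = classes.get(row["GENE"], {}).get(row["MODEL"], set())
                if vset:
                    burden_genos[row["GENE"]] = \
                        burden_mod.collapse_gene_genotypes(vset, carriers)
                    burden_partners[row["GENE"]] = lead_ids[:5]
        anchor = lead_ids[0] if lead_ids else None
        pairs = secondary.build_battery(
            genotypes, lead_ids, anchor=anchor,
            sets={"leads": lead_ids[:6]} if len(lead_ids) >= 2 else None,
            sex=sex, burden_genotypes=burden_genos,
            burden_partners=burden_partners)
        battery = secondary.run_interaction_battery(
            pairs, pheno, acov, fdr=params.get("fdr", 0.15), layer="ONL")
        battery.to_csv(self.outdir / "interactions.tsv", sep="\t",
                       index=False, float_format="%.6g")

        # disease-gene enrichment of significant burden genes
        enrichment = {}
        disease_path = self._input("disease_genes", "disease_genes.txt")
        disease = {ln.strip() for ln in disease_path.read_text().splitlines()
                   if ln.strip()}
        if not burden_df.empty:
            tested = set(burden_df.loc[burden_df["TESTABLE"], "GENE"])
            sig = set(burden_df.loc[burden_df["SIGNIFICANT"].fillna(False),
                                    "GENE"])
            N = len(tested)
            K = len(tested & disease)
            n = len(sig)
            k = len(sig & disease)
            if n and K:
                enrichment = dict(N=N, K=K, n=n, k=k,
                                  p=secondary.hypergeometric_overlap(
                                      k, n, K, N))
        (self.outdir / "enrichment.json").write_text(
            json.dumps(enrichment, indent=2))

        # stratified grid means for the top interaction discovery
        strat_rows = 0
        disc = battery[battery["DISCOVERY"]] if not battery.empty else battery
        disc = disc[disc["CATEGORY"].isin(["anchor", "pairwise:leads"])] \
            if not disc.empty else disc
        if not disc.empty:
            top = disc.sort_values("P").iloc[0]
            cube = ThicknessCube.from_tsv(
                self._input("thickness", "thickness.tsv")
            ).subset_individuals(cohort)
            strat = secondary.stratified_segment_means(
                cube, genotypes.dosage(top["TERM1"]),
                genotypes.dosage(top["TERM2"]), layer="ONL")
            strat.to_csv(self.outdir / "stratified_means.tsv", sep="\t",
                         index=False, float_format="%.6g")
            strat_rows = len(strat)
        self._log_stage("secondary", dict(
            n_pairs=len(battery),
            n_discoveries=int(battery["DISCOVERY"].sum())
            if not battery.empty else 0,
            enrichment=enrichment, n_stratified_rows=strat_rows))
        return dict(battery=battery, enrichment=enrichment)

    def run_all(self, simulate: bool = True) -> dict:
        """Execute every stage in order; abort with stage name on error."""
        out = {}
        order = STAGES if simulate else STAGES[1:]
        for name in order:
            try:
                out[name] = getattr(self, f"stage_{name}")()
            except Exception:
                logger.error("pipeline aborted in stage %r", name)
                self._log_stage(f"{name}:failed", {})
                raise
        return out


def run_pipeline(config: RunConfig, simulate: bool = True) -> dict:
    return PipelineRun(config).run_all(simulate=simulate)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging.")
def cli(verbose):
    """GWAS pipeline for photoreceptor-layer thickness on the ETDRS grid."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s")


def _load_config(config_path, outdir=None, seed=None, preset=None):
    cfg = (RunConfig.from_yaml(config_path) if config_path else RunConfig())
    if outdir is not None:
        cfg.outdir = outdir
    if seed is not None:
        cfg.seed = seed
    if preset is not None:
        cfg.preset = preset
    return cfg


config_opt = click.option("--config", "config_path", default=None,
                          type=click.Path(exists=True),
                          help="YAML run configuration.")
outdir_opt = click.option("--out", "outdir", default=None,
                          help="Run directory (overrides config).")
seed_opt = click.option("--seed", default=None, type=int,
                        help="Master seed (overrides config).")


def _stage_command(name, extra_help=""):
    @cli.command(name=name, help=f"Run the {name} stage.{extra_help}")
    @config_opt
    @outdir_opt
    @seed_opt
    def _cmd(config_path, outdir, seed):
        cfg = _load_config(config_path, outdir, seed)
        getattr(PipelineRun(cfg), f"stage_{name}")()
    return _cmd


for _name in ("qc", "pheno", "spatial", "burden", "secondary"):
    _stage_command(_name)


@cli.command(name="simulate")
@config_opt
@outdir_opt
@seed_opt
@click.option("--preset", default=None,
              type=click.Choice(sorted(synthio.PRESETS)),
              help="Fixture preset (overrides config).")
def simulate_cmd(config_path, outdir, seed, preset):
    """Generate a synthetic input bundle."""
    cfg = _load_config(config_path, outdir, seed, preset)
    PipelineRun(cfg).stage_simulate()


@cli.command(name="gwas")
@config_opt
@outdir_opt
@seed_opt
@click.option("--threshold", default=None, type=float,
              help="Genome-wide significance threshold.")
@click.option("--min-sep", default=None, type=int,
              help="Minimum lead separation in bp.")
@click.option("--group-window", default=None, type=int,
              help="Locus grouping window in bp.")
def gwas_cmd(config_path, outdir, seed, threshold, min_sep, group_window):
    """Run the per-layer GWAS, min-p meta and locus selection."""
    cfg = _load_config(config_path, outdir, seed)
    if threshold is not None:
        cfg.gwas["p_threshold"] = threshold
    if min_sep is not None:
        cfg.gwas["min_sep"] = min_sep
    if group_window is not None:
        cfg.gwas["group_window"] = group_window
    PipelineRun(cfg).stage_gwas()


@cli.command(name="all")
@config_opt
@outdir_opt
@seed_opt
@click.option("--preset", default=None,
              type=click.Choice(sorted(synthio.PRESETS)))
@click.option("--no-simulate", is_flag=True,
              help="Skip generation; use configured input paths.")
def all_cmd(config_path, outdir, seed, preset, no_simulate):
    """Run every stage end-to-end."""
    cfg = _load_config(config_path, outdir, seed, preset)
    run_pipeline(cfg, simulate=not no_simulate)


if __name__ == "__main__":
    cli()
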