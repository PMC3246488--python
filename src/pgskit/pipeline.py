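"""End-to-end orchestration: QC -> scores -> r2 -> scans -> regions -> recovery.

A single flat-key YAML config drives the run; every stage writes its output
under the run directory and the manifest (JSON) echoes the resolved config,
package version, and the files each stage produced, so a run can be
reproduced bit-identically from the manifest alone. Stages whose inputs are
absent (no panels, no catalog) are skipped and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from . import __version__
from . import assoc as assoc_mod
from . import cohort as cohort_mod
from . import genio, regions as regions_mod, scoring, varexp

log = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat-key pipeline configuration (see ``RunConfig.from_yaml``)."""

    out_dir: str
    genotypes: str | None = None
    samples: str | None = None
    panels: list[str] = dc_field(default_factory=list)
    catalog: str | None = None
    simulate: bool = False
    sim_n_snps: int = 2000
    sim_n_causal: int = 180
    sim_score_variance_share: float = 0.08
    maf_min: float = 0.02
    hwe_p_min: float = 1e-4
    call_rate_min: float = 0.95
    score_kinds: list[str] = dc_field(default_factory=lambda: ["unweighted", "weighted"])
    assoc_methods: list[str] = dc_field(default_factory=lambda: ["ols", "gc", "mg"])
    seed_p: float = 5e-4
    extend_p: float = 5e-3
    max_gap: int = 25_000
    top_k: int = 100
    recovery_window: int = 250_000
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise PipelineConfigError("config must set out_dir")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genotypes", "samples"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineConfigError(
                        f"{name} path required unless simulate: true")
                if not Path(p).exists():
                    raise PipelineConfigError(f"{name} path does not exist: {p}")
            for p in self.panels:
                if not Path(p).exists():
                    raise PipelineConfigError(f"panel path does not exist: {p}")
            if self.catalog and not Path(self.catalog).exists():
                raise PipelineConfigError(
                    f"catalog path does not exist: {self.catalog}")
        for t in (self.maf_min, self.hwe_p_min, self.call_rate_min):
            if not 0 <= t <= 1:
                raise PipelineConfigError("QC thresholds must be in [0, 1]")
        bad = set(self.score_kinds) - {"unweighted", "weighted", "genotypic"}
        if bad:
            raise PipelineConfigError(f"unknown score kinds: {sorted(bad)}")
        bad = set(self.assoc_methods) - {"ols", "gc", "mg"}
        if bad:
            raise PipelineConfigError(f"unknown association methods: {sorted(bad)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "config": {k: getattr(config, k)
                                 for k in config.__dataclass_fields__},
                      "stages": {}}

    def record(stage: str, **files):
        manifest["stages"][stage] = {k: str(v) for k, v in files.items()}

    # -- inputs -------------------------------------------------------------
    if config.simulate:
        try:
            sim = cohort_mod.SimConfig(n_snps=config.sim_n_snps,
                                       rng_seed=config.rng_seed)
            samples = cohort_mod.simulate_pedigrees(sim)
            gm = cohort_mod.drop_genotypes(samples, sim)
            truth = cohort_mod.make_true_panel(
                gm, config.sim_n_causal, config.sim_score_variance_share,
                rng_seed=config.rng_seed)
            samples = cohort_mod.simulate_phenotype(gm, samples, truth,
                                                    rng_seed=config.rng_seed)
            panel = cohort_mod.perturb_effect_panel(
                truth, gm, est_se=0.05, sign_flip_fraction=0.0,
                rng_seed=config.rng_seed)
            samples_path = out / "samples.tsv"
            cohort_mod.write_sample_table(samples, samples_path)
            geno_prefix = out / "genotypes"
            genio.write_matrix_tsv(gm, geno_prefix)
            panel_path = out / "panel_true.tsv"
            scoring.write_panel_tsv(panel, panel_path)
            panels = [panel_path]
            record("simulate", samples=samples_path, genotypes=geno_prefix,
                   panel=panel_path)
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
    else:
        try:
            gm = genio.read_genotypes(config.genotypes)
            samples = cohort_mod.read_sample_table(config.samples)
            panels = list(config.panels)
        except Exception as exc:
            raise StageError("load", str(exc)) from exc

    # -- QC -----------------------------------------------------------------
    try:
        gm, qc_report = genio.snp_qc_filter(
            gm, config.maf_min, config.hwe_p_min, config.call_rate_min)
        qc_path = out / "qc_report.tsv"
        qc_report.write_tsv(qc_path)
        record("qc", report=qc_path)
    except Exception as exc:
        raise StageError("qc", str(exc)) from exc

    # -- covariate adjustment ------------------------------------------------
    try:
        samples = samples[samples["sample_id"].isin(gm.sample_ids)]
        model = varexp.adjust_phenotype(samples)
        gm_model = gm.subset_samples(model.sample_ids)
        record("adjust")
    except Exception as exc:
        raise StageError("adjust", str(exc)) from exc

    # -- scores and r2 --------------------------------------------------------
    scores: list[scoring.ScoreSet] = []
    if panels:
        try:
            for panel_path in panels:
                panel = scoring.read_panel_tsv(panel_path)
                aligned = scoring.align_panel(panel, gm_model)
                name = Path(panel_path).stem
                for kind in config.score_kinds:
                    if kind == "genotypic" and not set(
                            scoring.GENOTYPE_WEIGHT_COLUMNS) <= set(panel.columns):
                        log.info("panel %s lacks genotype weights; skipping "
                                 "genotypic score", name)
                        continue
                    sc = scoring.compute_score(gm_model, aligned, kind, name)
                    sc.write_tsv(out / f"score_{name}_{kind}.tsv")
                    scores.append(sc)
            r2 = varexp.r2_table(model, scores)
            r2_path = out / "variance_explained.tsv"
            r2.to_csv(r2_path, sep="\t", index=False)
            record("scores_r2", table=r2_path)
        except Exception as exc:
            raise StageError("scores_r2", str(exc)) from exc
    else:
        log.info("no effect panels configured; skipping score and r2 stages")

    # -- association scans ----------------------------------------------------
    scans: dict[str, object] = {}
    try:
        y = model.residuals
        if {"ols", "gc"} & set(config.assoc_methods):
            ols = assoc_mod.ols_scan(y, gm_model)
            scans["ols"] = ols
            assoc_mod.write_assoc_tsv(ols, out / "assoc_ols.tsv")
        if "gc" in config.assoc_methods:
            lam = assoc_mod.gc_lambda(scans["ols"]["chi2"])
            gc = assoc_mod.gc_correct(scans["ols"], lam)
            scans["gc"] = gc.assoc
            manifest["gc_lambda"] = gc.lambda_raw
            assoc_mod.write_assoc_tsv(gc.assoc, out / "assoc_gc.tsv")
        if "mg" in config.assoc_methods:
            kin = assoc_mod.genomic_kinship(gm_model)
            vc = assoc_mod.fit_null_lmm(y, kin)
            manifest["variance_components"] = {
                "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2}
            mg = assoc_mod.mg_scan(y, gm_model, vc, kin)
            scans["mg"] = mg
            assoc_mod.write_assoc_tsv(mg, out / "assoc_mg.tsv")
        record("assoc", **{m: out / f"assoc_{m}.tsv" for m in scans})
    except Exception as exc:
        raise StageError("assoc", str(exc)) from exc

    # -- regions and recovery --------------------------------------------------
    catalog = None
    if config.catalog:
        catalog = regions_mod.read_catalog_tsv(config.catalog)
    recovery_counts = {}
    try:
        for method, scan in scans.items():
            regs = regions_mod.build_regions(scan, config.seed_p,
                                             config.extend_p, config.max_gap)
            top = regions_mod.top_regions(regs, config.top_k)
            regions_mod.write_regions_tsv(top, out / f"regions_{method}.tsv")
            if catalog is not None:
                rep = regions_mod.recover_known_loci(top, catalog,
                                                     config.recovery_window)
                rep.table.to_csv(out / f"recovery_{method}.tsv",
                                 sep="\t", index=False)
                recovery_counts[method] = rep.n_recovered
        if recovery_counts:
            manifest["recovered_loci"] = recovery_counts
        record("regions", **{m: out / f"regions_{m}.tsv" for m in scans})
    except Exception as exc:
        raise StageError("regions", str(exc)) from exc

    # -- concordance ------------------------------------------------------------
    if panels and "ols" in scans:
        try:
            conc_rows = []
            # re-scan on cm-scale residuals so cohort betas share the
            # panels' phenotype units (p-values are unchanged)
            scan_cm = assoc_mod.ols_scan(
                model.residuals * model.residual_scale, gm_model)
            for panel_path in panels:
                panel = scoring.read_panel_tsv(panel_path)
                res = regions_mod.panel_concordance(panel, scan_cm)
                res.per_snp.to_csv(
                    out / f"concordance_{Path(panel_path).stem}.tsv",
                    sep="\t", index=False)
                conc_rows.append({
                    "panel": Path(panel_path).stem,
                    "pearson_rho": res.pearson_rho,
                    "n_shared": res.n_shared,
                    "n_sign_discordant": res.n_sign_discordant,
                    "rho_concordant_subset": res.rho_concordant_subset,
                    "n_het_nominal": res.n_het_nominal,
                    "n_het_bonferroni": res.n_het_bonferroni})
            manifest["concordance"] = conc_rows
            record("concordance")
        except Exception as exc:
            raise StageError("concordance", str(exc)) from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
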