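"""Declarative pipeline configuration and the end-to-end orchestrator.

Configuration is a single YAML/dict with CLI overrides (precedence
CLI > file > defaults). Every threshold is validated against its
documented domain before any stage runs, and unknown keys are rejected.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import __version__
from .errors import ConfigError

logger = logging.getLogger(__name__)


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cases: int = Field(default=97, gt=0)
    n_severe: int = Field(default=34, gt=0)
    n_replication: int = Field(default=147, gt=0)
    n_reference: int = Field(default=1000, gt=0)
    n_genes: int = Field(default=200, gt=0)
    variants_per_gene: int = Field(default=30, gt=0)


class PipelineConfig(BaseModel):
    """All thresholds of the pipeline, each constrained to its documented domain."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "tinvar_out"
    seed: int = Field(default=0, ge=0)
    rare_maf: float = Field(default=0.01, gt=0, le=0.5)
    cadd_damaging: float = Field(default=20, ge=0)
    pli_intolerant: float = Field(default=0.9, ge=0, le=1)
    loeuf_intolerant: float = Field(default=0.5, gt=0)
    loeuf_bin_max: int = Field(default=2, ge=0, le=9)
    blacklist_threshold: float = Field(default=0.66, ge=0, le=1)
    known_sv_threshold: float = Field(default=0.99, ge=0, le=1)
    sv_min_bp: int = Field(default=1_000, gt=0)
    sv_max_bp: int = Field(default=1_000_000, gt=0)
    ultra_rare_freq: float = Field(default=0.001, ge=0, le=1)
    thi_severe: float = Field(default=58, ge=0, le=100)
    tfi_chronic: float = Field(default=48, ge=0, le=100)
    alpha: float = Field(default=0.05, gt=0, le=1)
    counting: str = Field(default="alleles", pattern="^(alleles|carriers)$")
    simulation: SimulationSection = Field(default_factory=SimulationSection)

    @classmethod
    def load(cls, path=None, **overrides) -> "PipelineConfig":
        data = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            cfg = cls(**data)
        except PydanticValidationError as e:
            raise ConfigError(str(e)) from None
        if cfg.sv_min_bp >= cfg.sv_max_bp:
            raise ConfigError(
                f"SV size window inverted: [{cfg.sv_min_bp}, {cfg.sv_max_bp}]"
            )
        return cfg

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """simulate -> classify -> burden-snv -> sv-filter -> burden-sv -> clinical.

    Runs the whole pipeline on a simulated study at the configured sizes,
    writing TSV outputs plus a run manifest (config hash, seed, version)
    into ``config.outdir``. Deterministic: same config + seed gives
    byte-identical outputs.
    """
    from . import burden, classify, clinical, simulate, sv
    from .io import write_clinical, write_constraint_table, write_regions_bed, write_sv_calls

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sim = simulate.SimulationConfig(seed=config.seed,
                                    **config.simulation.model_dump())
    sites = simulate.simulate_sites(sim)
    panel = simulate.generate_reference_panel(sim, name="REF", sites=sites)
    discovery = simulate.generate_case_cohort(sim, panel, "discovery", sites=sites)
    replication = simulate.generate_case_cohort(sim, panel, "replication", sites=sites)
    constraint = simulate.generate_constraint_table(sim)

    paths["cases_vcf"] = Path(discovery.to_vcf(out / "cases.vcf"))
    paths["replication_vcf"] = Path(replication.to_vcf(out / "replication.vcf"))
    panel.to_csv(out / "reference_panel.tsv", sep="\t", index=False)
    paths["reference_panel"] = out / "reference_panel.tsv"
    paths["constraint"] = Path(write_constraint_table(constraint, out / "constraint.tsv"))
    discovery.ground_truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    logger.info("simulate: %d variants, %d cases", len(discovery.cohort.variants),
                discovery.cohort.n_samples)

    # Classification audit table
    rows = []
    for v in discovery.cohort.variants:
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "gene": v.gene,
            "class": classify.classify_consequence(v.consequence_term).value,
            "damaging": classify.is_damaging(v.cadd_phred),
            "rare": classify.is_rare(v, ["REF"], config.rare_maf),
        })
    pd.DataFrame(rows).to_csv(out / "classified.tsv", sep="\t", index=False)
    paths["classified"] = out / "classified.tsv"
    logger.info("classify: %d variants, %d rare", len(rows),
                sum(r["rare"] for r in rows))

    gba_kwargs = dict(constraint=constraint, alpha=config.alpha,
                      rare_threshold=config.rare_maf, counting=config.counting)
    disc_res = burden.run_gba(discovery.cohort, **gba_kwargs)
    sev_res = burden.run_gba(discovery.severe_view(), **gba_kwargs)
    repl_res = burden.run_gba(replication.cohort, **gba_kwargs)
    replicated = burden.replicate(disc_res, repl_res)
    for name, df in (("burden_discovery", disc_res), ("burden_severe", sev_res),
                     ("burden_replication", repl_res), ("replicated_genes", replicated)):
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        paths[name] = out / f"{name}.tsv"
    logger.info("burden-snv: %d discovery rows, %d replicated genes",
                len(disc_res), len(replicated))

    callset = simulate.generate_sv_callset(sim)
    paths["sv_calls"] = Path(write_sv_calls(callset.svs, out / "sv_calls.tsv"))
    paths["blacklist"] = Path(write_regions_bed(callset.blacklist, out / "blacklist.bed"))
    paths["constrained_bed"] = Path(
        write_regions_bed(callset.constrained_regions, out / "constrained.bed"))
    sv_table, tallies = sv.run_sv_pipeline(
        callset.svs, callset.blacklist, callset.known_svs, constraint,
        callset.gene_intervals,
        min_bp=config.sv_min_bp, max_bp=config.sv_max_bp,
        blacklist_threshold=config.blacklist_threshold,
        known_threshold=config.known_sv_threshold,
        max_ref_freq=config.ultra_rare_freq, alpha=config.alpha)
    sv_table.to_csv(out / "sv_burden.tsv", sep="\t", index=False)
    paths["sv_burden"] = out / "sv_burden.tsv"
    logger.info("burden-sv: tallies %s", tallies)

    records = simulate.generate_clinical_table(sim)
    paths["clinical_csv"] = Path(write_clinical(records, out / "clinical.csv"))
    severe = clinical.select_severe(records, config.thi_severe)
    rest = [r for r in records if r.thi < config.thi_severe]
    comp_rows = []
    for feature in ("hyperacusis", "hearing_loss", "headache", "anxiety", "depression"):
        cmp_ = clinical.compare_categorical(feature, severe, rest)
        comp_rows.append({
            "feature": feature,
            "severe": f"{cmp_.count_a} ({cmp_.percent_a}%)",
            "other": f"{cmp_.count_b} ({cmp_.percent_b}%)",
            "test": cmp_.test, "p": cmp_.p_value,
        })
    pd.DataFrame(comp_rows).to_csv(out / "clinical_comparisons.tsv", sep="\t", index=False)
    paths["clinical_comparisons"] = out / "clinical_comparisons.tsv"
    logger.info("clinical: %d severe of %d", len(severe), len(records))

    manifest = {"tool": "tinvar", "version": __version__, "seed": config.seed,
                "config_sha256": config.digest(),
                "stage_tallies_sv": tallies,
                "outputs": {k: str(v) for k, v in sorted(paths.items())}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = out / "manifest.json"
    return paths
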