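"""Synthetic cohorts with known ground truth.

Everything downstream of variant calling is testable without any download:
this module emulates a discovery cohort (default 97 whole genomes, with a
severe subset of 34 selected on THI score), a replication cohort (147), a
1000-sample population reference panel, an SV call set with a planted
recurrent deletion, region sets (blacklist, constrained regions), a gene
constraint table, and a clinical table whose comorbidity rates follow the
severe/non-severe split observed in Swedish tinnitus cohorts.

Genetic model
-------------
Each variant has a latent population allele frequency drawn from a Beta
law (default Beta(0.2, 50): heavily rare-skewed; >80% of draws below 1%).
The reference panel reports a Binomial(2*n_reference, f) draw of each
latent frequency. Case genotypes are sampled per allele under
Hardy-Weinberg independence from the *latent* frequency, so that under the
null the case-vs-panel comparison is an honest two-sample problem and the
burden test stays calibrated.

Enrichment is planted per gene through the odds-ratio identity on the
collapsed rare-variant frequency F of the targeted class:

    F_case = OR * F / (1 - F + OR * F)

and the implied scaling is distributed uniformly over that gene's variants
of the class, which makes the configured OR the estimand of the downstream
collapsing test. The severe subset is a random subsample of cases: same
genetic model, different clinical model.

Identical config + seed => byte-identical outputs.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (AnnotatedVariant, ClinicalRecord, GeneConstraint, RegionSet,
                 StructuralVariantCall, VcfCohort, write_vcf)

CHROM = "sim1"
GENE_SPAN = 100_000       # bp reserved per gene on the pseudo-chromosome
GENE_LENGTH = 50_000      # bp of each gene body
VARIANT_STEP = 100        # bp between successive sites within a gene

_LOF_TERMS = ("stop_gained", "stop_lost", "start_lost", "frameshift_variant",
              "splice_donor_variant", "splice_acceptor_variant")

# Comorbidity probabilities conditional on severe status, (non-severe, severe).
# Severe values follow the SEVTIN column of the clinical table this emulates
# (e.g. hyperacusis 32/34); non-severe values are the complement counts.
DEFAULT_CLINICAL_PROBS: dict[str, tuple[float, float]] = {
    "hyperacusis": (35 / 63, 32 / 34),
    "hearing_loss": (35 / 63, 27 / 34),
    "headache": (24 / 63, 11 / 34),
    "anxiety": (29 / 63, 25 / 34),
    "depression": (17 / 63, 13 / 34),
}

_DURATION_PROBS = {
    # ("6m-3y", "3-10y", "10-20y", ">20y", "missing")
    False: np.array([8, 16, 20, 12, 7]) / 63,
    True: np.array([8, 5, 13, 5, 3]) / 34,
}


@dataclass(frozen=True)
class EnrichedGene:
    gene: str
    odds_ratio: float
    variant_class: str  # "LOF" | "MISSENSE"

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ConfigError(f"target odds ratio must be > 0, got {self.odds_ratio}")
        if self.variant_class not in ("LOF", "MISSENSE"):
            raise ConfigError(f"enrichment class must be LOF or MISSENSE, got {self.variant_class}")


@dataclass(frozen=True)
class SvSpec:
    """Shape of the simulated SV call set.

    The recurrent-deletion carrier frequencies default to the effect size
    of the strongest reported constrained-region deletion (0.216 in cases,
    0.235 in the severe subset, 0.017 in the reference panel).
    """

    n_del: int = 40
    n_dup: int = 20
    min_length: int = 1_000
    max_length: int = 1_000_000
    recurrent_case_freq: float = 0.216
    recurrent_severe_freq: float = 0.235
    recurrent_ref_freq: float = 0.017
    constrained_fraction: float = 0.3   # fraction of background SVs placed in constrained genes
    blacklist_fraction: float = 0.1     # fraction of artifact calls planted inside the blacklist
    novel_fraction: float = 0.1         # fraction absent from the known-SV database

    def __post_init__(self):
        if self.min_length >= self.max_length:
            raise ConfigError(
                f"SV length range inverted: [{self.min_length}, {self.max_length}]"
            )
        for name in ("recurrent_case_freq", "recurrent_severe_freq", "recurrent_ref_freq",
                     "constrained_fraction", "blacklist_fraction", "novel_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 97
    n_severe: int = 34
    n_replication: int = 147
    n_reference: int = 1000
    n_genes: int = 200
    variants_per_gene: int = 30
    maf_distribution: tuple[float, float] = (0.2, 50.0)
    enriched_genes: tuple[EnrichedGene, ...] = (
        EnrichedGene("GENE0001", 4.0, "MISSENSE"),
        EnrichedGene("GENE0002", 3.4, "MISSENSE"),
        EnrichedGene("GENE0003", 2.9, "LOF"),
    )
    constrained_fraction: float = 0.2
    sv_spec: SvSpec = field(default_factory=SvSpec)
    clinical_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_PROBS))
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_severe", "n_replication", "n_reference",
                     "n_genes", "variants_per_gene"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_severe > self.n_cases:
            raise ConfigError(
                f"n_severe ({self.n_severe}) must not exceed n_cases ({self.n_cases})"
            )
        a, b = self.maf_distribution
        if a <= 0 or b <= 0:
            raise ConfigError(f"Beta shape parameters must be > 0, got ({a}, {b})")
        if not (0 <= self.constrained_fraction <= 1):
            raise ConfigError(f"constrained_fraction must be in [0,1]")
        for feat, (p0, p1) in self.clinical_probs.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ConfigError(f"clinical probabilities for {feat} must be in [0,1]")
        genes = [e.gene for e in self.enriched_genes]
        if len(genes) != len(set(genes)):
            raise ConfigError("duplicate gene in enriched_genes")

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    def gene_interval(self, gene_index: int) -> tuple[str, int, int]:
        start = gene_index * GENE_SPAN
        return (CHROM, start, start + GENE_LENGTH)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, named, reproducible stream per artifact."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode()) % 2**31])


@dataclass
class GroundTruth:
    """True per-gene enrichment and per-SV status; one row per simulated unit."""

    genes: pd.DataFrame   # gene, enriched, target_or, variant_class, constrained
    svs: pd.DataFrame     # ident, planted_recurrent, constrained, in_blacklist, known

    def write(self, genes_path, svs_path):
        self.genes.to_csv(genes_path, sep="\t", index=False)
        self.svs.to_csv(svs_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sites and reference panel
# ---------------------------------------------------------------------------

_REF_ALT = (("A", "T"), ("C", "G"), ("G", "A"), ("T", "C"))


def simulate_sites(config: SimulationConfig) -> pd.DataFrame:
    """The shared variant-site table: positions, consequences, CADD, latent truth."""
    rng = _rng(config, "sites")
    a, b = config.maf_distribution
    genes = config.gene_names()
    n = config.n_genes * config.variants_per_gene

    gene_idx = np.repeat(np.arange(config.n_genes), config.variants_per_gene)
    within = np.tile(np.arange(config.variants_per_gene), config.n_genes)
    pos = gene_idx * GENE_SPAN + within * VARIANT_STEP + 1  # 1-based

    csq_class = rng.choice(["LOF", "MISSENSE", "SYNONYMOUS", "OTHER"], size=n,
                           p=[0.2, 0.5, 0.2, 0.1])
    lof_cycle = np.array(_LOF_TERMS)[np.arange(n) % len(_LOF_TERMS)]
    csq = np.where(csq_class == "LOF", lof_cycle,
                   np.where(csq_class == "MISSENSE", "missense_variant",
                            np.where(csq_class == "SYNONYMOUS", "synonymous_variant",
                                     "intron_variant")))
    cadd = np.round(rng.uniform(0, 40, size=n), 2)
    cadd_missing = rng.random(n) < 0.1
    true_freq = rng.beta(a, b, size=n)

    ra = np.array(_REF_ALT)[np.arange(n) % len(_REF_ALT)]
    return pd.DataFrame({
        "chrom": CHROM, "pos": pos, "ref": ra[:, 0], "alt": ra[:, 1],
        "gene": np.array(genes)[gene_idx], "consequence": csq,
        "cadd": np.where(cadd_missing, np.nan, cadd),
        "true_freq": true_freq,
    })


def generate_reference_panel(config: SimulationConfig, name: str = "REF",
                             sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per simulated variant with panel allele count/number/frequency.

    Counts are Binomial(2*n_reference, latent frequency) draws; under the
    default Beta(0.2, 50) law the large majority of rows are rare (<1%).
    """
    if sites is None:
        sites = simulate_sites(config)
    rng = _rng(config, f"panel:{name}")
    an = 2 * config.n_reference
    ac = rng.binomial(an, sites["true_freq"].to_numpy())
    panel = sites.copy()
    panel["allele_count"] = ac
    panel["allele_number"] = an
    panel["frequency"] = ac / an
    panel["panel"] = name
    return panel


# ---------------------------------------------------------------------------
# Case cohorts
# ---------------------------------------------------------------------------

def _case_sampling_freqs(config: SimulationConfig, sites: pd.DataFrame,
                         rare_threshold: float = 0.01) -> np.ndarray:
    """Per-variant case allele frequencies with planted per-gene enrichment.

    For an enriched gene, the collapsed latent frequency F of its rare
    variants of the targeted class is mapped through the odds-ratio
    identity and the resulting scale factor applied uniformly to that
    class's variants.
    """
    freqs = sites["true_freq"].to_numpy().copy()
    lof = sites["consequence"].isin(_LOF_TERMS).to_numpy()
    missense = (sites["consequence"] == "missense_variant").to_numpy()
    for spec in config.enriched_genes:
        in_gene = (sites["gene"] == spec.gene).to_numpy()
        cls_mask = in_gene & (lof if spec.variant_class == "LOF" else missense)
        rare_mask = cls_mask & (sites["true_freq"].to_numpy() < rare_threshold)
        basis = rare_mask if rare_mask.any() else cls_mask
        if not basis.any():
            raise ConfigError(
                f"enriched gene {spec.gene} has no {spec.variant_class} variants to scale"
            )
        F = float(sites.loc[basis, "true_freq"].sum())
        if F >= 1:
            raise ConfigError(f"collapsed frequency {F:.3f} for {spec.gene} is not rare")
        f_case = spec.odds_ratio * F / (1 - F + spec.odds_ratio * F)
        scale = f_case / F
        scaled = freqs[cls_mask] * scale
        if np.any(scaled > 1):
            raise ConfigError(
                f"target OR {spec.odds_ratio} for {spec.gene} implies a case "
                f"frequency above 1"
            )
        freqs[cls_mask] = scaled
    return freqs


def severe_subset(config: SimulationConfig) -> np.ndarray:
    """Indices (into the discovery cohort) of the severe subsample."""
    rng = _rng(config, "severe")
    return np.sort(rng.choice(config.n_cases, size=config.n_severe, replace=False))


@dataclass
class SimulatedCohort:
    """A simulated case cohort: split variants, genotypes, severe labels, truth."""

    cohort: VcfCohort
    severe_indices: np.ndarray | None
    ground_truth: GroundTruth

    def to_vcf(self, path):
        return write_vcf(self.cohort.variants, path,
                         samples=self.cohort.samples, genotypes=self.cohort.genotypes)

    def severe_view(self) -> VcfCohort:
        """The severe subsample as its own cohort (recomputed allele counts)."""
        idx = self.severe_indices
        gt = self.cohort.genotypes[:, idx]
        variants = []
        for i, v in enumerate(self.cohort.variants):
            row = gt[i]
            variants.append(replace(
                v,
                case_allele_count=int(row[row > 0].sum()),
                case_allele_number=2 * int((row >= 0).sum()),
            ))
        return VcfCohort(variants=variants,
                         samples=[self.cohort.samples[i] for i in idx],
                         genotypes=gt)


def _gene_truth(config: SimulationConfig, constrained_genes: frozenset[str]) -> pd.DataFrame:
    spec_by_gene = {e.gene: e for e in config.enriched_genes}
    rows = []
    for g in config.gene_names():
        e = spec_by_gene.get(g)
        rows.append({
            "gene": g, "enriched": e is not None,
            "target_or": e.odds_ratio if e else 1.0,
            "variant_class": e.variant_class if e else "",
            "constrained": g in constrained_genes,
        })
    return pd.DataFrame(rows)


def generate_case_cohort(config: SimulationConfig,
                         panels: pd.DataFrame | Sequence[pd.DataFrame],
                         cohort: str = "discovery",
                         sites: pd.DataFrame | None = None) -> SimulatedCohort:
    """Simulate per-sample diploid genotypes for the discovery or replication cohort.

    ``panels`` (one table or a list of tables from
    :func:`generate_reference_panel`) supply the annotation frequencies
    attached to each variant. Non-enriched genes have case frequency equal
    to the latent panel frequency in expectation; enriched genes follow
    their configured collapsed odds ratio in expectation.
    """
    if cohort not in ("discovery", "replication"):
        raise ConfigError(f"cohort must be 'discovery' or 'replication', got {cohort!r}")
    if sites is None:
        sites = simulate_sites(config)
    if isinstance(panels, pd.DataFrame):
        panels = [panels]

    n = config.n_cases if cohort == "discovery" else config.n_replication
    prefix = "TIG" if cohort == "discovery" else "REP"
    rng = _rng(config, f"cohort:{cohort}")
    freqs = np.clip(_case_sampling_freqs(config, sites), 0.0, 1.0)
    genotypes = rng.binomial(2, freqs[:, None], size=(len(sites), n)).astype(np.int8)
    allele_counts = genotypes.sum(axis=1)

    panel_cols = [
        (p["panel"].iloc[0], p["allele_count"].to_numpy(), int(p["allele_number"].iloc[0]))
        for p in panels
    ]
    variants = []
    for i, row in enumerate(sites.itertuples(index=False)):
        variants.append(AnnotatedVariant(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene=row.gene, consequence_term=row.consequence,
            cadd_phred=None if np.isnan(row.cadd) else float(row.cadd),
            case_allele_count=int(allele_counts[i]), case_allele_number=2 * n,
            panel_freqs={name: (int(ac[i]), an) for name, ac, an in panel_cols},
        ))
    samples = [f"{prefix}{i + 1:04d}" for i in range(n)]
    constrained = frozenset(constrained_gene_names(config))
    truth = GroundTruth(genes=_gene_truth(config, constrained), svs=pd.DataFrame())
    severe = severe_subset(config) if cohort == "discovery" else None
    return SimulatedCohort(
        cohort=VcfCohort(variants=variants, samples=samples, genotypes=genotypes),
        severe_indices=severe, ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Constraint table
# ---------------------------------------------------------------------------

def constrained_gene_names(config: SimulationConfig) -> list[str]:
    """Deterministic choice of high-constraint genes; enriched genes included."""
    rng = _rng(config, "constraint")
    genes = config.gene_names()
    n_constrained = max(int(round(config.constrained_fraction * config.n_genes)),
                        len(config.enriched_genes))
    forced = [e.gene for e in config.enriched_genes]
    others = [g for g in genes if g not in forced]
    extra = rng.choice(len(others), size=max(n_constrained - len(forced), 0), replace=False)
    chosen = set(forced) | {others[i] for i in extra}
    return [g for g in genes if g in chosen]


def generate_constraint_table(config: SimulationConfig) -> dict[str, GeneConstraint]:
    rng = _rng(config, "constraint-scores")
    constrained = set(constrained_gene_names(config))
    out = {}
    for g in config.gene_names():
        if g in constrained:
            out[g] = GeneConstraint(
                gene=g, pli=float(rng.uniform(0.905, 1.0)),
                loeuf=float(rng.uniform(0.05, 0.49)), loeuf_bin=int(rng.integers(0, 2)),
            )
        else:
            out[g] = GeneConstraint(
                gene=g, pli=float(rng.uniform(0.0, 0.89)),
                loeuf=float(rng.uniform(0.5, 1.9)), loeuf_bin=int(rng.integers(2, 10)),
            )
    return out


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSvCallset:
    svs: list[StructuralVariantCall]
    known_svs: list[StructuralVariantCall]
    blacklist: RegionSet
    constrained_regions: RegionSet
    gene_intervals: dict[str, tuple[str, int, int]]
    ground_truth: GroundTruth


def generate_sv_callset(config: SimulationConfig) -> SimulatedSvCallset:
    """Simulate DEL/DUP calls with a planted recurrent deletion in a constrained gene.

    Also emits the region sets the SV stage consumes: a blacklist (gaps /
    segmental-duplication stand-ins) beyond the gene-bearing stretch of the
    pseudo-chromosome, and the constrained-region BED derived from the
    high-constraint genes.
    """
    spec = config.sv_spec
    rng = _rng(config, "sv")
    genes = config.gene_names()
    constrained = constrained_gene_names(config)
    gene_intervals = {g: config.gene_interval(i) for i, g in enumerate(genes)}
    constrained_regions = RegionSet(
        "constrained", [gene_intervals[g] for g in constrained])

    genome_end = config.n_genes * GENE_SPAN
    blacklist = RegionSet("blacklist", [
        (CHROM, genome_end + 100_000, genome_end + 600_000),
        (CHROM, genome_end + 1_000_000, genome_end + 1_500_000),
    ])

    sizes = {"cases": config.n_cases, "severe": config.n_severe,
             "reference": config.n_reference}

    # Placement is slot-confined so that ground-truth constraint status is
    # exact: a background SV overlaps a constrained gene iff it was targeted
    # at one. Non-targeted SVs stay inside the slot (gene body + downstream
    # gap) of a non-constrained gene, or a spare slot past the genes.
    constrained_set = set(constrained)
    unconstrained_slots = [
        (i * GENE_SPAN, (i + 1) * GENE_SPAN)
        for i, g in enumerate(genes) if g not in constrained_set
    ] or [(genome_end, genome_end + GENE_SPAN)]

    def draw_interval(in_constrained: bool, in_blacklist: bool) -> tuple[int, int]:
        length = int(np.exp(rng.uniform(np.log(spec.min_length), np.log(spec.max_length))))
        if in_blacklist:
            start = int(rng.integers(genome_end + 100_000, genome_end + 600_000 - 1))
            return start, start + length
        if in_constrained and constrained:
            g = constrained[int(rng.integers(len(constrained)))]
            _, gs, _ = gene_intervals[g]
            start = int(rng.integers(gs, gs + GENE_LENGTH // 2))
            return start, start + length
        slot_start, slot_end = unconstrained_slots[int(rng.integers(len(unconstrained_slots)))]
        start = int(rng.integers(slot_start, slot_end - spec.min_length))
        end = min(start + length, slot_end)
        return start, max(end, start + spec.min_length)

    svs, truth_rows = [], []
    n_bg = spec.n_del + spec.n_dup
    for i in range(n_bg):
        sv_type = "DEL" if i < spec.n_del else "DUP"
        in_blacklist = rng.random() < spec.blacklist_fraction
        in_constrained = (not in_blacklist) and rng.random() < spec.constrained_fraction
        start, end = draw_interval(in_constrained, in_blacklist)
        ref_freq = float(rng.beta(0.5, 60))
        carriers = {
            "cases": int(rng.binomial(sizes["cases"], ref_freq)),
            "reference": int(rng.binomial(sizes["reference"], ref_freq)),
        }
        carriers["severe"] = int(rng.binomial(sizes["severe"],
                                              carriers["cases"] / sizes["cases"]))
        evidence = {}
        if in_constrained:
            evidence["constrained_gene_overlap"] = True
        if rng.random() < 0.15:
            evidence["benign_region_overlap"] = True
        known = rng.random() >= spec.novel_fraction
        sv = StructuralVariantCall(chrom=CHROM, start=start, end=end, sv_type=sv_type,
                                   carriers=carriers, cohort_sizes=dict(sizes),
                                   evidence=evidence)
        svs.append(sv)
        truth_rows.append({"ident": sv.ident, "planted_recurrent": False,
                           "constrained": in_constrained, "in_blacklist": in_blacklist,
                           "known": known})

    # Planted recurrent deletion at the configured carrier frequencies per
    # cohort; it targets a constrained gene unless the configuration rules
    # constrained placement out entirely.
    planted_constrained = spec.constrained_fraction > 0 and bool(constrained)
    if planted_constrained:
        _, gs, ge = gene_intervals[constrained[0]]
    else:
        gs, ge = unconstrained_slots[0]
    start = gs + 1_000
    end = min(start + 3_000, ge)
    planted = StructuralVariantCall(
        chrom=CHROM, start=start, end=end, sv_type="DEL",
        carriers={
            "cases": int(rng.binomial(sizes["cases"], spec.recurrent_case_freq)),
            "severe": int(rng.binomial(sizes["severe"], spec.recurrent_severe_freq)),
            "reference": int(rng.binomial(sizes["reference"], spec.recurrent_ref_freq)),
        },
        cohort_sizes=dict(sizes),
        evidence={"constrained_gene_overlap": True} if planted_constrained else {},
    )
    svs.append(planted)
    truth_rows.append({"ident": planted.ident, "planted_recurrent": True,
                       "constrained": planted_constrained, "in_blacklist": False,
                       "known": True})

    known_svs = [
        StructuralVariantCall(chrom=sv.chrom, start=sv.start, end=sv.end,
                              sv_type=sv.sv_type)
        for sv, row in zip(svs, truth_rows) if row["known"]
    ]
    truth = GroundTruth(genes=pd.DataFrame(), svs=pd.DataFrame(truth_rows))
    return SimulatedSvCallset(svs=svs, known_svs=known_svs, blacklist=blacklist,
                              constrained_regions=constrained_regions,
                              gene_intervals=gene_intervals, ground_truth=truth)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def generate_clinical_table(config: SimulationConfig) -> list[ClinicalRecord]:
    """One record per discovery-cohort case.

    Severe subjects (the same subsample as the genetic severe subset) draw
    THI uniformly in [58, 100], the rest in [0, 57]; every subject meets
    the chronic inclusion criterion TFI >= 48. Comorbidity flags are
    Bernoulli with severity-conditional probabilities.
    """
    rng = _rng(config, "clinical")
    severe = set(severe_subset(config).tolist())
    duration_cats = ("6m-3y", "3-10y", "10-20y", ">20y", "missing")
    records = []
    for i in range(config.n_cases):
        is_severe = i in severe
        thi = float(rng.integers(58, 101)) if is_severe else float(rng.integers(0, 58))
        tfi = float(rng.integers(48, 101))
        age = float(np.clip(rng.normal(48.8 if is_severe else 44.5, 13.0), 18, 90))
        sex = "F" if rng.random() < (0.47 if is_severe else 0.60) else "M"
        flags = {feat: bool(rng.random() < (p1 if is_severe else p0))
                 for feat, (p0, p1) in config.clinical_probs.items()}
        duration = str(rng.choice(duration_cats, p=_DURATION_PROBS[is_severe]))
        records.append(ClinicalRecord(
            subject=f"TIG{i + 1:04d}", age=round(age, 1), sex=sex, thi=thi, tfi=tfi,
            hearing_loss=flags.get("hearing_loss", False),
            hyperacusis=flags.get("hyperacusis", False),
            headache=flags.get("headache", False),
            anxiety=flags.get("anxiety", False),
            depression=flags.get("depression", False),
            duration_category=duration,
        ))
    return records
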