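"""Structural-variant prioritization and constrained-region burden.

Stage order (each stage is a pure predicate, so the documented order and
joint application agree):

1. size window: keep calls with length in [1 kb, 1 Mb]; oversized calls
   survive only by matching a known SV at >= 99% reciprocal overlap
2. artifact removal: drop calls covered > 66% (strict) by the blacklist
   union (genome gaps, segmental duplications, V(D)J regions)
3. known-SV concordance: keep calls matching a same-type database SV at
   >= 99% reciprocal overlap (novel calls are treated as likely false
   positives)
4. ACMG-style class from a declarative rubric; classes 3-5 retained
5. constrained-region overlap (gene pLI > 0.9 and LOEUF bin < 2) and
   ultra-rare flag (reference carrier frequency <= 0.001, the resolution
   of a 1000-sample panel)
6. carrier-frequency burden: per SV, a 2x2 carrier table (cases vs
   reference) tested with the Pearson chi-squared of
   :func:`tinvar.burden.burden_test` in carrier mode

Overlap conventions: the 66% artifact rule measures one-sided coverage of
the SV by the region union (no double counting); the 99% concordance rule
is reciprocal, |intersection| / max(|sv|, |known|).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .burden import CollapsedGeneCount, burden_test
from .classify import VariantClass
from .errors import ConfigError, ValidationError
from .io import GeneConstraint, RegionSet, StructuralVariantCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapReport:
    ident: str
    region_set: str
    covered_fraction: float
    best_reciprocal: float = 0.0

    def __post_init__(self):
        for name in ("covered_fraction", "best_reciprocal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValidationError(f"{name} must be in [0,1], got {v}")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def covered_fraction(sv: StructuralVariantCall, regions: RegionSet) -> float:
    """Fraction of the SV covered by the union of the region set.

    Computed on merged intersections, so fragmenting a region into
    adjacent pieces leaves the value unchanged.
    """
    pieces = regions.overlapping(sv.chrom, sv.start, sv.end)
    if not pieces:
        return 0.0
    covered = 0
    cur_start, cur_end = pieces[0]
    for s, e in pieces[1:]:
        if s > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start
    return covered / sv.length


def reciprocal_overlap(a: StructuralVariantCall, b: StructuralVariantCall) -> float:
    """|intersection| / max(|a|, |b|); 0 for different chromosomes. Symmetric."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / max(a.length, b.length)


def best_reciprocal_overlap(sv: StructuralVariantCall,
                            known: Sequence[StructuralVariantCall]) -> float:
    """Maximum reciprocal overlap against any same-type known SV."""
    best = 0.0
    for k in known:
        if k.sv_type != sv.sv_type:
            continue
        best = max(best, reciprocal_overlap(sv, k))
    return best


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_by_size(svs: Iterable[StructuralVariantCall], min_bp: int = 1_000,
                   max_bp: int = 1_000_000
                   ) -> tuple[list[StructuralVariantCall], list[StructuralVariantCall]]:
    """Split calls into the in-window set and the oversized set (stricter path).

    Both window ends are inclusive; undersized calls are dropped outright.
    """
    if min_bp >= max_bp:
        raise ConfigError(f"size window inverted: [{min_bp}, {max_bp}]")
    kept, oversized = [], []
    for sv in svs:
        if min_bp <= sv.length <= max_bp:
            kept.append(sv)
        elif sv.length > max_bp:
            oversized.append(sv)
    return kept, oversized


def filter_artifacts(svs: Iterable[StructuralVariantCall], blacklist: RegionSet,
                     threshold: float = 0.66) -> list[StructuralVariantCall]:
    """Drop calls covered strictly more than ``threshold`` by the blacklist."""
    return [sv for sv in svs if covered_fraction(sv, blacklist) <= threshold]


def filter_known(svs: Iterable[StructuralVariantCall],
                 known: Sequence[StructuralVariantCall],
                 threshold: float = 0.99) -> list[StructuralVariantCall]:
    """Keep calls with a same-type known SV at reciprocal overlap >= threshold."""
    return [sv for sv in svs if best_reciprocal_overlap(sv, known) >= threshold]


# ---------------------------------------------------------------------------
# ACMG-style classification
# ---------------------------------------------------------------------------

def load_acmg_rules(path=None) -> dict:
    """Load a declarative rubric: ordered evidence-pattern -> class rules."""
    if path is None:
        text = resources.files("tinvar").joinpath("data/acmg_rules.yaml").read_text()
    else:
        text = open(path, encoding="utf-8").read()
    rules = yaml.safe_load(text)
    for key in ("flags", "rules", "default_class"):
        if key not in rules:
            raise ConfigError(f"ACMG rules file missing key {key!r}")
    for rule in rules["rules"]:
        for flag in rule["when"]:
            if flag not in rules["flags"]:
                raise ConfigError(f"rule references undeclared evidence flag {flag!r}")
        if rule["class"] not in range(1, 6):
            raise ConfigError(f"ACMG class must be 1-5, got {rule['class']}")
    return rules


def classify_acmg(sv: StructuralVariantCall, rules: Mapping | None = None,
                  evidence: Mapping[str, bool] | None = None) -> int:
    """Deterministic class 1-5 from the first matching rule.

    Evidence keys not declared in the rules file are a configuration
    error: a silent typo in an evidence flag must not downgrade a call.
    """
    if rules is None:
        rules = load_acmg_rules()
    ev = dict(sv.evidence)
    if evidence:
        ev.update(evidence)
    declared = set(rules["flags"])
    for key in ev:
        if key not in declared:
            raise ConfigError(f"evidence key {key!r} not declared in ACMG rules")
    for rule in rules["rules"]:
        if all(ev.get(flag, False) == wanted for flag, wanted in rule["when"].items()):
            return int(rule["class"])
    return int(rules["default_class"])


def retain_reportable(svs: Iterable[StructuralVariantCall],
                      rules: Mapping | None = None) -> list[StructuralVariantCall]:
    """Classify and keep classes 3-5 (VUS, likely pathogenic, pathogenic)."""
    if rules is None:
        rules = load_acmg_rules()
    kept = []
    for sv in svs:
        sv.acmg_class = classify_acmg(sv, rules)
        if sv.acmg_class >= 3:
            kept.append(sv)
    return kept


# ---------------------------------------------------------------------------
# Constraint and rarity flags
# ---------------------------------------------------------------------------

def constrained_overlap(sv: StructuralVariantCall,
                        constraint: Mapping[str, GeneConstraint],
                        gene_intervals: Mapping[str, tuple[str, int, int]]
                        ) -> tuple[bool, list[str]]:
    """Does the SV intersect a high-constraint gene (pLI > 0.9, LOEUF bin < 2)?

    Returns the flag and the overlapped constrained gene symbols.
    """
    hits = []
    for gene, (chrom, start, end) in gene_intervals.items():
        if chrom != sv.chrom or end <= sv.start or start >= sv.end:
            continue
        c = constraint.get(gene)
        if c is None or c.loeuf_bin is None:
            continue
        if c.pli > 0.9 and c.loeuf_bin < 2:
            hits.append(gene)
    return (bool(hits), sorted(hits))


def flag_ultra_rare(sv: StructuralVariantCall, reference: str = "reference",
                    max_ref_freq: float = 0.001) -> bool:
    """True iff the reference carrier frequency is <= max_ref_freq (inclusive).

    An SV absent from the reference panel counts as frequency 0.
    """
    size = sv.cohort_sizes.get(reference)
    if size is None:
        return True
    return sv.carriers.get(reference, 0) / size <= max_ref_freq


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

SV_BURDEN_COLUMNS = ["ident", "sv_type", "genes", "carriers_case", "freq_case",
                     "carriers_severe", "freq_severe", "carriers_ref", "freq_ref",
                     "chi2", "p", "OR", "ci_low", "ci_high",
                     "ultra_rare", "constrained", "acmg_class"]


def sv_burden(svs: Sequence[StructuralVariantCall], case_cohort: str = "cases",
              reference: str = "reference", severe_cohort: str = "severe",
              constraint: Mapping[str, GeneConstraint] | None = None,
              gene_intervals: Mapping[str, tuple[str, int, int]] | None = None,
              alpha: float = 0.05, max_ref_freq: float = 0.001) -> pd.DataFrame:
    """Per-SV carrier-frequency burden of the case cohort against the reference.

    Carrier frequencies are reported to 3 decimals; an all-zero carrier
    table returns p = 1 with the OR reported missing. Sorted by p
    ascending, then OR descending, then identity.
    """
    rows = []
    for sv in svs:
        for cohort in (case_cohort, reference):
            if cohort not in sv.cohort_sizes:
                raise ValidationError(f"missing cohort size for {cohort!r} at {sv.ident}")
        counts = CollapsedGeneCount(
            gene=sv.ident, variant_class=VariantClass.OTHER,
            case_alleles=sv.carriers.get(case_cohort, 0),
            case_allele_number=sv.cohort_sizes[case_cohort],
            panel_alleles=sv.carriers.get(reference, 0),
            panel_allele_number=sv.cohort_sizes[reference],
            n_variants=1,
        )
        res = burden_test(counts, panel=reference, alpha=alpha)
        degenerate = (res.a == 0 and res.c == 0)
        constrained, genes = (False, [])
        if constraint is not None and gene_intervals is not None:
            constrained, genes = constrained_overlap(sv, constraint, gene_intervals)
        row = {
            "ident": sv.ident, "sv_type": sv.sv_type, "genes": ",".join(genes),
            "carriers_case": res.a,
            "freq_case": round(res.a / sv.cohort_sizes[case_cohort], 3),
            "carriers_ref": res.c,
            "freq_ref": round(res.c / sv.cohort_sizes[reference], 3),
            "chi2": res.chi2, "p": res.p_value,
            "OR": float("nan") if degenerate else res.odds_ratio,
            "ci_low": float("nan") if degenerate else res.ci_low,
            "ci_high": float("nan") if degenerate else res.ci_high,
            "ultra_rare": flag_ultra_rare(sv, reference, max_ref_freq),
            "constrained": constrained,
            "acmg_class": sv.acmg_class,
        }
        if severe_cohort in sv.cohort_sizes:
            row["carriers_severe"] = sv.carriers.get(severe_cohort, 0)
            row["freq_severe"] = round(
                sv.carriers.get(severe_cohort, 0) / sv.cohort_sizes[severe_cohort], 3)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=SV_BURDEN_COLUMNS)
    return df.sort_values(["p", "OR", "ident"], ascending=[True, False, True],
                          kind="mergesort").reset_index(drop=True)


def sv_burden_grouped(svs: Sequence[StructuralVariantCall], case_cohort: str = "cases",
                      reference: str = "reference",
                      constraint: Mapping[str, GeneConstraint] | None = None,
                      gene_intervals: Mapping[str, tuple[str, int, int]] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Burden clustered by SV type x constrained status (pooled carrier counts)."""
    groups: dict[tuple[str, bool], dict] = {}
    for sv in svs:
        constrained = False
        if constraint is not None and gene_intervals is not None:
            constrained, _ = constrained_overlap(sv, constraint, gene_intervals)
        key = (sv.sv_type, constrained)
        acc = groups.setdefault(key, {"case": 0, "ref": 0, "n": 0,
                                      "case_size": sv.cohort_sizes[case_cohort],
                                      "ref_size": sv.cohort_sizes[reference]})
        acc["case"] += sv.carriers.get(case_cohort, 0)
        acc["ref"] += sv.carriers.get(reference, 0)
        acc["n"] += 1
    rows = []
    for (sv_type, constrained), acc in sorted(groups.items()):
        # Pooled carrier events against pooled opportunity (size x SV count).
        counts = CollapsedGeneCount(
            gene=f"{sv_type}:{'constrained' if constrained else 'unconstrained'}",
            variant_class=VariantClass.OTHER,
            case_alleles=acc["case"], case_allele_number=acc["case_size"] * acc["n"],
            panel_alleles=acc["ref"], panel_allele_number=acc["ref_size"] * acc["n"],
            n_variants=acc["n"],
        )
        res = burden_test(counts, panel=reference, alpha=alpha)
        rows.append({
            "group": counts.gene, "sv_type": sv_type, "constrained": constrained,
            "n_svs": acc["n"], "carriers_case": res.a, "carriers_ref": res.c,
            "chi2": res.chi2, "p": res.p_value, "OR": res.odds_ratio,
            "enriched": res.enriched,
        })
    return pd.DataFrame(rows)


def run_sv_pipeline(svs: Sequence[StructuralVariantCall],
                    blacklist: RegionSet,
                    known: Sequence[StructuralVariantCall],
                    constraint: Mapping[str, GeneConstraint],
                    gene_intervals: Mapping[str, tuple[str, int, int]],
                    rules: Mapping | None = None,
                    min_bp: int = 1_000, max_bp: int = 1_000_000,
                    blacklist_threshold: float = 0.66,
                    known_threshold: float = 0.99,
                    max_ref_freq: float = 0.001,
                    alpha: float = 0.05,
                    case_cohort: str = "cases", reference: str = "reference"
                    ) -> tuple[pd.DataFrame, dict]:
    """Full prioritization + burden: returns the burden table and stage tallies."""
    tallies = {"input": len(svs)}
    in_window, oversized = filter_by_size(svs, min_bp, max_bp)
    oversized_kept = filter_known(oversized, known, known_threshold)
    stage = in_window + oversized_kept
    tallies["size_window"] = len(stage)
    stage = filter_artifacts(stage, blacklist, blacklist_threshold)
    tallies["blacklist"] = len(stage)
    stage = filter_known(stage, known, known_threshold)
    tallies["known_concordance"] = len(stage)
    stage = retain_reportable(stage, rules)
    tallies["acmg_reportable"] = len(stage)
    constrained_stage = [
        sv for sv in stage if constrained_overlap(sv, constraint, gene_intervals)[0]
    ]
    tallies["constrained"] = len(constrained_stage)
    ultra = [sv for sv in constrained_stage
             if flag_ultra_rare(sv, reference, max_ref_freq)]
    tallies["ultra_rare"] = len(ultra)
    table = sv_burden(constrained_stage, case_cohort=case_cohort, reference=reference,
                      constraint=constraint, gene_intervals=gene_intervals,
                      alpha=alpha, max_ref_freq=max_ref_freq)
    for name, count in tallies.items():
        logger.info("sv stage %s: %d calls", name, count)
    return table, tallies
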