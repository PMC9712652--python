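"""Per-gene collapsing burden test of a case cohort against reference panels.

Rare qualifying variants (LoF or missense, reference-panel MAF < 0.01) are
collapsed per gene into a single 2x2 allele-count table

    =============  ===========  =============
                   alt alleles  other alleles
    cases          a            b = 2N_case - a
    panel          c            d = 2N_panel - c
    =============  ===========  =============

and tested with the Pearson chi-squared statistic (1 df, no continuity
correction) on the raw cells. The effect size is the odds ratio
OR = (a*d)/(b*c) with the Haldane-Anscombe +0.5 correction applied to all
four cells whenever any cell is zero, and a Wald 95% interval
exp(ln OR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)) on the (corrected) cells.
The chi-squared uses raw cells so that p-value and OR stay decoupled.

Counting modes: ``alleles`` (2N chromosomes, the default for collapsed
SNVs) and ``carriers`` (samples carrying >= 1 qualifying allele, the mode
used for structural-variant tables).

A gene is *enriched* against a panel when p < alpha and OR > 1; a gene is
*replicated* when it is enriched (same variant class) against at least one
panel in the discovery cohort and at least one panel in the replication
cohort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import VariantClass, classify_consequence, constraint_flags, is_damaging, is_rare
from .errors import CapabilityError, ValidationError
from .io import AnnotatedVariant, GeneConstraint, VcfCohort


@dataclass(frozen=True)
class CollapsedGeneCount:
    """Collapsed allele counts for one gene x variant class x panel."""

    gene: str
    variant_class: VariantClass
    case_alleles: int
    case_allele_number: int
    panel_alleles: int
    panel_allele_number: int
    n_variants: int

    def __post_init__(self):
        if not (0 <= self.case_alleles <= self.case_allele_number):
            raise ValidationError(
                f"case alleles {self.case_alleles} outside [0, {self.case_allele_number}] "
                f"for {self.gene}"
            )
        if not (0 <= self.panel_alleles <= self.panel_allele_number):
            raise ValidationError(
                f"panel alleles {self.panel_alleles} outside [0, {self.panel_allele_number}] "
                f"for {self.gene}"
            )


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    variant_class: VariantClass
    panel: str
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    enriched: bool
    intolerant_pli: bool = False
    intolerant_loeuf: bool = False
    n_variants: int = 0


@dataclass(frozen=True)
class MultiHitCarrier:
    subject: str
    gene: str
    n_sites: int

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValidationError(f"multi-hit carrier requires >= 2 sites, got {self.n_sites}")


def chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table.

    Degenerate tables (a zero row or column margin) return (0.0, 1.0) by
    convention: no evidence either way rather than fabricated significance.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def odds_ratio_wald(a: float, b: float, c: float, d: float,
                    z: float = 1.959963984540054) -> tuple[float, float, float]:
    """OR and Wald 95% CI; Haldane-Anscombe +0.5 on all cells if any is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


def burden_test(counts: CollapsedGeneCount, panel: str = "panel",
                alpha: float = 0.05) -> BurdenResult:
    """Test one collapsed gene count against one reference panel."""
    if counts.case_allele_number == 0 or counts.panel_allele_number == 0:
        raise ValidationError(f"zero allele number for {counts.gene}")
    a = counts.case_alleles
    b = counts.case_allele_number - a
    c = counts.panel_alleles
    d = counts.panel_allele_number - c
    chi2, p = chi2_2x2(a, b, c, d)
    or_, lo, hi = odds_ratio_wald(a, b, c, d)
    return BurdenResult(
        gene=counts.gene, variant_class=counts.variant_class, panel=panel,
        a=a, b=b, c=c, d=d, chi2=chi2, p_value=p,
        odds_ratio=or_, ci_low=lo, ci_high=hi,
        enriched=(p < alpha and or_ > 1), n_variants=counts.n_variants,
    )


def _carrier_count(genotypes_row: np.ndarray) -> int:
    return int((genotypes_row > 0).sum())


def collapse(variants: Sequence[AnnotatedVariant], n_cases: int, panel: str,
             panel_allele_number: int, variant_class: VariantClass,
             damaging_only: bool = False, counting: str = "alleles",
             genotypes: np.ndarray | None = None) -> list[CollapsedGeneCount]:
    """Collapse already rarity-filtered variants per gene for one class and panel.

    Sites absent from the panel contribute 0 alt alleles against the
    declared ``panel_allele_number``. With ``counting='carriers'`` the case
    side counts samples carrying at least one qualifying allele (requires
    ``genotypes``); the panel side keeps its allele counts, as reference
    panels publish counts, not genotypes.
    """
    if counting not in ("alleles", "carriers"):
        raise ValidationError(f"counting must be 'alleles' or 'carriers', got {counting!r}")
    if counting == "carriers" and genotypes is None:
        raise CapabilityError("carrier counting requires per-sample genotypes")

    per_gene: dict[str, dict] = {}
    for idx, v in enumerate(variants):
        if not v.gene:
            continue
        if classify_consequence(v.consequence_term) is not variant_class:
            continue
        if damaging_only and variant_class is VariantClass.MISSENSE and not is_damaging(v.cadd_phred):
            continue
        acc = per_gene.setdefault(v.gene, {"case": 0, "panel": 0, "n": 0, "carrier_mask": None})
        if counting == "alleles":
            acc["case"] += v.case_allele_count
        else:
            mask = genotypes[idx] > 0
            acc["carrier_mask"] = mask if acc["carrier_mask"] is None else (acc["carrier_mask"] | mask)
        acc["panel"] += v.panel_freqs.get(panel, (0, 0))[0]
        acc["n"] += 1

    case_total = n_cases if counting == "carriers" else 2 * n_cases
    out = []
    for gene in sorted(per_gene):
        acc = per_gene[gene]
        case_count = (int(acc["carrier_mask"].sum()) if counting == "carriers"
                      else acc["case"])
        out.append(
            CollapsedGeneCount(
                gene=gene, variant_class=variant_class,
                case_alleles=case_count, case_allele_number=case_total,
                panel_alleles=acc["panel"], panel_allele_number=panel_allele_number,
                n_variants=acc["n"],
            )
        )
    return out


RESULT_COLUMNS = ["gene", "class", "panel", "a", "b", "c", "d", "chi2", "p",
                  "OR", "ci_low", "ci_high", "pli", "loeuf", "enriched", "n_variants"]


def run_gba(cohort: VcfCohort | Sequence[AnnotatedVariant], n_cases: int | None = None,
            panels: Mapping[str, int] | None = None,
            constraint: Mapping[str, GeneConstraint] | None = None,
            classes: Iterable[VariantClass] = (VariantClass.LOF, VariantClass.MISSENSE),
            alpha: float = 0.05, rare_threshold: float = 0.01,
            damaging_only: bool = False, counting: str = "alleles",
            adjust: str | None = None) -> pd.DataFrame:
    """Gene burden analysis: rarity filter, collapse, test, sort.

    Parameters
    ----------
    cohort
        A :class:`VcfCohort` or a plain variant list (then ``n_cases`` is
        required).
    panels
        Panel name -> declared allele number (2 x panel sample count). When
        omitted, panel names and allele numbers are taken from the variants.
    adjust
        Optional multiple-testing correction appended as extra columns:
        ``"bonferroni"`` or ``"bh"`` (Benjamini-Hochberg). Off by default;
        the primary p column is always unadjusted.

    Returns one row per gene x class x panel, sorted by p ascending, then
    OR descending, then gene symbol.
    """
    if isinstance(cohort, VcfCohort):
        variants, genotypes = cohort.variants, cohort.genotypes
        n_cases = cohort.n_samples if cohort.n_samples else n_cases
    else:
        variants, genotypes = list(cohort), None
    if n_cases is None:
        raise ValidationError("n_cases is required when no sample columns are available")
    if panels is None:
        panels = {}
        for v in variants:
            for name, (_, an) in v.panel_freqs.items():
                panels[name] = max(panels.get(name, 0), an)
    if not panels:
        raise ValidationError("no reference panels available")

    keep = [i for i, v in enumerate(variants) if is_rare(v, panels, rare_threshold)]
    variants_kept = [variants[i] for i in keep]
    genotypes_kept = genotypes[keep] if genotypes is not None else None

    rows = []
    for panel_name, panel_an in panels.items():
        for vclass in classes:
            for counts in collapse(variants_kept, n_cases, panel_name, panel_an,
                                   vclass, damaging_only, counting, genotypes_kept):
                res = burden_test(counts, panel=panel_name, alpha=alpha)
                pli_flag, loeuf_flag = constraint_flags(counts.gene, constraint or {})
                rows.append({
                    "gene": res.gene, "class": res.variant_class.value, "panel": res.panel,
                    "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                    "chi2": res.chi2, "p": res.p_value, "OR": res.odds_ratio,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "pli": pli_flag, "loeuf": loeuf_flag,
                    "enriched": res.enriched, "n_variants": res.n_variants,
                })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if df.empty:
        return df
    df = df.sort_values(["p", "OR", "gene"], ascending=[True, False, True],
                        kind="mergesort").reset_index(drop=True)
    if adjust:
        from statsmodels.stats.multitest import multipletests
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(adjust)
        if method is None:
            raise ValidationError(f"unknown adjustment {adjust!r}")
        df[f"p_{adjust}"] = multipletests(df["p"], method=method)[1]
    return df


def replicate(discovery: pd.DataFrame, replication: pd.DataFrame,
              alpha: float | None = None) -> pd.DataFrame:
    """Cross-cohort replication of enriched genes.

    A gene (per variant class) is replicated iff it is enriched against at
    least one panel in the discovery results AND against at least one panel
    in the replication results. The output lists the supporting
    panel comparisons on each side.
    """
    def supported(df):
        if df.empty:
            return {}
        enr = df[df["enriched"]]
        out = {}
        for (gene, vclass), grp in enr.groupby(["gene", "class"]):
            out[(gene, vclass)] = sorted(grp["panel"].unique())
        return out

    disc, repl = supported(discovery), supported(replication)
    rows = []
    for key in sorted(set(disc) & set(repl)):
        gene, vclass = key
        rows.append({
            "gene": gene, "class": vclass,
            "discovery_panels": ",".join(disc[key]),
            "replication_panels": ",".join(repl[key]),
        })
    return pd.DataFrame(rows, columns=["gene", "class", "discovery_panels",
                                       "replication_panels"])


def find_multihit_carriers(cohort: VcfCohort, genes: Iterable[str],
                           variant_class: VariantClass | None = None,
                           rare_threshold: float = 0.01,
                           panels: Iterable[str] | None = None) -> list[MultiHitCarrier]:
    """Subjects carrying >= 2 qualifying variant *sites* in the same listed gene.

    A subject homozygous at a single site does not qualify: the unit is
    sites, not alleles.
    """
    if cohort.genotypes is None:
        raise CapabilityError("multi-hit retrieval requires per-sample genotypes")
    genes = set(genes)
    site_counts: dict[str, np.ndarray] = {}
    for idx, v in enumerate(cohort.variants):
        if v.gene not in genes:
            continue
        if variant_class is not None and classify_consequence(v.consequence_term) is not variant_class:
            continue
        if panels is not None and not is_rare(v, panels, rare_threshold):
            continue
        hit = (cohort.genotypes[idx] > 0).astype(int)
        site_counts[v.gene] = site_counts.get(v.gene, 0) + hit
    out = []
    for gene in sorted(site_counts):
        counts = site_counts[gene]
        for sample_idx in np.nonzero(counts >= 2)[0]:
            out.append(MultiHitCarrier(subject=cohort.samples[sample_idx],
                                       gene=gene, n_sites=int(counts[sample_idx])))
    return out
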