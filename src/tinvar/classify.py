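"""Coding-variant classification: consequence class, rarity, damage, constraint.

The vocabulary mirrors the standard Sequence Ontology terms used by VEP.
Loss-of-function (LoF) is exactly {stop_gained, stop_lost, start_lost,
frameshift_variant, splice_donor_variant, splice_acceptor_variant};
missense and synonymous map to their own classes; anything else is OTHER.

Boundary semantics, fixed across the pipeline:

* rare      <=> allele frequency < 0.01 in *every* supplied reference panel
* damaging  <=> CADD phred strictly > 20 (missing score counts as not damaging)
* intolerant gene <=> pLI >= 0.9 (or LOEUF < 0.5 for the LOEUF flag)
"""
from __future__ import annotations

import csv
import logging
from enum import Enum
from importlib import resources
from typing import Mapping

from .errors import ConfigError, ValidationError
from .io import AnnotatedVariant, GeneConstraint

logger = logging.getLogger(__name__)


class VariantClass(str, Enum):
    LOF = "LOF"
    MISSENSE = "MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


def _load_vocabulary() -> dict[str, VariantClass]:
    """Load the versioned consequence-term table shipped with the package."""
    table = {}
    path = resources.files("tinvar").joinpath("data/consequence_terms.tsv")
    with path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["term"].lower()] = VariantClass(row["variant_class"])
    return table


_VOCABULARY = _load_vocabulary()

LOF_TERMS = frozenset(t for t, c in _VOCABULARY.items() if c is VariantClass.LOF)


def classify_consequence(term: str, vocabulary: Mapping[str, VariantClass] | None = None
                         ) -> VariantClass:
    """Map a consequence term to its variant class; unknown terms are OTHER.

    Total and case-insensitive on the documented vocabulary.
    """
    if not term:
        raise ValidationError("empty consequence term")
    vocab = _VOCABULARY if vocabulary is None else vocabulary
    cls = vocab.get(term.lower())
    if cls is None:
        logger.info("unknown consequence term %r mapped to OTHER", term)
        return VariantClass.OTHER
    return cls


def is_damaging(cadd_phred: float | None) -> bool:
    """True iff the CADD phred score is strictly above 20; missing -> False."""
    return cadd_phred is not None and cadd_phred > 20


def is_rare(variant: AnnotatedVariant, panels, threshold: float = 0.01) -> bool:
    """True iff the variant's frequency is below ``threshold`` in every panel.

    A variant absent from a panel of declared size counts as frequency 0
    there. A frequency exactly at the threshold is the common side
    (MAF >= 0.01 is common).
    """
    panels = list(panels)
    if not panels:
        raise ConfigError("is_rare requires at least one reference panel")
    return all(variant.panel_frequency(p) < threshold for p in panels)


def constraint_flags(gene: str, constraint: Mapping[str, GeneConstraint]
                     ) -> tuple[bool, bool]:
    """(pLI >= 0.9, LOEUF < 0.5) flags for a gene; absent gene -> (False, False)."""
    c = constraint.get(gene)
    if c is None:
        logger.info("gene %s absent from constraint table; flags default to False", gene)
        return (False, False)
    return (c.pli >= 0.9, c.loeuf < 0.5)


def cohort_maf_floor(n_samples: int) -> float:
    """Minimum nonzero allele frequency observable in a diploid cohort: 1/(2N).

    Used to annotate variants sitting at the cohort's resolution floor,
    not to drop them.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    return 1.0 / (2 * n_samples)
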