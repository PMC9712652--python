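"""Typed records and readers/writers for every external format the pipeline touches.

Coordinate conventions are uniform across the package: intervals are held
0-based half-open internally; VCF I/O is 1-based (positions preserved as
read); BED I/O is 0-based half-open. All text is UTF-8.

Readers validate strictly and raise :class:`~tinvar.errors.ValidationError`
or :class:`~tinvar.errors.FormatError` instead of coercing; error messages
carry file, line and field. Unknown INFO keys and extra table columns are
tolerated with a logged notice, since annotator outputs (VEP, vcfanno,
AnnotSV) vary.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DURATION_CATEGORIES = ("6m-3y", "3-10y", "10-20y", ">20y", "missing")

_VCF_MISSING = "."


@dataclass
class AnnotatedVariant:
    """One coding SNV/short-indel ALT allele with its annotations.

    ``panel_freqs`` maps a reference-panel name to an (allele_count,
    allele_number) pair; counts are carried exactly so that 2x2 tables
    downstream are built from integers, never from rounded frequencies.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: str
    consequence_term: str
    cadd_phred: float | None
    case_allele_count: int
    case_allele_number: int
    panel_freqs: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}", field="pos")
        if self.alt == self.ref:
            raise ValidationError(f"alt equals ref ({self.ref}) at {self.chrom}:{self.pos}")
        if not (0 <= self.case_allele_count <= self.case_allele_number):
            raise ValidationError(
                f"case allele count {self.case_allele_count} outside "
                f"[0, {self.case_allele_number}] at {self.chrom}:{self.pos}"
            )
        for name, (ac, an) in self.panel_freqs.items():
            if not (0 <= ac <= an):
                raise ValidationError(
                    f"panel {name} allele count {ac} outside [0, {an}] at {self.chrom}:{self.pos}"
                )

    def panel_frequency(self, panel: str) -> float:
        """Allele frequency in a panel; a variant absent from a declared panel is 0."""
        ac, an = self.panel_freqs.get(panel, (0, 0))
        return ac / an if an else 0.0

    @property
    def case_frequency(self) -> float:
        return self.case_allele_count / self.case_allele_number


@dataclass(frozen=True)
class GeneConstraint:
    """gnomAD-style per-gene constraint: pLI, LOEUF, and the LOEUF decile bin."""

    gene: str
    pli: float
    loeuf: float
    loeuf_bin: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.pli <= 1.0):
            raise ValidationError(f"pLI must be in [0,1], got {self.pli}", field="pli")
        if self.loeuf < 0:
            raise ValidationError(f"LOEUF must be >= 0, got {self.loeuf}", field="loeuf")
        if self.loeuf_bin is not None and self.loeuf_bin not in range(10):
            raise ValidationError(
                f"LOEUF bin must be a decile 0-9, got {self.loeuf_bin}", field="loeuf_bin"
            )


@dataclass
class StructuralVariantCall:
    """A DEL/DUP interval with per-cohort carrier counts and classification evidence."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    sv_type: str  # DEL | DUP
    carriers: dict[str, int] = field(default_factory=dict)
    cohort_sizes: dict[str, int] = field(default_factory=dict)
    evidence: dict[str, bool] = field(default_factory=dict)
    acmg_class: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"SV interval end ({self.end}) must exceed start ({self.start})"
            )
        if self.sv_type not in ("DEL", "DUP"):
            raise ValidationError(f"sv_type must be DEL or DUP, got {self.sv_type!r}")
        for cohort, n in self.carriers.items():
            size = self.cohort_sizes.get(cohort)
            if size is not None and n > size:
                raise ValidationError(
                    f"{n} carriers exceed cohort size {size} for {cohort} "
                    f"at {self.chrom}:{self.start}-{self.end}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def ident(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.sv_type}"

    def carrier_frequency(self, cohort: str) -> float:
        return self.carriers.get(cohort, 0) / self.cohort_sizes[cohort]


class RegionSet:
    """A named set of genomic intervals (0-based half-open) with overlap queries.

    Backed by per-chromosome interval trees; query results are independent
    of the order intervals were added in.
    """

    def __init__(self, name: str, intervals=()):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int):
        if end <= start:
            raise ValidationError(f"interval end ({end}) must exceed start ({start})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self._n += 1

    def __len__(self):
        return self._n

    def intervals(self):
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Intersections of [start, end) with the set, clipped to the query."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
        )


@dataclass
class ClinicalRecord:
    """Per-subject questionnaire scores and comorbidity flags.

    THI (Tinnitus Handicap Inventory) and TFI (Tinnitus Functional Index)
    are both 0-100; THI >= 58 defines the severe subgroup, TFI >= 48 the
    chronic/bothersome inclusion criterion.
    """

    subject: str
    age: float
    sex: str
    thi: float
    tfi: float
    hearing_loss: bool
    hyperacusis: bool
    headache: bool
    anxiety: bool
    depression: bool
    duration_category: str = "missing"

    def __post_init__(self):
        for name in ("thi", "tfi"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{name} must be in [0,100], got {v}", field=name)
        if self.duration_category not in DURATION_CATEGORIES:
            raise ValidationError(
                f"duration_category {self.duration_category!r} not in {DURATION_CATEGORIES}",
                field="duration_category",
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VcfCohort:
    """A cohort read from VCF: split variants plus optional per-sample genotypes.

    ``genotypes`` is an (n_variants x n_samples) array of ALT-allele dosages
    (0/1/2, -1 for missing), aligned with ``variants``; ``None`` when the
    file has no sample columns.
    """

    variants: list[AnnotatedVariant]
    samples: list[str]
    genotypes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)


_PANEL_HEADER_RE = re.compile(r"^##panel=<ID=([^,>]+),AN=(\d+)>")


def _panel_declarations(raw_header: str) -> dict[str, int]:
    panels = {}
    for line in raw_header.splitlines():
        m = _PANEL_HEADER_RE.match(line)
        if m:
            panels[m.group(1)] = int(m.group(2))
    return panels


def read_vcf(path) -> VcfCohort:
    """Read an annotated case VCF into split, validated variants.

    Multiallelic records are split per ALT allele before anything else.
    Case allele counts are recomputed from GT fields when sample columns
    are present, otherwise taken from INFO AC/AN. Reference-panel counts
    come from ``AC_PANEL_<name>``/``AN_PANEL_<name>`` INFO pairs; panels
    declared in ``##panel=`` header lines contribute frequency 0 for
    records that lack the keys.
    """
    path = str(path)
    vcf = VCF(path)
    declared_panels = _panel_declarations(vcf.raw_header)
    samples = list(vcf.samples)
    n_samples = len(samples)

    variants: list[AnnotatedVariant] = []
    dosage_rows: list[np.ndarray] = []
    for rec_no, rec in enumerate(vcf, start=1):
        locus = f"{rec.CHROM}:{rec.POS}"
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ")
        for key, val in (("GENE", gene), ("CSQ", csq)):
            if val is None:
                raise FormatError(
                    f"missing required INFO key {key} at {locus}",
                    path=path, line=rec_no, field=key,
                )
        alts = rec.ALT
        n_alt = len(alts)

        if n_samples:
            gt = np.asarray(rec.genotypes, dtype=int)[:, :2]
            if np.any(gt > n_alt):
                raise FormatError(
                    f"GT allele index exceeds ALT count at {locus}",
                    path=path, line=rec_no, field="GT",
                )
            allele_number = int((gt >= 0).sum())
        else:
            an_info = rec.INFO.get("AN")
            if an_info is None:
                raise FormatError(
                    f"no sample columns and no INFO AN at {locus}",
                    path=path, line=rec_no, field="AN",
                )
            allele_number = int(an_info)

        for alt_idx, alt in enumerate(alts):
            fields = _split_info(rec, alt_idx, n_alt)
            if n_samples:
                dosages = (gt == alt_idx + 1).sum(axis=1).astype(np.int8)
                dosages[(gt < 0).all(axis=1)] = -1
                ac = int((gt == alt_idx + 1).sum())
            else:
                ac = fields.pop("__AC__", None)
                if ac is None:
                    raise FormatError(
                        f"no sample columns and no INFO AC at {locus}",
                        path=path, line=rec_no, field="AC",
                    )
                dosages = None

            panel_freqs = dict(fields["panels"])
            for name, an in declared_panels.items():
                panel_freqs.setdefault(name, (0, an))

            variants.append(
                AnnotatedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=gene,
                    consequence_term=csq if n_alt == 1 else csq.split(",")[alt_idx],
                    cadd_phred=fields["cadd"],
                    case_allele_count=ac,
                    case_allele_number=allele_number,
                    panel_freqs=panel_freqs,
                )
            )
            if dosages is not None:
                dosage_rows.append(dosages)

    genotypes = np.vstack(dosage_rows) if dosage_rows else None
    if n_samples and not variants:
        genotypes = None
    return VcfCohort(variants=variants, samples=samples, genotypes=genotypes)


def _split_info(rec, alt_idx: int, n_alt: int) -> dict:
    """Per-ALT view of the INFO fields this pipeline understands."""

    def per_alt(value):
        if value is None:
            return None
        if n_alt == 1:
            return value[0] if isinstance(value, tuple) else value
        return value[alt_idx] if isinstance(value, tuple) else value

    out = {"panels": {}, "cadd": None}
    cadd = per_alt(rec.INFO.get("CADD"))
    if cadd is not None:
        out["cadd"] = float(cadd)
    ac = per_alt(rec.INFO.get("AC"))
    if ac is not None:
        out["__AC__"] = int(ac)
    for key, value in rec.INFO:
        if key.startswith("AC_PANEL_"):
            name = key[len("AC_PANEL_"):]
            an = rec.INFO.get(f"AN_PANEL_{name}")
            if an is None:
                raise FormatError(
                    f"INFO {key} present without AN_PANEL_{name} at {rec.CHROM}:{rec.POS}",
                    field=f"AN_PANEL_{name}",
                )
            out["panels"][name] = (int(per_alt(value)), int(an))
    return out


_VCF_INFO_HEADERS = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence term">',
    '##INFO=<ID=CADD,Number=A,Type=Float,Description="CADD phred score">',
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Case alternate allele count">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Case allele number">',
]


def write_vcf(variants, path, samples=None, genotypes=None):
    """Write variants to a VCF v4.2 text file.

    With ``samples``/``genotypes`` (ALT dosage matrix, -1 missing), GT
    columns are emitted; otherwise case counts go into INFO AC/AN.
    ``read_vcf(write_vcf(x))`` reproduces every field.
    """
    variants = list(variants)
    if (samples is None) != (genotypes is None):
        raise ValidationError("samples and genotypes must be given together")
    panel_names = sorted({p for v in variants for p in v.panel_freqs})
    panel_an = {
        p: max(v.panel_freqs[p][1] for v in variants if p in v.panel_freqs)
        for p in panel_names
    }
    contigs = sorted({v.chrom for v in variants})

    lines = ["##fileformat=VCFv4.2", "##source=tinvar"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [f"##panel=<ID={p},AN={panel_an[p]}>" for p in panel_names]
    lines += _VCF_INFO_HEADERS
    for p in panel_names:
        lines.append(
            f'##INFO=<ID=AC_PANEL_{p},Number=A,Type=Integer,Description="Panel {p} allele count">'
        )
        lines.append(
            f'##INFO=<ID=AN_PANEL_{p},Number=1,Type=Integer,Description="Panel {p} allele number">'
        )
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples is not None:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        header_cols += ["FORMAT"] + list(samples)
    lines.append("\t".join(header_cols))

    for i, v in enumerate(variants):
        info = [f"GENE={v.gene}", f"CSQ={v.consequence_term}"]
        if v.cadd_phred is not None:
            info.append(f"CADD={v.cadd_phred:g}")
        if samples is None:
            info.append(f"AC={v.case_allele_count}")
            info.append(f"AN={v.case_allele_number}")
        for p, (ac, an) in sorted(v.panel_freqs.items()):
            info += [f"AC_PANEL_{p}={ac}", f"AN_PANEL_{p}={an}"]
        row = [v.chrom, str(v.pos), _VCF_MISSING, v.ref, v.alt,
               _VCF_MISSING, "PASS", ";".join(info)]
        if samples is not None:
            row.append("GT")
            row += [_GT_STRINGS[d] for d in np.asarray(genotypes[i], dtype=int)]
        lines.append("\t".join(row))

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


# ---------------------------------------------------------------------------
# Constraint table, BED, SV TSV, clinical CSV
# ---------------------------------------------------------------------------

def read_constraint_table(path) -> dict[str, GeneConstraint]:
    """Read a gene constraint TSV (columns gene, pli, loeuf, loeuf_bin)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "pli", "loeuf"):
        if col not in df.columns:
            raise FormatError(f"constraint table missing column {col!r}", path=path, field=col)
    dupes = df["gene"][df["gene"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(
            f"duplicate gene rows in constraint table: {', '.join(dupes)}", path=path
        )
    out = {}
    for i, row in df.iterrows():
        bin_val = row.get("loeuf_bin")
        if bin_val is None or (isinstance(bin_val, float) and np.isnan(bin_val)):
            bin_val = None
        else:
            bin_val = int(bin_val)
        try:
            out[row["gene"]] = GeneConstraint(
                gene=row["gene"], pli=float(row["pli"]),
                loeuf=float(row["loeuf"]), loeuf_bin=bin_val,
            )
        except ValidationError as e:
            raise ValidationError(str(e), path=path, line=i + 2) from None
    return out


def write_constraint_table(constraints: Mapping[str, GeneConstraint], path):
    rows = [
        {"gene": c.gene, "pli": c.pli, "loeuf": c.loeuf,
         "loeuf_bin": c.loeuf_bin if c.loeuf_bin is not None else ""}
        for c in constraints.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_regions_bed(path, name: str) -> RegionSet:
    """Read a BED3 file (0-based half-open) into a RegionSet."""
    regions = RegionSet(name)
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED line has fewer than 3 columns", path=path, line=line_no)
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValidationError(
                    f"BED end ({end}) must exceed start ({start})", path=path, line=line_no
                )
            regions.add(chrom, start, end)
    return regions


def write_regions_bed(regions: RegionSet, path):
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end in regions.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return path


def read_sv_calls(path) -> list[StructuralVariantCall]:
    """Read SV calls from TSV.

    Expected columns: chrom, start, end, sv_type, plus ``carriers_<cohort>``
    and ``n_<cohort>`` pairs; optional ``evidence`` (semicolon-joined flags)
    and ``acmg_class``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "start", "end", "sv_type"):
        if col not in df.columns:
            raise FormatError(f"SV table missing column {col!r}", path=path, field=col)
    carrier_cols = [c for c in df.columns if c.startswith("carriers_")]
    size_cols = {c[len("n_"):]: c for c in df.columns if c.startswith("n_")}
    svs = []
    for i, row in df.iterrows():
        carriers, sizes = {}, {}
        for col in carrier_cols:
            cohort = col[len("carriers_"):]
            carriers[cohort] = int(row[col])
            if cohort in size_cols:
                sizes[cohort] = int(row[size_cols[cohort]])
        evidence = {}
        ev = row.get("evidence")
        if isinstance(ev, str) and ev:
            evidence = {k: True for k in ev.split(";")}
        acmg = row.get("acmg_class")
        acmg = None if acmg is None or (isinstance(acmg, float) and np.isnan(acmg)) else int(acmg)
        try:
            svs.append(
                StructuralVariantCall(
                    chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
                    sv_type=str(row["sv_type"]), carriers=carriers, cohort_sizes=sizes,
                    evidence=evidence, acmg_class=acmg,
                )
            )
        except ValidationError as e:
            raise ValidationError(str(e), path=path, line=i + 2) from None
    return svs


def write_sv_calls(svs, path):
    cohorts = sorted({c for sv in svs for c in sv.carriers})
    rows = []
    for sv in svs:
        row = {"chrom": sv.chrom, "start": sv.start, "end": sv.end, "sv_type": sv.sv_type}
        for c in cohorts:
            row[f"carriers_{c}"] = sv.carriers.get(c, 0)
            row[f"n_{c}"] = sv.cohort_sizes.get(c, "")
        row["evidence"] = ";".join(sorted(k for k, v in sv.evidence.items() if v))
        row["acmg_class"] = sv.acmg_class if sv.acmg_class is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


_BOOL_FIELDS = ("hearing_loss", "hyperacusis", "headache", "anxiety", "depression")


def read_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical CSV (RFC 4180) into validated records."""
    df = pd.read_csv(path, dtype={"subject": str, "sex": str, "duration_category": str})
    required = ("subject", "age", "sex", "thi", "tfi") + _BOOL_FIELDS
    for col in required:
        if col not in df.columns:
            raise FormatError(f"clinical table missing column {col!r}", path=path, field=col)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ClinicalRecord(
                    subject=row["subject"], age=float(row["age"]), sex=row["sex"],
                    thi=float(row["thi"]), tfi=float(row["tfi"]),
                    duration_category=row.get("duration_category", "missing"),
                    **{f: bool(int(row[f])) for f in _BOOL_FIELDS},
                )
            )
        except ValidationError as e:
            raise ValidationError(str(e), path=path, line=i + 2) from None
    return records


def write_clinical(records, path):
    rows = []
    for r in records:
        row = {"subject": r.subject, "age": r.age, "sex": r.sex, "thi": r.thi, "tfi": r.tfi}
        row.update({f: int(getattr(r, f)) for f in _BOOL_FIELDS})
        row["duration_category"] = r.duration_category
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
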