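"""Render burden and clinical outputs in the field's table conventions.

Cell formats: SV carrier cells are ``count (frequency to 3 decimals)``,
clinical cells are ``count (whole %)``, and p-values below 0.001 render
as ``<0.001``.
"""
from __future__ import annotations

import math

import pandas as pd

from .clinical import display_percent


def format_sv_cell(carriers: int, cohort_size: int) -> str:
    return f"{carriers} ({carriers / cohort_size:.3f})"


def format_clinical_cell(count: int, total: int) -> str:
    return f"{count} ({display_percent(count, total)}%)"


def format_p(p: float) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def render_markdown_table(df: pd.DataFrame, title: str = "") -> str:
    lines = []
    if title:
        lines += [f"### {title}", ""]
    cols = list(df.columns)
    lines.append("| " + " | ".join(cols) + " |")
    lines.append("|" + "|".join("---" for _ in cols) + "|")
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_sv_report(sv_table: pd.DataFrame) -> str:
    """A Table-2-style view: per-cohort 'n (freq)' cells plus the test p."""
    rows = []
    for _, r in sv_table.iterrows():
        row = {
            "SV": r["ident"], "type": r["sv_type"], "genes": r.get("genes", ""),
            "cases": f"{int(r['carriers_case'])} ({r['freq_case']:.3f})",
            "reference": f"{int(r['carriers_ref'])} ({r['freq_ref']:.3f})",
            "p": format_p(r["p"]),
        }
        if "carriers_severe" in r and not pd.isna(r.get("carriers_severe")):
            row["severe"] = f"{int(r['carriers_severe'])} ({r['freq_severe']:.3f})"
        rows.append(row)
    return render_markdown_table(pd.DataFrame(rows), "SV burden (cases vs reference)")


def render_clinical_report(comparisons: pd.DataFrame) -> str:
    df = comparisons.copy()
    if "p" in df.columns:
        df["p"] = df["p"].map(format_p)
    return render_markdown_table(df, "Clinical features")
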