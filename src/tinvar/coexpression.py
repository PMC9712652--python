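"""Probe correlation and cross-gene regional co-expression.

A stand-in for the brain-atlas microarray step: given an expression
matrix (probes x brain regions, with each probe assigned to a gene),
compute Pearson correlations between the probes of a gene, select probes
with a significant correlation (two-sided p < 0.05 by default), and
report the regions where the selected probes of all queried genes are
simultaneously expressed above threshold (each probe's own row median by
default; neither cutoff is standardized in the field, so both are
explicit parameters).
"""
from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

GENE_COLUMN = "gene"


def read_expression_matrix(path) -> pd.DataFrame:
    """Probes x regions TSV: index column probe id, first column gene symbol."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if GENE_COLUMN not in df.columns:
        raise ValidationError(f"expression matrix needs a {GENE_COLUMN!r} column")
    if df.index.duplicated().any():
        raise ValidationError("duplicate probe ids in expression matrix")
    return df


def _check_matrix(matrix: pd.DataFrame):
    if GENE_COLUMN not in matrix.columns:
        raise ValidationError(f"expression matrix needs a {GENE_COLUMN!r} column")
    if matrix.index.duplicated().any():
        raise ValidationError("duplicate probe ids in expression matrix")
    if matrix.shape[1] - 1 < 2:
        raise ValidationError("need >= 2 regions for any correlation")


def probe_correlations(matrix: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Pearson r and two-sided p for every probe pair of a gene across regions.

    A zero-variance probe yields a missing correlation (NaN) rather than
    an error; correlations are invariant under positive affine rescaling
    of a probe.
    """
    _check_matrix(matrix)
    sub = matrix[matrix[GENE_COLUMN] == gene].drop(columns=[GENE_COLUMN])
    if len(sub) < 2:
        raise ValidationError(f"gene {gene} has {len(sub)} probe(s); need >= 2")
    rows = []
    for p1, p2 in combinations(sub.index, 2):
        x, y = sub.loc[p1].to_numpy(float), sub.loc[p2].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"gene": gene, "probe_1": p1, "probe_2": p2,
                     "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def _selected_probes(matrix: pd.DataFrame, gene: str, p_threshold: float) -> list[str]:
    """Probes of a gene supported by a significant inter-probe correlation.

    A single-probe gene is taken at face value (its one probe selected);
    with several probes, a probe qualifies if it has a significant
    positive correlation with at least one sibling probe.
    """
    sub = matrix[matrix[GENE_COLUMN] == gene]
    if sub.empty:
        raise ValidationError(f"gene {gene} absent from expression matrix")
    if len(sub) == 1:
        return list(sub.index)
    corr = probe_correlations(matrix, gene)
    hits = corr[(corr["p"] < p_threshold) & (corr["r"] > 0)]
    selected = sorted(set(hits["probe_1"]) | set(hits["probe_2"]))
    if not selected:
        raise ValidationError(f"gene {gene} has no probe pair with p < {p_threshold}")
    return selected


def coexpressed_regions(matrix: pd.DataFrame, genes: Sequence[str],
                        threshold: float | None = None,
                        p_threshold: float = 0.05) -> list[str]:
    """Regions where the selected probes of all listed genes exceed threshold.

    ``threshold=None`` uses each probe's own row median; a scalar applies
    uniformly. Returns region labels in matrix column order.
    """
    _check_matrix(matrix)
    probes = []
    for gene in genes:
        probes.extend(_selected_probes(matrix, gene, p_threshold))
    expr = matrix.loc[probes].drop(columns=[GENE_COLUMN]).astype(float)
    if threshold is None:
        cutoff = expr.median(axis=1).to_numpy()[:, None]
        above = expr.to_numpy() > cutoff
    else:
        above = expr.to_numpy() > threshold
    mask = above.all(axis=0)
    return [region for region, ok in zip(expr.columns, mask) if ok]
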