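"""Panel co-expression analysis and Fisher-z correlation averaging.

A reference-gene panel is validated by the genes co-expressed with it: for
each panel gene, every other gene whose Pearson correlation across all
samples exceeds a threshold in absolute value is a co-expression partner,
and the strongest partners form the RGCOEX (reference-gene-coexpressed)
panel. Correlation coefficients are averaged on the Fisher-z scale
(z = atanh(cc)), the variance-stabilizing transform for correlations.

Correlations are computed on log2(FPKM + 1) by default; the scale is
exposed because it is a convention, not a mathematical necessity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortError, ExpressionMatrix
from .diffstab import log2_transform

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionResult", "RgcoexPanel",
    "pearson_cc", "coexpressed_genes", "fisher_z", "inverse_fisher_z",
    "average_correlations", "select_rgcoex_panel",
]


@dataclass(frozen=True)
class CoexpressionResult:
    """Thresholded panel-vs-transcriptome correlation pairs.

    ``pairs`` has one row per (panel gene, partner) with |cc| above the
    threshold; ``all_cc`` keeps the full panel x transcriptome correlation
    frame for ranking and diagnostics.
    """

    pairs: pd.DataFrame          # columns: panel_gene, partner, cc, fisher_z
    all_cc: pd.DataFrame         # panel genes x all genes
    cc_threshold: float

    def partners_of(self, panel_gene: str) -> list[str]:
        sel = self.pairs[self.pairs["panel_gene"] == panel_gene]
        return list(sel["partner"])


@dataclass(frozen=True)
class RgcoexPanel:
    genes: tuple[str, ...]
    best_cc: dict[str, float]
    cc_threshold: float
    requested_k: int


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN for a constant vector.

    A constant vector has no defined correlation — the undefined case is
    reported as missing rather than silently as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise CohortError("vectors must have equal length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def fisher_z(cc: float) -> float:
    """Fisher's variance-stabilizing transform, z = atanh(cc)."""
    if not abs(cc) < 1:
        raise CohortError(f"|cc| must be < 1, got {cc}")
    return float(np.arctanh(cc))


def inverse_fisher_z(z: float) -> float:
    return float(np.tanh(z))


def average_correlations(ccs: Sequence[float]) -> float:
    """Mean correlation via Fisher-z: tanh(mean(atanh(cc)))."""
    ccs = [c for c in ccs]
    if len(ccs) == 0:
        raise CohortError("cannot average an empty list of correlations")
    return inverse_fisher_z(float(np.mean([fisher_z(c) for c in ccs])))


def coexpressed_genes(panel: Sequence[str], m: ExpressionMatrix,
                      cc_threshold: float = 0.6, pseudocount: float = 1.0,
                      log_scale: bool = True) -> CoexpressionResult:
    """All genes with |Pearson cc| above threshold against each panel gene.

    Correlations run across ALL samples of the matrix. A panel gene may
    legitimately have zero partners. Constant genes have undefined
    correlation and are treated as missing.
    """
    if not 0 < cc_threshold < 1:
        raise CohortError("cc_threshold must lie in (0, 1)")
    missing = [g for g in panel if g not in m.gene_ids]
    if missing:
        raise CohortError(f"panel gene(s) not in matrix: {missing[:5]}")
    data = log2_transform(m, pseudocount) if log_scale else m.data
    x = data.to_numpy()
    sd = x.std(axis=1, ddof=1)
    mean = x.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zs = (x - mean[:, None]) / sd[:, None]      # constant rows become NaN
    n = x.shape[1]
    panel_idx = [m.gene_ids.index(g) for g in panel]
    cc_mat = zs[panel_idx] @ zs.T / (n - 1)
    cc_mat = np.clip(cc_mat, -1.0, 1.0)
    all_cc = pd.DataFrame(cc_mat, index=list(panel), columns=m.gene_ids)

    rows = []
    for g in panel:
        cc_row = all_cc.loc[g].drop(labels=[g])
        hits = cc_row[cc_row.abs() > cc_threshold].dropna()
        for partner, cc in hits.items():
            z = float(np.arctanh(cc)) if abs(cc) < 1 else float(np.sign(cc) * np.inf)
            rows.append((g, partner, float(cc), z))
    pairs = pd.DataFrame(rows, columns=["panel_gene", "partner", "cc", "fisher_z"])
    return CoexpressionResult(pairs=pairs, all_cc=all_cc, cc_threshold=cc_threshold)


def select_rgcoex_panel(coex: CoexpressionResult, cc_threshold: float = 0.70,
                        k: int = 8) -> RgcoexPanel:
    """Top-k co-expression partners ranked by best |cc| over the panel.

    Panel members themselves are excluded from the ranking (the panel
    validates itself through OTHER genes). If fewer than k partners clear
    the threshold, all passing partners are returned with a warning.
    """
    if k < 1:
        raise CohortError("k must be >= 1")
    panel_genes = set(coex.all_cc.index)
    pairs = coex.pairs[~coex.pairs["partner"].isin(panel_genes)]
    if pairs.empty:
        logger.warning("no co-expression partners available for RGCOEX selection")
        return RgcoexPanel(genes=(), best_cc={}, cc_threshold=cc_threshold,
                           requested_k=k)
    best = pairs.assign(abs_cc=pairs["cc"].abs()).groupby("partner")["abs_cc"].max()
    passing = best[best > cc_threshold].sort_values(ascending=False)
    # stable tie-break on gene id
    ranked = sorted(passing.items(), key=lambda it: (-it[1], it[0]))
    if len(ranked) < k:
        logger.warning("only %d partner(s) exceed |cc| > %.2f (requested %d)",
                       len(ranked), cc_threshold, k)
    chosen = ranked[:k]
    return RgcoexPanel(genes=tuple(g for g, _ in chosen),
                       best_cc={g: float(c) for g, c in chosen},
                       cc_threshold=cc_threshold, requested_k=k)
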