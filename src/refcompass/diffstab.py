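"""Per-gene differential-expression and stability statistics.

The reference-candidate screen applies three criteria jointly to every gene:
no tumor/normal differential expression (BH-adjusted ANOVA FDR > 0.05),
stability (coefficient of variation < 30% across all samples, tumors and
normals combined), and high abundance (mean FPKM > 100). CV and mean are
computed on raw FPKM; differential testing is done on log2(FPKM + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortError, CohortPairing, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateFilterParams", "PanelSummary",
    "log2_transform", "zscore_genes", "log2_tn_ratio", "gene_anova",
    "bh_fdr", "gene_stats", "filter_reference_candidates", "panel_summary",
    "compare_cv_between_groups", "hca",
]


@dataclass(frozen=True)
class CandidateFilterParams:
    """Strict thresholds of the reference-candidate screen.

    A gene passes when fdr > fdr_min AND cv < cv_max_percent AND
    mean > mean_fpkm_min (all strict inequalities).
    """

    fdr_min: float = 0.05
    cv_max_percent: float = 30.0
    mean_fpkm_min: float = 100.0

    def __post_init__(self):
        if min(self.fdr_min, self.cv_max_percent, self.mean_fpkm_min) < 0:
            raise CohortError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class PanelSummary:
    genes: tuple[str, ...]
    average_sd: float
    average_cv_percent: float


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(FPKM + pseudocount); genes x samples DataFrame."""
    if pseudocount < 0:
        raise CohortError("pseudocount must be >= 0")
    if pseudocount == 0 and (m.values == 0).any():
        raise CohortError("zero FPKM with zero pseudocount: log2 undefined")
    return np.log2(m.data + pseudocount)


def zscore_genes(transformed: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sample SD 1 (ddof=1).

    Zero-variance genes cannot be standardized; they are dropped with a
    warning rather than raising, since whole-transcriptome matrices
    routinely contain flat rows.
    """
    sd = transformed.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("excluding %d zero-variance gene(s) from z-scoring: %s",
                       int(flat.sum()), list(transformed.index[flat][:5]))
    kept = transformed.loc[~flat]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~flat], axis=0)


def log2_tn_ratio(m: ExpressionMatrix, pairing: CohortPairing,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene, per-pair log2(tumor / normal), columns indexed by tumor id."""
    logt = log2_transform(m.subset(samples=pairing.tumor_ids), pseudocount)
    logn = log2_transform(m.subset(samples=pairing.normal_ids), pseudocount)
    out = logt.to_numpy() - logn.to_numpy()
    return pd.DataFrame(out, index=m.gene_ids, columns=pairing.tumor_ids)


def gene_anova(m: ExpressionMatrix, tumor_samples: Sequence[str],
               normal_samples: Sequence[str], pseudocount: float = 1.0,
               paired: bool = False) -> pd.Series:
    """Two-group one-way ANOVA p per gene on log2(FPKM + pseudocount).

    With two groups the F statistic is the square of the pooled-variance t,
    so the p-values coincide with a two-sided equal-variance t-test. The
    ``paired`` option tests the per-pair log2 ratios against zero instead
    (samples must then be listed pair-aligned); it is off by default.
    """
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise CohortError("each group needs at least 2 samples")
    logm = log2_transform(m, pseudocount)
    a = logm[list(tumor_samples)].to_numpy()
    b = logm[list(normal_samples)].to_numpy()
    if paired:
        if a.shape != b.shape:
            raise CohortError("paired test requires equal group sizes")
        res = sps.ttest_1samp(a - b, 0.0, axis=1)
    else:
        res = sps.f_oneway(a, b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within- and between-group variance leaves F undefined; such a
    # gene shows no evidence of a difference, so report p = 1
    degenerate = np.isnan(p)
    if degenerate.any():
        logger.debug("%d gene(s) with degenerate variance: p set to 1",
                     int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
    return pd.Series(p, index=m.gene_ids, name="p_value")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise CohortError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_stats(m: ExpressionMatrix, pairing: CohortPairing,
               pseudocount: float = 1.0, paired_test: bool = False) -> pd.DataFrame:
    """Per-gene summary table driving the candidate screen.

    Columns: mean_fpkm, sd_fpkm (sample SD, n-1), cv_percent (over all
    tumors and normals combined), p_value, fdr, mean_log2_tn. CV is NaN
    (and the gene flagged in ``cv_defined``) when the mean is zero.
    """
    sub = m.subset(samples=pairing.tumor_ids + pairing.normal_ids)
    vals = sub.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    if (mean == 0).any():
        logger.warning("%d gene(s) with zero mean FPKM: CV undefined",
                       int((mean == 0).sum()))
    p = gene_anova(sub, pairing.tumor_ids, pairing.normal_ids,
                   pseudocount=pseudocount, paired=paired_test)
    ratios = log2_tn_ratio(m, pairing, pseudocount)
    return pd.DataFrame({
        "mean_fpkm": mean,
        "sd_fpkm": sd,
        "cv_percent": cv,
        "cv_defined": mean > 0,
        "p_value": p.to_numpy(),
        "fdr": bh_fdr(p.to_numpy()),
        "mean_log2_tn": ratios.mean(axis=1).to_numpy(),
    }, index=pd.Index(m.gene_ids, name="gene_id"))


def filter_reference_candidates(stats: pd.DataFrame,
                                params: CandidateFilterParams = CandidateFilterParams(),
                                ) -> list[str]:
    """Apply the three strict screen criteria; sort by ascending CV, ties by id."""
    ok = (
        (stats["fdr"] > params.fdr_min)
        & (stats["cv_percent"] < params.cv_max_percent)
        & (stats["mean_fpkm"] > params.mean_fpkm_min)
        & stats["cv_defined"]
    )
    passed = stats.loc[ok, "cv_percent"]
    return sorted(passed.index, key=lambda g: (passed[g], g))


def panel_summary(stats: pd.DataFrame, genes: Sequence[str]) -> PanelSummary:
    """Unweighted mean SD and CV over a gene panel."""
    if len(genes) == 0:
        raise CohortError("empty gene panel")
    missing = [g for g in genes if g not in stats.index]
    if missing:
        raise CohortError(f"panel gene(s) missing from stats: {missing[:5]}")
    sub = stats.loc[list(genes)]
    return PanelSummary(genes=tuple(genes),
                        average_sd=float(sub["sd_fpkm"].mean()),
                        average_cv_percent=float(sub["cv_percent"].mean()))


def _group_cv(m: ExpressionMatrix, genes: Sequence[str], samples: Sequence[str]) -> np.ndarray:
    vals = m.subset(genes=genes, samples=samples).values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, 100.0 * sd / mean, np.nan)


def compare_cv_between_groups(m: ExpressionMatrix, genes: Sequence[str],
                              group_a: Sequence[str], group_b: Sequence[str],
                              ) -> tuple[float, float]:
    """Two-sample equal-variance t-test on per-gene CVs between sample groups.

    Each gene's CV is computed within group A and within group B; the test
    compares the two CV vectors across genes (spreadsheet two-sample t-test
    convention). Returns (t statistic, two-sided p).
    """
    if len(genes) < 2:
        raise CohortError("need at least 2 genes to compare CV distributions")
    cv_a = _group_cv(m, genes, group_a)
    cv_b = _group_cv(m, genes, group_b)
    res = sps.ttest_ind(cv_a, cv_b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class Dendrogram:
    linkage: np.ndarray        # scipy linkage matrix over samples
    labels: tuple[str, ...]
    leaf_order: tuple[str, ...]


def hca(z: pd.DataFrame, linkage_method: str = "average",
        metric: str = "euclidean") -> Dendrogram:
    """Agglomerative clustering of samples on a gene-standardized matrix."""
    if z.shape[1] < 2:
        raise CohortError("need at least 2 samples to cluster")
    x = z.to_numpy().T
    if np.isnan(x).any():
        raise CohortError("NaN in matrix passed to hca")
    link = hierarchy.linkage(x, method=linkage_method, metric=metric)
    leaves = hierarchy.leaves_list(link)
    labels = tuple(z.columns)
    return Dendrogram(linkage=link, labels=labels,
                      leaf_order=tuple(labels[i] for i in leaves))
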