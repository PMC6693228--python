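"""PCA embedding, L2-distance outlier calling and stage-class enrichment.

The subtyping procedure mirrors a manual analysis: project samples onto the
first two principal components of a small gene panel, draw a circle around
the bulk of the cohort, and ask whether the samples falling outside are
enriched for high-stage tumors and their adjacent normals. The defaults
make the manual step reproducible — center at the centroid, radius at a
distance quantile — while preserving explicit overrides.

The enrichment test follows spreadsheet CHITEST semantics: Pearson
chi-square on the 2x2 table with margin-derived expected counts, one
degree of freedom, no continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_io import CohortError, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding", "OutlierResult", "EnrichmentResult",
    "pca_embed", "flag_outliers", "build_contingency",
    "chi_square_enrichment", "select_high_cv_panel", "fold_change_flags",
]


@dataclass(frozen=True)
class Embedding:
    """Sample coordinates on the top-k principal components."""

    coords: pd.DataFrame               # samples x components, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    components: np.ndarray             # k x genes loadings (orthonormal rows)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coords.index)


@dataclass(frozen=True)
class OutlierResult:
    center: np.ndarray
    radius: float
    distance: pd.Series                # per sample L2 distance to center
    outside: pd.Series                 # strict distance > radius

    @property
    def flags(self) -> dict[str, bool]:
        return {s: bool(v) for s, v in self.outside.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float
    dof: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool = False


def pca_embed(z: pd.DataFrame, k: int = 2) -> Embedding:
    """Project samples onto the top-k principal components.

    ``z`` is a gene-standardized matrix (genes x samples). The projection is
    computed by SVD of the sample-centered data. Component signs are fixed
    deterministically: the largest-magnitude gene loading of each component
    is made positive, so repeated runs are comparable.
    """
    n_genes, n_samples = z.shape
    if not 1 <= k <= min(n_genes, n_samples):
        raise CohortError(f"k={k} out of range for a {n_genes}x{n_samples} matrix")
    x = z.to_numpy().T                     # samples x genes
    if np.isnan(x).any():
        raise CohortError("NaN in matrix passed to pca_embed")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign convention
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u[:, :k] * s[:k]
    total = float((s ** 2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return Embedding(
        coords=pd.DataFrame(coords, index=z.columns,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=evr,
        components=vt[:k],
    )


def flag_outliers(e: Embedding, center: Sequence[float] | None = None,
                  radius: float | None = None,
                  radius_quantile: float = 90.0) -> OutlierResult:
    """Call samples outside a circle on PC1-PC2.

    Default center is the centroid of all samples and the default radius is
    the ``radius_quantile``-th percentile of sample distances, reproducing
    the manual circle-drawing step; both can be overridden. A sample is an
    outlier when its Euclidean distance strictly exceeds the radius.
    """
    if e.coords.shape[1] < 2:
        raise CohortError("embedding needs at least 2 components")
    xy = e.coords.iloc[:, :2].to_numpy()
    c = xy.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    if c.shape != (2,):
        raise CohortError("center must be a 2-vector on PC1-PC2")
    dist = np.sqrt(((xy - c) ** 2).sum(axis=1))
    r = float(np.percentile(dist, radius_quantile)) if radius is None else float(radius)
    if r <= 0:
        raise CohortError("radius must be positive")
    distance = pd.Series(dist, index=e.coords.index, name="distance")
    return OutlierResult(center=c, radius=r, distance=distance,
                         outside=distance > r)


def build_contingency(flags: Mapping[str, bool],
                      classes: Mapping[str, str]) -> np.ndarray:
    """2x2 table: rows {HST+HSN, LST+LSN}, columns {outside, inside}.

    Samples whose stage class is missing or not one of the four labels are
    excluded with a warning (they carry no stage information).
    """
    table = np.zeros((2, 2), dtype=int)
    skipped = []
    for sid, outside in flags.items():
        cls = classes.get(sid)
        if cls in ("HST", "HSN"):
            row = 0
        elif cls in ("LST", "LSN"):
            row = 1
        else:
            skipped.append(sid)
            continue
        table[row, 0 if outside else 1] += 1
    if skipped:
        logger.warning("excluded %d sample(s) without a stage class: %s",
                       len(skipped), skipped[:5])
    return table


def chi_square_enrichment(table: np.ndarray) -> EnrichmentResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Expected counts come from the margins. A zero row margin is an error
    (an empty stage class cannot be tested); if a column margin is zero the
    observed table equals its expectation and the statistic is 0, p = 1.
    Expected cells below 1 attach a warning flag to the result rather than
    failing, matching how a spreadsheet test would silently proceed.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise CohortError("contingency table must be 2x2 non-negative integers")
    if (t.sum(axis=1) == 0).any():
        raise CohortError("zero row margin: stage class empty")
    if (t.sum(axis=0) == 0).any():
        expected = t.sum(axis=1, keepdims=True) * t.sum(axis=0, keepdims=True) / t.sum()
        return EnrichmentResult(statistic=0.0, dof=1, p_value=1.0,
                                expected=expected,
                                low_expected_warning=bool((expected < 1).any()))
    stat, p, dof, expected = sps.chi2_contingency(t, correction=False)
    low = bool((expected < 1).any())
    if low:
        logger.warning("expected cell count below 1; chi-square approximation is rough")
    return EnrichmentResult(statistic=float(stat), dof=int(dof),
                            p_value=float(p), expected=expected,
                            low_expected_warning=low)


def select_high_cv_panel(candidates: Sequence[str], m: ExpressionMatrix,
                         subgroup_samples: Sequence[str], k: int = 8) -> list[str]:
    """Pick the k candidate genes with the largest CV over a sample subgroup.

    CV is computed on raw FPKM within ``subgroup_samples`` only (e.g. the
    high-stage tumors). Ties at the cut are broken by ascending gene id.
    """
    if k > len(candidates):
        raise CohortError(f"k={k} exceeds the {len(candidates)} candidates")
    vals = m.subset(genes=list(candidates), samples=list(subgroup_samples)).values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, -np.inf)
    order = sorted(zip(-cv, candidates))
    return [g for _, g in order[:k]]


def fold_change_flags(m: ExpressionMatrix, genes: Sequence[str],
                      baseline_samples: Sequence[str],
                      fold: float = 4.0) -> pd.DataFrame:
    """Flag samples whose FPKM falls more than ``fold`` below a baseline mean.

    The baseline is the mean FPKM over ``baseline_samples`` (typically the
    low-stage adjacent normals) per gene; a sample is flagged for a gene
    when its value is strictly below baseline/fold. Genes with zero
    baseline mean are skipped with a warning. Returns a boolean genes x
    samples frame; per-sample flagged-gene counts are its column sums.
    """
    if len(baseline_samples) == 0:
        raise CohortError("baseline sample set is empty")
    if fold <= 1:
        raise CohortError("fold threshold must be > 1")
    sub = m.subset(genes=list(genes))
    base = sub.subset(samples=list(baseline_samples)).data.mean(axis=1)
    zero = base == 0
    if zero.any():
        logger.warning("skipping %d gene(s) with zero baseline mean: %s",
                       int(zero.sum()), list(base.index[zero][:5]))
    kept = sub.data.loc[~zero]
    return kept.lt(base[~zero] / fold, axis=0)
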