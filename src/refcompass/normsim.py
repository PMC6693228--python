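"""Normalization-impact simulation and 2^-ddCt relative quantification.

The central question: how much does the stability (CV) of a reference gene
matter when target expression is divided by it? Each candidate reference —
a real gene or a hypothetical constant with CV exactly 0 — renormalizes a
target panel; tumor/normal separation of the renormalized panel is then
quantified by the mean silhouette of samples on the first two principal
components. Dividing by a constant is provably inert (per-gene z-scores are
shift-invariant on the log scale), so the zero-CV reference reproduces the
unnormalized baseline exactly; noisy references inject their own variance
into every target coherently and can erase the separation.

The qPCR side implements plain 2^-ddCt relative quantification (replicates
averaged in Ct space, multi-gene references combined by arithmetic mean of
Ct, i.e. geometric mean of expression) and Pearson concordance between NGS
log2 tumor/normal ratios and qPCR log2 fold changes, averaged across genes
on the Fisher-z scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .cohort_io import CohortError, CohortPairing, ExpressionMatrix
from .coexpr import average_correlations, pearson_cc
from .diffstab import log2_transform, zscore_genes
from .subtyping import Embedding, pca_embed

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSpec", "NormalizationRun",
    "normalize_by_reference", "separation_score", "cv_separation_profile",
    "delta_delta_ct", "multi_reference_ddct", "ddct_fold_changes",
    "ngs_qpcr_concordance",
]


@dataclass(frozen=True)
class ReferenceSpec:
    """A normalization reference: real gene(s) or a hypothetical constant.

    ``genes`` lists one or more gene ids (multi-gene references divide by
    the per-sample geometric mean); ``constant`` is a fixed FPKM value with
    CV exactly 0 by construction. Exactly one of the two must be set.
    """

    genes: tuple[str, ...] = ()
    constant: float | None = None
    label: str | None = None

    def __post_init__(self):
        if (len(self.genes) > 0) == (self.constant is not None):
            raise CohortError("reference must be either gene(s) or a constant")
        if self.constant is not None and self.constant <= 0:
            raise CohortError("constant reference must be positive")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.constant is not None:
            return f"const:{self.constant:g}"
        return "+".join(self.genes)

    @staticmethod
    def parse(text: str) -> "ReferenceSpec":
        """Parse ``const:100`` or ``GENE`` or ``GENE1+GENE2``."""
        text = text.strip()
        if text.lower().startswith("const:"):
            return ReferenceSpec(constant=float(text.split(":", 1)[1]))
        return ReferenceSpec(genes=tuple(text.split("+")))


@dataclass
class NormalizationRun:
    reference: ReferenceSpec
    reference_cv_percent: float
    normalized: ExpressionMatrix       # targets x samples, divided values
    separation: float | None = None


def _reference_divisor(m: ExpressionMatrix, ref: ReferenceSpec) -> np.ndarray:
    if ref.constant is not None:
        return np.full(len(m.sample_ids), float(ref.constant))
    sub = m.subset(genes=list(ref.genes))
    vals = sub.values
    zero = vals == 0
    if zero.any():
        _, s = np.argwhere(zero)[0]
        raise CohortError(f"reference value 0 in sample {m.sample_ids[s]!r}")
    return np.exp(np.log(vals).mean(axis=0))    # geometric mean over ref genes


def _reference_cv(m: ExpressionMatrix, ref: ReferenceSpec) -> float:
    if ref.constant is not None:
        return 0.0
    div = _reference_divisor(m, ref)
    return float(100.0 * div.std(ddof=1) / div.mean())


def normalize_by_reference(m: ExpressionMatrix, targets: Sequence[str],
                           ref: ReferenceSpec) -> NormalizationRun:
    """Divide each target gene by the per-sample reference expression."""
    div = _reference_divisor(m, ref)
    sub = m.subset(genes=list(targets))
    normalized = ExpressionMatrix(sub.data.div(pd.Series(div, index=sub.sample_ids), axis=1))
    return NormalizationRun(reference=ref,
                            reference_cv_percent=_reference_cv(m, ref),
                            normalized=normalized)


def separation_score(m: "ExpressionMatrix | Embedding", labels: Mapping[str, str],
                     pseudocount: float = 0.0) -> float:
    """Mean silhouette of samples on PC1-PC2 under tumor/normal labels.

    An expression matrix is log2-transformed, gene-standardized and embedded
    on the first two principal components; a precomputed
    :class:`~refcompass.subtyping.Embedding` is scored directly. The
    silhouette coefficient (Euclidean) scores how well the two label groups
    separate: ~1 for clean separation, ~0 for none, negative for inverted
    structure.

    The default pseudocount is 0 (pure log): only then is the score exactly
    invariant to division by a per-sample constant, which is what makes the
    hypothetical zero-CV reference the exact baseline. Matrices containing
    zeros need a positive pseudocount, which sacrifices that exactness.
    """
    if isinstance(m, Embedding):
        sample_ids = m.sample_ids
        coords = m.coords.iloc[:, :2].to_numpy()
    else:
        sample_ids = m.sample_ids
        coords = None
    lab = [labels[s] for s in sample_ids]
    groups = pd.Series(lab).value_counts()
    if len(groups) < 2:
        raise CohortError("need two label groups for a separation score")
    if (groups < 2).any():
        raise CohortError("each label group needs at least 2 samples")
    if coords is None:
        z = zscore_genes(log2_transform(m, pseudocount))
        if z.shape[0] < 2:
            raise CohortError("fewer than 2 variable genes: no embedding")
        coords = pca_embed(z, k=2).coords.to_numpy()
    return float(silhouette_score(coords, np.asarray(lab)))


def cv_separation_profile(m: ExpressionMatrix, targets: Sequence[str],
                          references: Sequence[ReferenceSpec],
                          labels: Mapping[str, str],
                          pseudocount: float = 0.0) -> pd.DataFrame:
    """Score tumor/normal separation after normalizing by each reference.

    The returned table always includes the unnormalized baseline (labelled
    ``none``) and should normally include a hypothetical zero-CV constant
    among the references. Columns: reference, cv_percent, separation.
    """
    if len(references) < 2:
        raise CohortError("need at least 2 references for a profile")
    rows = [("none", float("nan"),
             separation_score(m.subset(genes=list(targets)), labels, pseudocount))]
    for ref in references:
        run = normalize_by_reference(m, targets, ref)
        run.separation = separation_score(run.normalized, labels, pseudocount)
        rows.append((ref.name, run.reference_cv_percent, run.separation))
    return pd.DataFrame(rows, columns=["reference", "cv_percent", "separation"])


# ---------------------------------------------------------------------------
# qPCR: 2^-ddCt


def delta_delta_ct(ct_target_tumor: float, ct_ref_tumor: float,
                   ct_target_normal: float, ct_ref_normal: float) -> float:
    """Relative tumor/normal fold change, 2^-((Ct_T,t - Ct_T,r) - (Ct_N,t - Ct_N,r)).

    Ct values must be replicate-averaged beforehand. Invariant to adding a
    constant to every Ct and to shifting the reference by the same amount
    in both tissues.
    """
    for ct in (ct_target_tumor, ct_ref_tumor, ct_target_normal, ct_ref_normal):
        if not (np.isfinite(ct) and ct > 0):
            raise CohortError("all Ct values must be finite and > 0")
    ddct = (ct_target_tumor - ct_ref_tumor) - (ct_target_normal - ct_ref_normal)
    return float(2.0 ** -ddct)


def _mean_ct(ct: pd.DataFrame, gene: str, sample: str) -> float:
    sel = ct[(ct["gene"] == gene) & (ct["sample"] == sample)]["ct"]
    if sel.empty:
        return float("nan")
    return float(sel.mean())


def multi_reference_ddct(ct: pd.DataFrame, target: str,
                         references: Sequence[str],
                         tumor_sample: str, normal_sample: str) -> float:
    """ddCt fold change with the reference Ct averaged over a gene set.

    Averaging Ct arithmetically is equivalent to a geometric mean on the
    expression scale. With a single reference this reduces to
    :func:`delta_delta_ct`.
    """
    if len(references) == 0:
        raise CohortError("reference set is empty")
    ref_t = float(np.mean([_mean_ct(ct, r, tumor_sample) for r in references]))
    ref_n = float(np.mean([_mean_ct(ct, r, normal_sample) for r in references]))
    tgt_t = _mean_ct(ct, target, tumor_sample)
    tgt_n = _mean_ct(ct, target, normal_sample)
    return delta_delta_ct(tgt_t, ref_t, tgt_n, ref_n)


def ddct_fold_changes(ct: pd.DataFrame, target: str,
                      references: Sequence[str],
                      pairing: CohortPairing) -> pd.Series:
    """Per-pair ddCt fold changes; pairs with missing Ct are skipped."""
    folds = {}
    for t_id, n_id in pairing.pairs:
        try:
            folds[t_id] = multi_reference_ddct(ct, target, references, t_id, n_id)
        except CohortError:
            logger.warning("pair (%s, %s): missing Ct for %s, skipped", t_id, n_id, target)
    return pd.Series(folds, name=target, dtype=float)


def ngs_qpcr_concordance(ngs_log2_tn: pd.DataFrame,
                         qpcr_folds: pd.DataFrame,
                         genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene Pearson concordance of NGS log2 T/N vs qPCR log2 fold.

    Both frames are genes x pairs. Genes with fewer than 3 shared pairs are
    skipped. The last row, labelled ``__average__``, carries the Fisher-z
    average correlation over the retained genes.
    """
    genes = list(genes) if genes is not None else list(ngs_log2_tn.index)
    rows = []
    ccs = []
    for g in genes:
        if g not in ngs_log2_tn.index or g not in qpcr_folds.index:
            logger.warning("gene %s missing from one assay, skipped", g)
            continue
        shared = ngs_log2_tn.columns.intersection(
            qpcr_folds.loc[g].dropna().index)
        if len(shared) < 3:
            logger.warning("gene %s has %d shared pair(s) < 3, skipped", g, len(shared))
            continue
        x = ngs_log2_tn.loc[g, shared].to_numpy(dtype=float)
        y = np.log2(qpcr_folds.loc[g, shared].to_numpy(dtype=float))
        cc = pearson_cc(x, y)
        rows.append((g, cc, len(shared)))
        if not math.isnan(cc) and abs(cc) < 1:
            ccs.append(cc)
    out = pd.DataFrame(rows, columns=["gene", "cc", "n_pairs"]).set_index("gene")
    avg = average_correlations(ccs) if ccs else float("nan")
    out.loc["__average__"] = (avg, sum(out["n_pairs"]) if len(out) else 0)
    return out
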