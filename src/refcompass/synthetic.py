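"""Synthetic paired tumor/normal FPKM cohorts with planted gene classes.

The generator emulates the structure of a paired colorectal cohort: ~79
tumor/normal pairs with a 2:1 high:low stage ratio, and six planted gene
classes with known behavior so every downstream stage of the pipeline has
ground truth:

* ``hallmark_up`` / ``hallmark_down`` — strongly shifted in tumors
  (proliferation-program / enterocyte-program analogues);
* ``classical_ref`` — conventional housekeeping genes that are in fact
  dysregulated: per-gene tumor shifts of varying sign plus large per-gene
  variance, spanning a wide ladder of coefficients of variation;
* ``stable_ref`` — genuinely stable, highly expressed genes whose
  cohort-wide CV is planted inside a configurable band (default 15-29%)
  with mean FPKM above 100;
* ``transport_panel`` — stable, highly expressed genes forming a
  co-expression block; in a planted subset of high-stage patients both the
  tumor AND its adjacent normal collapse by more than ``outlier_fold``
  (default 4-fold; per-value depths are jittered beyond the nominal fold),
  the signature the subtyping stage must rediscover;
* ``coexpr_partner`` — genes sharing the transport block's latent factor
  and collapse, but with enough extra idiosyncratic variance that their
  cohort CV exceeds the candidate-filter band (they validate the panel via
  co-expression without competing for it);
* ``background`` — independent filler genes over a wide abundance range.

Generative model, on the log2 scale: for gene g and sample s,

    log2 FPKM(g, s) = b_g + delta_g * [s is tumor] + u_{g, p(s)}
                      + a_g * f_s + eps_{g,s} - log2(fold) * [collapse]

with b_g a class-dependent baseline, delta_g the class tumor shift,
u_{g,p} a gene-specific effect shared by the two samples of patient p
(this is what makes paired T/N ratios tight), f_s a per-sample latent
factor loading only on the co-expression block, and eps idiosyncratic
noise. The block loading a_g is chosen in closed form so that the expected
within-block correlation from the latent factor alone equals
``coexpr_block_cc``; the planted collapse adds further co-variation on top.
The latent factor's scale is graded by disease stage — damped by
``lst_latent_scale`` in low-stage patients, unit scale in high-stage
adjacent normals, amplified by ``hst_latent_scale`` in high-stage tumors —
emulating the progressively looser regulation of the transport program in
advanced disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import CohortError, ExpressionMatrix, SampleInfo

__all__ = ["SyntheticConfig", "TruthLabels", "generate_cohort",
           "truth_contingency", "generate_qpcr_table", "GENE_CLASSES"]

GENE_CLASSES = ("hallmark_up", "hallmark_down", "classical_ref", "stable_ref",
                "transport_panel", "coexpr_partner", "background")

_CLASS_PREFIX = {
    "hallmark_up": "UPG", "hallmark_down": "DNG", "classical_ref": "CRG",
    "stable_ref": "SRG", "transport_panel": "TPG", "coexpr_partner": "CXG",
    "background": "BGG",
}


def _default_class_counts(n_genes_total: int) -> dict[str, int]:
    fixed = {"hallmark_up": 15, "hallmark_down": 6, "classical_ref": 21,
             "stable_ref": 42, "transport_panel": 8, "coexpr_partner": 30}
    background = n_genes_total - sum(fixed.values())
    if background < 0:
        raise CohortError(f"n_genes_total={n_genes_total} too small for default class counts")
    return {**fixed, "background": background}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic paired cohort.

    Noise magnitudes are artifact choices (no generative model is published
    for the real cohort); the defaults are fixed so that the qualitative
    behavior of the real study — stable-gene filter recovery, high-stage
    outlier enrichment, CV-dependent normalization damage — is reproducible.
    """

    n_pairs: int = 79
    high_stage_fraction: float = 53 / 79
    n_genes_total: int = 2000
    class_counts: dict[str, int] | None = None
    effect_log2fc: Mapping[str, float] = field(default_factory=lambda: {
        "hallmark_up": 1.5, "hallmark_down": -1.5, "classical_ref": 0.8})
    stable_cv_band: tuple[float, float] = (15.0, 29.0)
    stable_mean_floor: float = 100.0
    outlier_subset_size: int = 5
    outlier_fold: float = 4.0
    collapse_depth_jitter: tuple[float, float] = (1.0, 1.4)
    coexpr_block_cc: float = 0.25
    noise_sd_log2: float = 0.15
    patient_effect_sd_log2: float = 0.12
    hst_latent_scale: float = 2.5
    lst_latent_scale: float = 0.5
    seed: int = 0

    def resolved_class_counts(self) -> dict[str, int]:
        counts = self.class_counts or _default_class_counts(self.n_genes_total)
        unknown = set(counts) - set(GENE_CLASSES)
        if unknown:
            raise CohortError(f"unknown gene class(es): {sorted(unknown)}")
        counts = {c: int(counts.get(c, 0)) for c in GENE_CLASSES}
        if any(v < 0 for v in counts.values()):
            raise CohortError("class counts must be non-negative")
        if sum(counts.values()) != self.n_genes_total:
            raise CohortError(
                f"class counts sum to {sum(counts.values())}, expected {self.n_genes_total}")
        return counts

    def n_high(self) -> int:
        return int(round(self.high_stage_fraction * self.n_pairs))

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise CohortError("n_pairs must be >= 2")
        if not 0.0 <= self.high_stage_fraction <= 1.0:
            raise CohortError("high_stage_fraction must be in [0, 1]")
        if self.outlier_subset_size > self.n_high():
            raise CohortError(
                f"outlier_subset_size={self.outlier_subset_size} exceeds the "
                f"{self.n_high()} high-stage pairs")
        if not 0.0 <= self.coexpr_block_cc < 1.0:
            raise CohortError("coexpr_block_cc must be in [0, 1)")
        if self.outlier_fold <= 1.0:
            raise CohortError("outlier_fold must be > 1")
        if self.noise_sd_log2 <= 0 or self.patient_effect_sd_log2 < 0:
            raise CohortError("noise magnitudes must be positive")
        lo, hi = self.stable_cv_band
        if not 0 < lo < hi:
            raise CohortError("stable_cv_band must satisfy 0 < low < high")
        self.resolved_class_counts()


@dataclass(frozen=True)
class TruthLabels:
    """Planted ground truth emitted alongside a synthetic cohort."""

    gene_class: dict[str, str]          # gene_id -> planted class
    outlier_sample: dict[str, bool]     # sample_id -> planted collapse flag
    patient_stage: dict[str, str]       # patient_id -> stage (I-IV)

    def genes_of(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]

    @property
    def outlier_samples(self) -> list[str]:
        return [s for s, flag in self.outlier_sample.items() if flag]


def _cv_to_log2_sd(cv_fraction: float) -> float:
    """Total log2-scale SD of a log-normal with the given raw-scale CV."""
    return math.sqrt(math.log(1.0 + cv_fraction ** 2)) / math.log(2.0)


def generate_cohort(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, list[SampleInfo], TruthLabels]:
    """Sample one synthetic cohort; bit-identical for identical config+seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.resolved_class_counts()
    n_pairs, n_genes = cfg.n_pairs, cfg.n_genes_total

    # --- gene bookkeeping ---------------------------------------------------
    gene_ids: list[str] = []
    gene_class: list[str] = []
    for cls in GENE_CLASSES:
        for i in range(counts[cls]):
            gene_ids.append(f"{_CLASS_PREFIX[cls]}{i + 1:04d}")
            gene_class.append(cls)
    cls_arr = np.array(gene_class)

    # --- patients, samples, clinical labels ---------------------------------
    patients = [f"P{i + 1:03d}" for i in range(n_pairs)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(n_pairs)]
    normal_ids = [f"N{i + 1:03d}" for i in range(n_pairs)]
    sample_ids = tumor_ids + normal_ids
    n_high = cfg.n_high()
    order = rng.permutation(n_pairs)
    is_high = np.zeros(n_pairs, dtype=bool)
    is_high[order[:n_high]] = True
    # detailed stage and nodal status mirror the real cohort's proportions
    stage = np.where(is_high,
                     np.where(rng.random(n_pairs) < 2 / 3, "III", "IV"),
                     np.where(rng.random(n_pairs) < 2 / 3, "II", "I"))
    lnlv_p = np.where(is_high, 28 / 53, 2 / 26)
    ln_lv = np.where(rng.random(n_pairs) < lnlv_p, "positive", "negative")
    grade = rng.choice(["well", "moderate", "poor"], size=n_pairs,
                       p=np.array([17, 36, 26]) / 79)

    high_idx = np.flatnonzero(is_high)
    outlier_idx = rng.choice(high_idx, size=cfg.outlier_subset_size, replace=False)
    is_outlier_patient = np.zeros(n_pairs, dtype=bool)
    is_outlier_patient[outlier_idx] = True

    samples: list[SampleInfo] = []
    for tissue, ids in (("tumor", tumor_ids), ("normal", normal_ids)):
        for i, sid in enumerate(ids):
            samples.append(SampleInfo(sample_id=sid, patient_id=patients[i],
                                      tissue=tissue, stage=str(stage[i]),
                                      ln_lv=str(ln_lv[i]), grade=str(grade[i])))

    # --- per-gene generative parameters -------------------------------------
    base_var = cfg.patient_effect_sd_log2 ** 2 + cfg.noise_sd_log2 ** 2
    baseline = np.empty(n_genes)
    delta = np.zeros(n_genes)          # tumor log2 shift
    extra_sd = np.zeros(n_genes)       # gene-specific idiosyncratic SD
    fx = cfg.effect_log2fc

    def mask(cls: str) -> np.ndarray:
        return cls_arr == cls

    m = mask("hallmark_up")
    baseline[m] = rng.uniform(5.0, 8.0, m.sum())
    delta[m] = fx.get("hallmark_up", 1.5)
    extra_sd[m] = 0.25
    m = mask("hallmark_down")
    baseline[m] = rng.uniform(5.0, 8.0, m.sum())
    delta[m] = fx.get("hallmark_down", -1.5)
    extra_sd[m] = 0.25
    m = mask("classical_ref")
    nm = m.sum()
    baseline[m] = rng.uniform(7.0, 10.0, nm)
    # per-gene shifts of varying magnitude, mostly up (17 of 21 in colon);
    # class effect value is the mean magnitude of the ladder
    mag = abs(fx.get("classical_ref", 0.8))
    shift_mag = rng.uniform(max(0.25, 0.4 * mag), max(0.3, 1.6 * mag), nm)
    sign = np.where(rng.random(nm) < 17 / 21, 1.0, -1.0)
    delta[m] = sign * shift_mag
    # deterministic CV ladder from ~25% up to ~100% raw-scale CV
    extra_sd[m] = np.linspace(0.30, 1.00, nm) if nm > 1 else 0.6
    m = mask("stable_ref")
    nm = m.sum()
    baseline[m] = rng.uniform(7.5, 10.5, nm)
    lo, hi = cfg.stable_cv_band
    target_cv = rng.uniform(lo + 2.0, hi - 2.0, nm) / 100.0
    target_var = np.array([_cv_to_log2_sd(c) for c in target_cv]) ** 2
    extra_sd[m] = np.sqrt(np.maximum(target_var - base_var, 0.0))
    m = mask("transport_panel")
    baseline[m] = rng.uniform(8.0, 10.0, m.sum())
    extra_sd[m] = 0.0
    m = mask("coexpr_partner")
    baseline[m] = rng.uniform(7.0, 9.0, m.sum())
    extra_sd[m] = rng.uniform(0.32, 0.45, m.sum())
    m = mask("background")
    nm = m.sum()
    baseline[m] = rng.uniform(0.0, 9.0, nm)
    extra_sd[m] = rng.uniform(0.15, 1.20, nm)

    # latent-factor loadings: expected within-block correlation from the
    # factor alone equals coexpr_block_cc (a_g^2 = rho/(1-rho) * v_g)
    block = mask("transport_panel") | mask("coexpr_partner")
    v_g = base_var + extra_sd ** 2
    rho = cfg.coexpr_block_cc
    loading = np.zeros(n_genes)
    if rho > 0:
        loading[block] = np.sqrt(rho / (1.0 - rho) * v_g[block])

    # --- assemble the log2 matrix -------------------------------------------
    is_tumor_col = np.concatenate([np.ones(n_pairs), np.zeros(n_pairs)])
    patient_of_col = np.concatenate([np.arange(n_pairs), np.arange(n_pairs)])

    log2m = baseline[:, None] + delta[:, None] * is_tumor_col[None, :]
    pat_eff = rng.normal(0.0, cfg.patient_effect_sd_log2, size=(n_genes, n_pairs))
    log2m += pat_eff[:, patient_of_col]
    latent = rng.normal(0.0, 1.0, size=2 * n_pairs)
    latent_scale = np.where(
        is_high[patient_of_col] & (is_tumor_col == 1), cfg.hst_latent_scale,
        np.where(is_high[patient_of_col], 1.0, cfg.lst_latent_scale))
    log2m += loading[:, None] * (latent * latent_scale)[None, :]
    eps_sd = np.sqrt(cfg.noise_sd_log2 ** 2 + extra_sd ** 2)
    log2m += rng.normal(0.0, 1.0, size=(n_genes, 2 * n_pairs)) * eps_sd[:, None]
    # collapse depth is jittered beyond the nominal fold: the planted subset
    # is downregulated by MORE than outlier_fold, so the nominal fold acts
    # as the detection boundary rather than the planted center
    collapse_col = is_outlier_patient[patient_of_col]
    n_collapse = int(collapse_col.sum())
    jl, jh = cfg.collapse_depth_jitter
    if jl > jh or jl < 1.0:
        raise CohortError("collapse_depth_jitter must satisfy 1 <= low <= high")
    depth = math.log2(cfg.outlier_fold) * rng.uniform(
        jl, jh, size=(int(block.sum()), n_collapse))
    log2m[np.ix_(block, collapse_col)] -= depth

    fpkm = np.exp2(log2m)
    matrix = ExpressionMatrix(pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids))

    truth = TruthLabels(
        gene_class=dict(zip(gene_ids, gene_class)),
        outlier_sample={sid: bool(is_outlier_patient[patient_of_col[j]])
                        for j, sid in enumerate(sample_ids)},
        patient_stage=dict(zip(patients, (str(s) for s in stage))),
    )
    return matrix, samples, truth


def truth_contingency(labels: TruthLabels, calls: Mapping[str, bool]) -> np.ndarray:
    """2x2 table of planted vs called outlier status.

    Rows: planted yes / no; columns: called yes / no. Every sample carried
    by the truth labels must appear in ``calls``.
    """
    missing = [s for s in labels.outlier_sample if s not in calls]
    if missing:
        raise CohortError(f"calls missing for sample(s): {missing[:5]}")
    table = np.zeros((2, 2), dtype=int)
    for sid, planted in labels.outlier_sample.items():
        called = bool(calls[sid])
        table[0 if planted else 1, 0 if called else 1] += 1
    return table


def generate_qpcr_table(matrix: ExpressionMatrix, genes: list[str],
                        samples: list[str], *, noise_sd_ct: float = 1.0,
                        replicates: int = 3, ct_at_fpkm1: float = 33.0,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a qPCR Ct table from expression values.

    Threshold cycles scale as ``ct_at_fpkm1 - log2(FPKM)`` (one cycle per
    doubling of template) plus Gaussian measurement noise per replicate.
    Useful for exercising the ddCt / concordance stages against NGS truth.
    """
    rng = rng or np.random.default_rng(0)
    sub = matrix.subset(genes=genes, samples=samples)
    rows = []
    for g in genes:
        for s in samples:
            expr = max(sub.data.loc[g, s], 1e-6)
            base_ct = ct_at_fpkm1 - math.log2(expr)
            for r in range(1, replicates + 1):
                rows.append((g, s, r, base_ct + rng.normal(0.0, noise_sd_ct)))
    return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
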