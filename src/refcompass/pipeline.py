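"""End-to-end orchestration: simulate/load -> stats -> panel -> subtype ->
co-expression -> normalization profile, with a JSON run report.

The pipeline is deliberately linear; every stage writes its own artifact
under the output directory and the report only repeats numbers that a stage
file already contains. A frozen ``paper_defaults`` parameter profile pins
every analysis threshold (FDR 0.05, CV 30%, FPKM 100, |cc| 0.6 and 0.70,
4-fold, k=8 panels, 2 components, 90th-percentile radius).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import cohort_io, coexpr, diffstab, normsim, subtyping
from .cohort_io import CohortError
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "RunConfig", "validate_config", "run_full"]


@dataclass
class AnalysisParams:
    """Analysis thresholds; defaults form the frozen paper-defaults profile."""

    fdr_min: float = 0.05
    cv_max_percent: float = 30.0
    mean_fpkm_min: float = 100.0
    pseudocount: float = 1.0
    panel_k: int = 8
    n_components: int = 2
    radius_quantile: float = 90.0
    center: tuple[float, float] | None = None
    radius: float | None = None
    cc_threshold: float = 0.6
    rgcoex_cc_threshold: float = 0.70
    rgcoex_k: int = 8
    fold: float = 4.0
    n_norm_targets: int = 15
    norm_reference_cvs: tuple[float, ...] = (15.0, 25.0, 40.0, 55.0, 75.0)


@dataclass
class RunConfig:
    """Full pipeline configuration: exactly one input source.

    Either ``matrix_path``+``samples_path`` point at on-disk data, or
    ``synthetic`` describes a cohort to simulate.
    """

    out_dir: str | Path = "refcompass_out"
    seed: int = 0
    matrix_path: str | None = None
    samples_path: str | None = None
    synthetic: SyntheticConfig | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        par = d.pop("params", None)
        cfg = RunConfig(**{k: v for k, v in d.items()
                           if k in {f.name for f in dataclasses.fields(RunConfig)}})
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        if par is not None:
            known = {f.name for f in dataclasses.fields(AnalysisParams)}
            cfg.params = AnalysisParams(**{k: v for k, v in par.items() if k in known})
        return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns findings instead of raising."""
    findings = []
    has_paths = cfg.matrix_path is not None or cfg.samples_path is not None
    if has_paths and cfg.synthetic is not None:
        findings.append("both input paths and a synthetic block are set; pick one")
    if not has_paths and cfg.synthetic is None:
        findings.append("no input: set matrix_path/samples_path or a synthetic block")
    if has_paths and (cfg.matrix_path is None or cfg.samples_path is None):
        findings.append("matrix_path and samples_path must both be set")
    if cfg.seed < 0:
        findings.append("seed must be a non-negative integer")
    p = cfg.params
    if p.panel_k < 1 or p.rgcoex_k < 1:
        findings.append("panel sizes must be >= 1")
    if not 0 < p.radius_quantile < 100:
        findings.append("radius_quantile must lie in (0, 100)")
    if cfg.synthetic is not None:
        try:
            cfg.synthetic.validate()
        except CohortError as e:
            findings.append(f"synthetic config: {e}")
    return findings


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage and return the assembled report (also written as JSON)."""
    findings = validate_config(cfg)
    if findings:
        raise CohortError("invalid config: " + "; ".join(findings))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    stage = "input"
    try:
        if cfg.synthetic is not None:
            syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            matrix, samples, truth = generate_cohort(syn)
            cohort_io.write_expression_matrix(matrix, out / "matrix.tsv")
            cohort_io.write_sample_table(samples, out / "samples.tsv")
            (out / "truth.json").write_text(json.dumps({
                "gene_class": truth.gene_class,
                "outlier_sample": truth.outlier_sample,
                "patient_stage": truth.patient_stage,
            }, indent=1))
        else:
            matrix = cohort_io.read_expression_matrix(cfg.matrix_path)
            samples = cohort_io.read_sample_table(cfg.samples_path)
            truth = None
        pairing = cohort_io.pair_cohort(samples)
        classes = {}
        for s in samples:
            try:
                classes[s.sample_id] = cohort_io.derive_stage_class(s)
            except CohortError:
                classes[s.sample_id] = "unknown"
        tissue = {s.sample_id: s.tissue for s in samples}
        report["stages"]["input"] = {
            "n_genes": matrix.shape[0], "n_samples": matrix.shape[1],
            "n_pairs": len(pairing), "n_unpaired": len(pairing.unpaired),
        }

        stage = "gene_stats"
        stats = diffstab.gene_stats(matrix, pairing, pseudocount=p.pseudocount)
        stats.to_csv(out / "gene_stats.tsv", sep="\t", float_format="%.6g")
        filt = diffstab.CandidateFilterParams(
            fdr_min=p.fdr_min, cv_max_percent=p.cv_max_percent,
            mean_fpkm_min=p.mean_fpkm_min)
        candidates = diffstab.filter_reference_candidates(stats, filt)
        pd.Series(candidates, name="gene_id").to_csv(
            out / "candidates.tsv", sep="\t", index=False)
        report["stages"]["candidates"] = {"count": len(candidates)}

        stage = "panel"
        hst_samples = [s for s, c in classes.items() if c == "HST"]
        if len(candidates) >= p.panel_k and len(hst_samples) >= 2:
            panel = subtyping.select_high_cv_panel(
                candidates, matrix, hst_samples, k=p.panel_k)
        else:
            panel = list(candidates)
            logger.warning("panel stage degraded: %d candidate(s), %d HST sample(s)",
                           len(candidates), len(hst_samples))
        (out / "panel.txt").write_text("\n".join(panel) + ("\n" if panel else ""))
        report["stages"]["panel"] = {"genes": panel}

        stage = "subtype"
        if len(panel) >= 2:
            z = diffstab.zscore_genes(diffstab.log2_transform(
                matrix.subset(genes=panel), p.pseudocount))
            emb = subtyping.pca_embed(z, k=max(p.n_components, 2))
            emb.coords.to_csv(out / "embedding.tsv", sep="\t", float_format="%.6g")
            res = subtyping.flag_outliers(
                emb, center=p.center, radius=p.radius,
                radius_quantile=p.radius_quantile)
            flags_df = pd.DataFrame({"distance": res.distance, "outside": res.outside})
            flags_df.to_csv(out / "outliers.tsv", sep="\t", float_format="%.6g")
            table = subtyping.build_contingency(res.flags, classes)
            enr = subtyping.chi_square_enrichment(table)
            (out / "contingency.json").write_text(json.dumps(
                {"table": table.tolist(),
                 "rows": ["HST+HSN", "LST+LSN"], "cols": ["outside", "inside"]}))
            (out / "enrichment.json").write_text(json.dumps(
                {"statistic": enr.statistic, "dof": enr.dof, "p_value": enr.p_value}))
            report["stages"]["subtype"] = {
                "n_outliers": int(res.outside.sum()),
                "contingency": table.tolist(),
                "enrichment_p": enr.p_value,
            }
            if truth is not None:
                tc = subtyping.build_contingency(
                    res.flags, {s: ("HST" if f else "LST")
                                for s, f in truth.outlier_sample.items()})
                report["stages"]["subtype"]["planted_outliers_flagged"] = int(tc[0, 0])
                report["stages"]["subtype"]["planted_outliers_total"] = int(tc[0].sum())
        else:
            report["stages"]["subtype"] = {"skipped": "empty panel"}

        stage = "fold_change"
        lsn = [s for s, c in classes.items() if c == "LSN"]
        if panel and lsn:
            fc = subtyping.fold_change_flags(matrix, panel, lsn, fold=p.fold)
            counts = fc.sum(axis=0)
            counts.rename("n_genes_down").to_csv(
                out / "fold_change_counts.tsv", sep="\t")
            report["stages"]["fold_change"] = {
                "n_samples_with_majority_of_panel_down":
                    int((counts > len(fc.index) / 2).sum())}
        else:
            report["stages"]["fold_change"] = {"skipped": "no panel or no LSN baseline"}

        stage = "coexpr"
        if panel:
            coe = coexpr.coexpressed_genes(panel, matrix, cc_threshold=p.cc_threshold,
                                           pseudocount=p.pseudocount)
            coe.pairs.to_csv(out / "coexpression.tsv", sep="\t",
                             index=False, float_format="%.6g")
            rg = coexpr.select_rgcoex_panel(coe, cc_threshold=p.rgcoex_cc_threshold,
                                            k=p.rgcoex_k)
            (out / "rgcoex_panel.txt").write_text(
                "\n".join(rg.genes) + ("\n" if rg.genes else ""))
            report["stages"]["coexpr"] = {
                "n_coexpressed_pairs": int(len(coe.pairs)),
                "rgcoex_panel": list(rg.genes),
            }
        else:
            report["stages"]["coexpr"] = {"skipped": "empty panel"}

        stage = "normsim"
        report["stages"]["normsim"] = _normalization_stage(
            matrix, stats, tissue, p, out)
    except CohortError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise CohortError(f"stage {stage!r} failed: {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _normalization_stage(matrix, stats, tissue, p: AnalysisParams, out: Path):
    """CV-vs-separation profile on the most tumor-shifted targets."""
    targets = list(stats.sort_values("mean_log2_tn", ascending=False)
                   .head(p.n_norm_targets).index)
    if len(targets) < 2:
        return {"skipped": "too few target genes"}
    expressed = stats[(stats["mean_fpkm"] > 10) & stats["cv_defined"]]
    refs = [normsim.ReferenceSpec(constant=100.0, label="hypothetical")]
    for cv_target in p.norm_reference_cvs:
        pool = expressed.loc[~expressed.index.isin(targets), "cv_percent"]
        if pool.empty:
            continue
        gene = (pool - cv_target).abs().idxmin()
        if gene not in {r.genes[0] for r in refs if r.genes}:
            refs.append(normsim.ReferenceSpec(genes=(gene,)))
    try:
        profile = normsim.cv_separation_profile(matrix, targets, refs, tissue)
    except CohortError as e:
        return {"skipped": str(e)}
    profile.to_csv(out / "normalization_profile.tsv", sep="\t",
                   index=False, float_format="%.6g")
    records = profile.to_dict(orient="records")
    for rec in records:           # baseline row has no reference CV
        if pd.isna(rec["cv_percent"]):
            rec["cv_percent"] = None
    return {"profile": records}
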