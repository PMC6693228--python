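"""Cohort input/output and structural validation.

This module owns the two on-disk tables every analysis starts from:

* an expression matrix of non-negative FPKM values, genes in rows and one
  column per sample (TSV, header row, first column ``gene_id``);
* a sample metadata table with columns ``sample_id``, ``patient_id``,
  ``tissue``, ``stage``, ``ln_lv`` and ``grade``.

It also derives the cohort's pairing structure (each patient contributes at
most one tumor and one adjacent-normal sample) and the four stage classes
used throughout: LST/HST for low-stage (I-II) / high-stage (III-IV) tumors,
and LSN/HSN for the histologically normal tissue adjacent to a low-/high-
stage tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortError",
    "ExpressionMatrix",
    "SampleInfo",
    "CohortPairing",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "derive_stage_class",
    "pair_cohort",
    "LOW_STAGES",
    "HIGH_STAGES",
]


class CohortError(ValueError):
    """Raised when an input file or cohort structure violates an invariant."""


LOW_STAGES = frozenset({"I", "II"})
HIGH_STAGES = frozenset({"III", "IV"})

# Token normalization maps (case-insensitive). Anything not listed maps to
# "unknown" with a logged warning, except tissue, which must resolve.
_TISSUE_TOKENS = {
    "tumor": "tumor",
    "tumour": "tumor",
    "t": "tumor",
    "cancer": "tumor",
    "carcinoma": "tumor",
    "normal": "normal",
    "n": "normal",
    "control": "normal",
    "adjacent": "normal",
    "adjacent normal": "normal",
}
_STAGE_TOKENS = {
    "i": "I", "1": "I", "stage i": "I", "stage 1": "I",
    "ii": "II", "2": "II", "stage ii": "II", "stage 2": "II",
    "iii": "III", "3": "III", "stage iii": "III", "stage 3": "III",
    "iv": "IV", "4": "IV", "stage iv": "IV", "stage 4": "IV",
}
_LNLV_TOKENS = {
    "positive": "positive", "pos": "positive", "+": "positive", "yes": "positive",
    "negative": "negative", "neg": "negative", "-": "negative", "no": "negative",
}
_GRADE_TOKENS = {
    "well": "well", "g1": "well", "low": "well",
    "moderate": "moderate", "moderately": "moderate", "medium": "moderate", "g2": "moderate",
    "poor": "poor", "poorly": "poor", "high": "poor", "g3": "poor",
}


class ExpressionMatrix:
    """Gene x sample matrix of non-negative, finite FPKM abundances.

    Thin wrapper around a ``pandas.DataFrame`` (genes in rows) that enforces
    the container invariants once at construction: unique gene and sample
    identifiers, numeric dtype, all values finite and >= 0. Negative zero is
    normalized to plain zero so round-trips are exact.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise CohortError(f"duplicate gene id {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise CohortError(f"duplicate sample id {dup!r}")
        values = data.to_numpy(dtype=float, copy=True)
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise CohortError(
                f"non-finite value at gene {data.index[g]!r}, sample {data.columns[s]!r}"
            )
        neg = values < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise CohortError(
                f"negative value {values[g, s]} at gene {data.index[g]!r}, "
                f"sample {data.columns[s]!r}"
            )
        values = values + 0.0  # normalize -0.0 -> 0.0
        self.data = pd.DataFrame(values, index=data.index.astype(str), columns=data.columns.astype(str))
        self.data.index.name = "gene_id"

    # -- container protocol -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given genes and/or samples."""
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise CohortError(f"unknown gene id(s): {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise CohortError(f"unknown sample id(s): {missing[:5]}")
            df = df[list(samples)]
        return ExpressionMatrix(df)

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequenced sample."""

    sample_id: str
    patient_id: str
    tissue: str          # tumor | normal
    stage: str = "unknown"    # I | II | III | IV | unknown
    ln_lv: str = "unknown"    # lymph-node / lymph-vessel status
    grade: str = "unknown"    # well | moderate | poor | unknown


@dataclass(frozen=True)
class CohortPairing:
    """Complete tumor/normal pairs per patient plus excluded singletons."""

    pairs: tuple[tuple[str, str], ...]   # (tumor sample_id, normal sample_id)
    unpaired: tuple[str, ...]

    @property
    def tumor_ids(self) -> list[str]:
        return [t for t, _ in self.pairs]

    @property
    def normal_ids(self) -> list[str]:
        return [n for _, n in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression_matrix(path: str | Path, *, transposed: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (genes in rows, header row present).

    ``transposed=True`` declares that the file stores samples in rows; the
    orientation is never guessed from the contents.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transposed:
        raw = raw.T
    try:
        df = raw.astype(float)
    except ValueError:
        for s in raw.columns:
            col = pd.to_numeric(raw[s], errors="coerce")
            bad = col.isna() & raw[s].notna()
            if bad.any():
                g = raw.index[bad][0]
                raise CohortError(
                    f"non-numeric value {raw.loc[g, s]!r} at gene {g!r}, sample {s!r}"
                ) from None
        raise
    return ExpressionMatrix(df)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, 12 significant digits, first header cell gene_id."""
    m.data.to_csv(Path(path), sep="\t", float_format="%.12g", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata


def _normalize_token(raw, table: dict[str, str], field: str, sample_id: str) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    token = str(raw).strip().lower()
    if token in ("", "na", "nan", "none", "unknown", "?"):
        return "unknown"
    if token in table:
        return table[token]
    logger.warning("sample %s: unrecognized %s token %r mapped to unknown", sample_id, field, raw)
    return "unknown"


_REQUIRED_COLUMNS = ("sample_id", "patient_id", "tissue", "stage", "ln_lv", "grade")


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    """Read and validate the sample metadata table.

    Token variants (case, spelling) are normalized per the documented maps;
    anything unmapped becomes ``unknown`` with a warning. A normal sample
    with blank stage inherits the stage of its paired tumor, since the
    adjacent-normal stage class is defined by the tumor's stage. Conflicting
    tumor/normal stages for one patient are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"sample table missing column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        sid = str(row.sample_id).strip()
        tissue_tok = str(row.tissue).strip().lower()
        if tissue_tok not in _TISSUE_TOKENS:
            raise CohortError(f"sample {sid!r}: unrecognized tissue {row.tissue!r}")
        records.append(SampleInfo(
            sample_id=sid,
            patient_id=str(row.patient_id).strip(),
            tissue=_TISSUE_TOKENS[tissue_tok],
            stage=_normalize_token(row.stage, _STAGE_TOKENS, "stage", sid),
            ln_lv=_normalize_token(row.ln_lv, _LNLV_TOKENS, "ln_lv", sid),
            grade=_normalize_token(row.grade, _GRADE_TOKENS, "grade", sid),
        ))
    return validate_samples(records)


def validate_samples(records: list[SampleInfo]) -> list[SampleInfo]:
    """Enforce per-patient invariants; fill blank normal stages from tumors."""
    seen_ids: set[str] = set()
    by_patient: dict[str, dict[str, SampleInfo]] = {}
    for r in records:
        if r.sample_id in seen_ids:
            raise CohortError(f"duplicate sample id {r.sample_id!r}")
        seen_ids.add(r.sample_id)
        slot = by_patient.setdefault(r.patient_id, {})
        if r.tissue in slot:
            raise CohortError(
                f"patient {r.patient_id!r} has more than one {r.tissue} sample"
            )
        slot[r.tissue] = r

    out = []
    for r in records:
        slot = by_patient[r.patient_id]
        if "tumor" in slot and "normal" in slot:
            t, n = slot["tumor"], slot["normal"]
            if n.stage == "unknown" and t.stage != "unknown" and r.tissue == "normal":
                r = replace(r, stage=t.stage)
            elif t.stage != n.stage and "unknown" not in (t.stage, n.stage):
                raise CohortError(
                    f"patient {r.patient_id!r}: tumor stage {t.stage} conflicts "
                    f"with normal stage {n.stage}"
                )
        out.append(r)
    return out


def write_sample_table(samples: Iterable[SampleInfo], path: str | Path) -> None:
    df = pd.DataFrame([s.__dict__ for s in samples], columns=list(_REQUIRED_COLUMNS))
    df.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# stage classes and pairing


def derive_stage_class(s: SampleInfo) -> str:
    """Map a sample to one of the four stage classes LST/HST/LSN/HSN.

    Tumors of stage I-II are LST, III-IV are HST; the adjacent normal
    inherits L/H from its tumor's stage (LSN/HSN).
    """
    if s.stage not in LOW_STAGES | HIGH_STAGES:
        raise CohortError(f"sample {s.sample_id!r}: stage-class undefined (stage={s.stage!r})")
    level = "L" if s.stage in LOW_STAGES else "H"
    suffix = "ST" if s.tissue == "tumor" else "SN"
    return level + suffix


def pair_cohort(samples: Sequence[SampleInfo]) -> CohortPairing:
    """List complete tumor/normal pairs; report incomplete patients as unpaired."""
    by_patient: dict[str, dict[str, SampleInfo]] = {}
    for r in samples:
        by_patient.setdefault(r.patient_id, {})[r.tissue] = r
    pairs, unpaired = [], []
    for pid in sorted(by_patient):
        slot = by_patient[pid]
        if "tumor" in slot and "normal" in slot:
            pairs.append((slot["tumor"].sample_id, slot["normal"].sample_id))
        else:
            unpaired.extend(s.sample_id for s in slot.values())
    if unpaired:
        logger.warning("%d sample(s) without a complete tumor/normal pair: %s",
                       len(unpaired), unpaired[:10])
    return CohortPairing(pairs=tuple(pairs), unpaired=tuple(unpaired))
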