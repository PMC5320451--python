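"""Metabolite exclusion rules and QC2-based between-batch normalization.

A targeted panel reports many analytes that are not reliably quantifiable
in a given matrix.  Following standard kit practice, a metabolite is
dropped when more than a fixed fraction of study samples fall outside its
quantifiable range (below LOD, below LLOQ, above ULOQ), when the blank
wells carry signal above LOD, or when the mid-level QC sample (QC2)
replicated on every plate is too variable (CV above a cutoff).  Surviving
metabolites are then normalized between plates using the QC2 repeats.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ConcentrationTable, ValidationError

FLAG_BELOW_LOD = "below_lod"
FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_ULOQ = "above_uloq"
FLAG_IN_RANGE = "in_range"
FLAG_MISSING = "missing"

OUT_OF_RANGE_FLAGS = (FLAG_BELOW_LOD, FLAG_BELOW_LLOQ, FLAG_ABOVE_ULOQ)

REASON_OUT_OF_RANGE = "out_of_range_fraction"
REASON_QC2_CV = "qc2_cv"
REASON_BLANK = "blank_out_of_range"


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Exclusion cutoffs: out-of-range fraction and QC2 CV, both in [0,1]."""

    max_out_of_range_fraction: float = 0.25
    max_qc2_cv: float = 0.30

    def __post_init__(self) -> None:
        for name in ("max_out_of_range_fraction", "max_qc2_cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclasses.dataclass
class ExclusionReport:
    retained: list[str]
    excluded: dict[str, str]  # abbreviation -> reason

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.excluded):
            raise ValidationError("retained and excluded sets overlap")

    def as_frame(self) -> pd.DataFrame:
        rows = [{"abbreviation": m, "status": "retained", "reason": ""} for m in self.retained]
        rows += [
            {"abbreviation": m, "status": "excluded", "reason": r}
            for m, r in self.excluded.items()
        ]
        return pd.DataFrame(rows)


def flag_out_of_range(values, annotation_row) -> list[str]:
    """Flag each value against the metabolite's quantification limits.

    Boundary convention follows the strict assay inequalities: a value
    strictly below LOD is ``below_lod``; a value equal to LOD (or between
    LOD and LLOQ) is ``below_lloq``; only values strictly above ULOQ are
    ``above_uloq``.  Missing values flag as ``missing``.
    """
    lod = float(annotation_row["lod"])
    lloq = float(annotation_row["lloq"])
    uloq = float(annotation_row["uloq"])
    flags = []
    for v in np.asarray(values, dtype=float):
        if np.isnan(v):
            flags.append(FLAG_MISSING)
        elif v < lod:
            flags.append(FLAG_BELOW_LOD)
        elif v < lloq:
            flags.append(FLAG_BELOW_LLOQ)
        elif v > uloq:
            flags.append(FLAG_ABOVE_ULOQ)
        else:
            flags.append(FLAG_IN_RANGE)
    return flags


def qc2_cv_stats(table: ConcentrationTable) -> dict[str, float]:
    """Per-metabolite coefficient of variation across all QC2 wells."""
    qc2 = table.values.loc[(table.samples["sample_type"] == "QC2").to_numpy()]
    if qc2.empty:
        raise ValidationError("table contains no QC2 samples")
    mean = qc2.mean(axis=0, skipna=True)
    sd = qc2.std(axis=0, ddof=1, skipna=True)
    cv = sd / mean.where(mean != 0, np.nan)
    return {m: float(cv[m]) for m in qc2.columns}


def _blank_out_of_range(table: ConcentrationTable, abbreviation: str, lod: float) -> bool:
    blanks = table.values.loc[(table.samples["sample_type"] == "blank").to_numpy(), abbreviation]
    if blanks.dropna().empty:
        return False
    return bool(blanks.mean(skipna=True) > lod)


def exclude_metabolites(
    table: ConcentrationTable,
    thresholds: QCThresholds | None = None,
    qc2_stats: Mapping[str, float] | None = None,
) -> ExclusionReport:
    """Apply the panel exclusion rules.

    A metabolite is excluded iff the fraction of *study* samples flagged
    out of range (below LOD, below LLOQ, or above ULOQ, pooled) exceeds
    ``max_out_of_range_fraction``, or its blank wells average above LOD,
    or its QC2 CV exceeds ``max_qc2_cv``.  The first matching rule, in that
    order, is recorded as the reason.  QC and blank wells never count
    toward the out-of-range fraction.
    """
    thresholds = thresholds or QCThresholds()
    if qc2_stats is None:
        qc2_stats = qc2_cv_stats(table)
    study = table.study_values()
    if study.empty:
        raise ValidationError("no study samples in table")
    missing = set(table.annotation["abbreviation"]) - set(qc2_stats)
    if missing:
        raise ValidationError(f"qc2_stats missing metabolite(s): {sorted(missing)}")

    retained: list[str] = []
    excluded: dict[str, str] = {}
    for _, ann in table.annotation.iterrows():
        m = ann["abbreviation"]
        flags = flag_out_of_range(study[m].to_numpy(), ann)
        n_scored = sum(f != FLAG_MISSING for f in flags)
        n_oor = sum(f in OUT_OF_RANGE_FLAGS for f in flags)
        frac = n_oor / n_scored if n_scored else 0.0
        if frac > thresholds.max_out_of_range_fraction:
            excluded[m] = REASON_OUT_OF_RANGE
        elif _blank_out_of_range(table, m, float(ann["lod"])):
            excluded[m] = REASON_BLANK
        elif qc2_stats[m] > thresholds.max_qc2_cv:
            excluded[m] = REASON_QC2_CV
        else:
            retained.append(m)
    return ExclusionReport(retained=retained, excluded=excluded)


def qc2_normalize(
    table: ConcentrationTable,
) -> tuple[ConcentrationTable, pd.DataFrame]:
    """Normalize concentrations between plates using QC2 repeats.

    The per-plate correction factor for a metabolite is
    ``target / plate_QC2_mean`` where the global target is the median of
    the per-plate QC2 means (robust to one bad plate).  Every value on the
    plate — study and QC wells alike — is multiplied by the factor, so the
    operation is idempotent and post-normalization QC2 plate means agree.

    Returns the normalized table and a (plate x metabolite) factor frame.
    """
    samples = table.samples
    is_qc2 = (samples["sample_type"] == "QC2").to_numpy()
    plates = sorted(samples["plate_id"].unique())
    for plate in plates:
        on_plate = (samples["plate_id"] == plate).to_numpy()
        if (on_plate & is_qc2).sum() < 2:
            raise ValidationError(f"plate {plate!r} has fewer than 2 QC2 samples")

    qc2_means = pd.DataFrame(index=plates, columns=table.values.columns, dtype=float)
    for plate in plates:
        sel = ((samples["plate_id"] == plate).to_numpy()) & is_qc2
        qc2_means.loc[plate] = table.values.loc[sel].mean(axis=0, skipna=True)
    if (qc2_means == 0).any().any() or qc2_means.isna().any().any():
        bad = qc2_means.columns[((qc2_means == 0) | qc2_means.isna()).any()].tolist()
        raise ValidationError(f"QC2 plate mean zero/undefined for {bad}")
    target = qc2_means.median(axis=0)
    factors = target / qc2_means  # plate x metabolite

    values = table.values.copy()
    for plate in plates:
        on_plate = (samples["plate_id"] == plate).to_numpy()
        values.loc[on_plate] = values.loc[on_plate].mul(factors.loc[plate], axis=1)
    out = ConcentrationTable(samples.copy(), table.annotation.copy(), values)
    factors.index.name = "plate_id"
    return out, factors
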