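"""Domain types and tabular I/O shared by every pipeline stage.

The central object is :class:`ConcentrationTable`: a sample x metabolite
matrix of plasma concentrations (uM) with per-sample metadata (sheep,
genotype, clock time, plate, well type) and a per-metabolite annotation
(compound class and assay quantification limits).  All files are plain
comma-separated text with one header row; missing values are empty fields.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

METABOLITE_CLASSES = (
    "amino_acid",
    "biogenic_amine",
    "acylcarnitine",
    "lysoPC",
    "PC_aa",
    "PC_ae",
    "sphingolipid",
)

GENOTYPES = ("control", "HD")

SAMPLE_TYPES = ("study", "QC1", "QC2", "QC3", "blank")

#: metadata columns of a concentration file, in canonical order
METADATA_COLUMNS = (
    "sample_id",
    "sheep_id",
    "genotype",
    "clock_time",
    "sampling_index",
    "plate_id",
    "sample_type",
)

ANNOTATION_COLUMNS = (
    "name",
    "abbreviation",
    "metabolite_class",
    "lod",
    "lloq",
    "uloq",
    "flags",
)


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates an invariant."""


def genotype_code(genotype: Iterable[str]) -> np.ndarray:
    """Code genotype control=0, HD=1 (HD is the positive class in ROC terms)."""
    arr = np.asarray(list(genotype), dtype=object)
    bad = set(arr) - set(GENOTYPES)
    if bad:
        raise ValidationError(f"unknown genotype value(s): {sorted(bad)}")
    return (arr == "HD").astype(int)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.copy()
    missing = set(ANNOTATION_COLUMNS[:-1]) - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
    if "flags" not in ann.columns:
        ann["flags"] = ""
    ann["flags"] = ann["flags"].fillna("")
    if ann["abbreviation"].duplicated().any():
        dups = ann.loc[ann["abbreviation"].duplicated(), "abbreviation"].tolist()
        raise ValidationError(f"duplicate metabolite abbreviation(s): {dups}")
    bad_class = set(ann["metabolite_class"]) - set(METABOLITE_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown metabolite class(es): {sorted(bad_class)}")
    for col in ("lod", "lloq", "uloq"):
        ann[col] = pd.to_numeric(ann[col])
    if (ann["lod"] < 0).any() or (ann["lloq"] < 0).any():
        raise ValidationError("LOD/LLOQ must be non-negative")
    if not ((ann["lod"] <= ann["lloq"]) & (ann["lloq"] < ann["uloq"])).all():
        bad = ann.loc[
            ~((ann["lod"] <= ann["lloq"]) & (ann["lloq"] < ann["uloq"])),
            "abbreviation",
        ].tolist()
        raise ValidationError(f"require lod <= lloq < uloq; violated by {bad}")
    return ann.reset_index(drop=True)


@dataclasses.dataclass
class ConcentrationTable:
    """Sample x metabolite concentration matrix with metadata.

    Attributes
    ----------
    samples : DataFrame
        One row per sample, columns :data:`METADATA_COLUMNS`.  QC and blank
        wells have an empty ``sheep_id``/``genotype``.
    annotation : DataFrame
        One row per metabolite, columns :data:`ANNOTATION_COLUMNS`; order
        matches the columns of ``values``.
    values : DataFrame
        Concentrations in uM, index = ``sample_id``, columns = metabolite
        abbreviations, NaN = missing.
    """

    samples: pd.DataFrame
    annotation: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.annotation = validate_annotation(self.annotation)
        samples = self.samples.reset_index(drop=True).copy()
        missing = set(METADATA_COLUMNS) - set(samples.columns)
        if missing:
            raise ValidationError(f"sample metadata missing column(s): {sorted(missing)}")
        if samples["sample_id"].duplicated().any():
            dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        bad_type = set(samples["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValidationError(f"unknown sample_type(s): {sorted(bad_type)}")
        study = samples["sample_type"] == "study"
        if (study & (samples["sheep_id"].fillna("") == "")).any():
            raise ValidationError("study samples must carry a sheep_id")
        geno = samples.loc[study, "genotype"]
        bad_geno = set(geno) - set(GENOTYPES)
        if bad_geno:
            raise ValidationError(f"unknown genotype(s): {sorted(bad_geno)}")
        samples["clock_time"] = samples["clock_time"].astype(float)
        samples["sampling_index"] = samples["sampling_index"].astype(int)
        self.samples = samples

        values = self.values.copy()
        abbr = list(self.annotation["abbreviation"])
        if list(values.columns) != abbr:
            extra = set(values.columns) - set(abbr)
            lacking = set(abbr) - set(values.columns)
            if extra or lacking:
                raise ValidationError(
                    f"value columns do not match annotation: extra={sorted(extra)}, "
                    f"missing={sorted(lacking)}"
                )
            values = values[abbr]
        values.index = pd.Index(samples["sample_id"], name="sample_id")
        values = values.astype(float)
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative concentrations are not allowed")
        self.values = values

    # -- convenience accessors -------------------------------------------------

    @property
    def study_mask(self) -> pd.Series:
        return (self.samples["sample_type"] == "study").reset_index(drop=True)

    def study_samples(self) -> pd.DataFrame:
        return self.samples.loc[self.study_mask.to_numpy()].reset_index(drop=True)

    def study_values(self) -> pd.DataFrame:
        return self.values.loc[self.study_mask.to_numpy()]

    def missing_fraction(self) -> float:
        """Fraction of missing cells among study samples."""
        vals = self.study_values().to_numpy()
        if vals.size == 0:
            return 0.0
        return float(np.isnan(vals).sum() / vals.size)

    def subset_metabolites(self, abbreviations: Iterable[str]) -> "ConcentrationTable":
        keep = list(abbreviations)
        unknown = set(keep) - set(self.annotation["abbreviation"])
        if unknown:
            raise ValidationError(f"unknown metabolite(s): {sorted(unknown)}")
        ann = self.annotation.set_index("abbreviation").loc[keep].reset_index()
        ann = ann[list(ANNOTATION_COLUMNS)]
        return ConcentrationTable(self.samples.copy(), ann, self.values[keep].copy())

    def copy(self) -> "ConcentrationTable":
        return ConcentrationTable(
            self.samples.copy(), self.annotation.copy(), self.values.copy()
        )


@dataclasses.dataclass(frozen=True)
class CohortDesign:
    """Sheep counts and per-sheep sampling depth of a study cohort."""

    n_control: int
    n_hd: int
    timepoints_per_sheep: int

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_hd, self.timepoints_per_sheep) < 1:
            raise ValidationError("cohort design fields must be positive")

    def check(self, table: ConcentrationTable) -> None:
        study = table.study_samples()
        by_geno = study.drop_duplicates("sheep_id").groupby("genotype")["sheep_id"].count()
        if int(by_geno.get("control", 0)) != self.n_control or int(
            by_geno.get("HD", 0)
        ) != self.n_hd:
            raise ValidationError(
                f"sheep counts {dict(by_geno)} do not match design "
                f"({self.n_control} control / {self.n_hd} HD)"
            )
        per_sheep = study.groupby("sheep_id")["sample_id"].count()
        if not (per_sheep == self.timepoints_per_sheep).all():
            raise ValidationError("per-sheep sample counts do not match design")


# -- file I/O ------------------------------------------------------------------


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype={"flags": str}, keep_default_na=False, na_values=[""])
    return validate_annotation(ann)


def read_concentration_table(
    path: str | Path, annotation_path: str | Path
) -> ConcentrationTable:
    """Read a wide concentration CSV plus its metabolite annotation.

    Empty cells become missing values; negative concentrations and duplicate
    sample ids are rejected.  Metabolite columns absent from the annotation
    raise a :class:`ValidationError` naming the column.
    """
    annotation = read_annotation(annotation_path)
    raw = pd.read_csv(path, dtype={"sample_id": str, "sheep_id": str, "plate_id": str})
    missing_meta = set(METADATA_COLUMNS) - set(raw.columns)
    if missing_meta:
        raise ValidationError(f"concentration file missing column(s): {sorted(missing_meta)}")
    meta_cols = list(METADATA_COLUMNS) + (
        ["phase_offset"] if "phase_offset" in raw.columns else []
    )
    value_cols = [c for c in raw.columns if c not in meta_cols]
    known = set(annotation["abbreviation"])
    for col in value_cols:
        if col not in known:
            raise ValidationError(f"metabolite column {col!r} absent from annotation")
    samples = raw[meta_cols].copy()
    samples["sheep_id"] = samples["sheep_id"].fillna("")
    samples["genotype"] = samples["genotype"].fillna("")
    ann = annotation.set_index("abbreviation").loc[value_cols].reset_index()
    ann = ann[list(ANNOTATION_COLUMNS)]
    values = raw[value_cols]
    return ConcentrationTable(samples, ann, values)


def write_concentration_table(table: ConcentrationTable, path: str | Path,
                              annotation_path: str | Path | None = None) -> None:
    wide = pd.concat(
        [table.samples.reset_index(drop=True), table.values.reset_index(drop=True)],
        axis=1,
    )
    wide.to_csv(path, index=False, float_format="%.10g")
    if annotation_path is not None:
        table.annotation.to_csv(annotation_path, index=False, float_format="%.10g")


#: float format used by write_results_table; stated in the file header comment
RESULTS_FLOAT_FORMAT = "%.10g"


def write_results_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with a precision header comment.

    Raises on an empty table (no file is created).
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    if rows.empty:
        raise ValidationError("refusing to write an empty results table")
    buf = io.StringIO()
    buf.write(f"# floats formatted {RESULTS_FLOAT_FORMAT}\n")
    rows.to_csv(buf, index=False, float_format=RESULTS_FLOAT_FORMAT)
    Path(path).write_text(buf.getvalue())


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
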