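"""Packaged machine-readable copy of the published per-metabolite screen.

``table1.csv`` is a transcription of the published 130-metabolite ANOVA
summary: genotype / time-of-day / interaction FDR values plus 24 h group
means (+/- SEM, uM) for the 10 control and 14 HD transgenic sheep.  It
serves two roles: the reference input for the class/direction tabulation,
and the effect-size source for the "paperlike" synthetic cohort preset.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import validate_annotation

_NUMERIC = [
    "fdr_genotype",
    "fdr_time",
    "fdr_interaction",
    "control_mean",
    "control_sem",
    "hd_mean",
    "hd_sem",
]


def reference_screen_table() -> pd.DataFrame:
    """The packaged 130-row screen table (FDRs and group means)."""
    with resources.files("hdsheep.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"flags": str}, keep_default_na=False, na_values=[""])
    df["flags"] = df["flags"].fillna("")
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col])
    df = df.rename(columns={"name": "metabolite"})
    return df


def reference_annotation() -> pd.DataFrame:
    """Annotation for the 130-metabolite panel, with synthetic assay limits.

    The published table reports no quantification limits, so nominal limits
    are attached relative to each metabolite's control mean (LOD = mean/50,
    LLOQ = mean/25, ULOQ = mean*50); they are labelled synthetic and only
    exercise the QC plumbing on generated data.
    """
    df = reference_screen_table()
    ann = pd.DataFrame(
        {
            "name": df["metabolite"],
            "abbreviation": df["abbreviation"],
            "metabolite_class": df["metabolite_class"],
            "lod": df["control_mean"] / 50.0,
            "lloq": df["control_mean"] / 25.0,
            "uloq": df["control_mean"] * 50.0,
            "flags": df["flags"],
        }
    )
    return validate_annotation(ann)
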