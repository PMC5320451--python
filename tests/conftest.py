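import numpy as np
import pandas as pd
import pytest

from hdsheep.data_model import ConcentrationTable


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": ["Citrulline", "Arginine"],
            "abbreviation": ["Cit", "Arg"],
            "metabolite_class": ["amino_acid", "amino_acid"],
            "lod": [0.2, 0.2],
            "lloq": [0.4, 0.4],
            "uloq": [1000.0, 1000.0],
            "flags": ["", ""],
        }
    )


@pytest.fixture
def tiny_table(tiny_annotation) -> ConcentrationTable:
    """4 study samples x 2 metabolites with one missing cell."""
    samples = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4"],
            "sheep_id": ["A", "A", "B", "B"],
            "genotype": ["control", "control", "HD", "HD"],
            "clock_time": [15.0, 17.0, 15.0, 17.0],
            "sampling_index": [0, 1, 0, 1],
            "plate_id": ["P1", "P1", "P1", "P1"],
            "sample_type": ["study"] * 4,
        }
    )
    values = pd.DataFrame(
        {"Cit": [1.0, 2.0, 3.0, np.nan], "Arg": [2.0, 2.0, 1.0, 1.5]}
    )
    return ConcentrationTable(samples, tiny_annotation, values)


def make_cohort_table(
    n_control: int,
    n_hd: int,
    timepoints: int,
    values_fn,
    annotation: pd.DataFrame,
    n_plates: int = 1,
) -> ConcentrationTable:
    """Build a study-only cohort table; values_fn(sheep_idx, genotype, t, rng-free)."""
    rows, vals = [], []
    sheep = [("control", f"C{i}") for i in range(n_control)] + [
        ("HD", f"H{i}") for i in range(n_hd)
    ]
    for si, (geno, sid) in enumerate(sheep):
        for t in range(timepoints):
            rows.append(
                {
                    "sample_id": f"{sid}_T{t}",
                    "sheep_id": sid,
                    "genotype": geno,
                    "clock_time": (15.0 + 2 * t) % 24.0,
                    "sampling_index": t,
                    "plate_id": f"P{(si * timepoints + t) % n_plates + 1}",
                    "sample_type": "study",
                }
            )
            vals.append(values_fn(si, geno, t))
    values = pd.DataFrame(vals, columns=annotation["abbreviation"])
    return ConcentrationTable(pd.DataFrame(rows), annotation, values)
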