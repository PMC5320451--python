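"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The study design it emulates: 24 rams (10 control, 14 HD transgenic),
two-hourly plasma samples over 25 h (13 time points, 15:00-15:00), a
130-metabolite targeted panel in six compound classes run on 5 plates
with 4 mid-level QC (QC2) wells each, hourly melatonin profiles, and
<1.2% missingness.  Concentrations follow a two-level lognormal model:

    value = group_mean x sheep_factor x cosinor x residual x plate_bias

with mean-preserving lognormal sheep (between-animal CV) and residual
(within-animal CV) factors and a cosinor term
``1 + A cos(2*pi*(t - DLMO - peak_offset)/24)`` phased to each sheep's
dim-light melatonin onset (DLMO ~ Normal(21.0, 0.9) h).  The "paperlike"
preset takes group means from the packaged published screen table and
derives per-metabolite CVs from its SEMs, so the simulated effect sizes
match the published cohort under the pooled-sample reading.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ConcentrationTable, ValidationError, validate_annotation
from .circadian import MelatoninProfile
from .reference import reference_screen_table

#: the eight published panel markers, used by the paperlike marker preset
PANEL_MARKERS = (
    "Cit",
    "Val",
    "PC aa C40:4",
    "PC aa C36:5",
    "lysoPC a C17:0",
    "SM (OH) C24:1",
    "Thr",
    "C14:1",
)


@dataclasses.dataclass
class SyntheticConfig:
    """Full parameterization of a simulated cohort.

    ``effect_table`` has one row per metabolite: abbreviation,
    metabolite_class, control_mean, hd_mean (uM), cv_between_sheep,
    cv_within_sheep.  ``rhythm`` maps abbreviation -> (relative amplitude
    in [0,1), peak offset in hours after DLMO).
    """

    effect_table: pd.DataFrame
    seed: int
    n_control: int = 10
    n_hd: int = 14
    timepoints: int = 13
    start_clock_time: float = 15.0
    sampling_interval_h: float = 2.0
    rhythm: Mapping[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    dlmo_mean: float = 21.0
    dlmo_sd: float = 0.9
    missing_rate: float = 0.012
    n_plates: int = 5
    qc2_per_plate: int = 4
    plate_bias_sd: float = 0.03
    qc2_noise_cv: float = 0.03
    melatonin_plateau: float = 100.0
    melatonin_floor: float = 3.9  # assay detection limit, pg/ml
    melatonin_noise_cv: float = 0.10
    melatonin_rise_tau: float = 0.5
    melatonin_duration: float = 9.0
    ar1_within: float = 0.0  # optional within-sheep autocorrelation, off by default

    def __post_init__(self) -> None:
        problems = []
        req = {"abbreviation", "control_mean", "hd_mean", "cv_between_sheep", "cv_within_sheep"}
        missing = req - set(self.effect_table.columns)
        if missing:
            problems.append(f"effect_table missing columns {sorted(missing)}")
        else:
            if (self.effect_table[["control_mean", "hd_mean"]] <= 0).any().any():
                problems.append("group means must be positive")
            cvs = self.effect_table[["cv_between_sheep", "cv_within_sheep"]]
            if ((cvs < 0) | (cvs >= 1)).any().any():
                problems.append("CVs must lie in [0,1)")
        for name in ("missing_rate",):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                problems.append(f"{name} must be in [0,1)")
        for abbr, (amp, _) in dict(self.rhythm).items():
            if not 0.0 <= amp < 1.0:
                problems.append(f"rhythm amplitude for {abbr} must be in [0,1)")
        if min(self.n_control, self.n_hd, self.timepoints, self.n_plates) < 1:
            problems.append("counts must be positive")
        if self.seed is None:
            problems.append("seed is mandatory")
        if problems:
            raise ValidationError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclasses.dataclass
class GeneratedCohort:
    concentrations: ConcentrationTable
    melatonin: list[MelatoninProfile]
    truth: dict  # true_effect flags, true DLMO per sheep, plate factors


def _lognormal_factor(rng: np.random.Generator, cv: np.ndarray, size: tuple) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV (broadcast)."""
    cv = np.asarray(cv, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(size)
    return np.exp(z * sigma - sigma**2 / 2.0)


def _default_annotation(effect: pd.DataFrame) -> pd.DataFrame:
    has_class = "metabolite_class" in effect.columns
    ann = pd.DataFrame(
        {
            "name": effect.get("name", effect["abbreviation"]),
            "abbreviation": effect["abbreviation"],
            "metabolite_class": effect["metabolite_class"] if has_class else "amino_acid",
            "lod": effect.get("lod", effect["control_mean"] / 50.0),
            "lloq": effect.get("lloq", effect["control_mean"] / 25.0),
            "uloq": effect.get("uloq", effect["control_mean"] * 50.0),
            "flags": effect.get("flags", ""),
        }
    )
    return validate_annotation(ann)


def generate_cohort(config: SyntheticConfig) -> GeneratedCohort:
    """Simulate concentrations, QC wells, melatonin profiles and truth labels."""
    rng = np.random.default_rng(config.seed)
    effect = config.effect_table.reset_index(drop=True)
    annotation = _default_annotation(effect)
    abbr = list(effect["abbreviation"])
    n_met = len(abbr)

    sheep_ids = [f"C{i+1:02d}" for i in range(config.n_control)] + [
        f"H{i+1:02d}" for i in range(config.n_hd)
    ]
    genotypes = ["control"] * config.n_control + ["HD"] * config.n_hd
    n_sheep = len(sheep_ids)
    true_dlmo = rng.normal(config.dlmo_mean, config.dlmo_sd, n_sheep)

    # unwrapped sampling times shared by all sheep (15:00 ... 15:00 next day)
    t_unwrapped = config.start_clock_time + config.sampling_interval_h * np.arange(
        config.timepoints
    )

    group_mean = np.where(
        np.array(genotypes)[:, None] == "HD",
        effect["hd_mean"].to_numpy()[None, :],
        effect["control_mean"].to_numpy()[None, :],
    )  # sheep x metabolite

    sheep_factor = _lognormal_factor(
        rng, effect["cv_between_sheep"].to_numpy()[None, :], (n_sheep, n_met)
    )

    amp = np.zeros(n_met)
    peak = np.zeros(n_met)
    rhythm = dict(config.rhythm)
    for j, m in enumerate(abbr):
        if m in rhythm:
            amp[j], peak[j] = rhythm[m]
    cos_term = 1.0 + amp[None, None, :] * np.cos(
        2.0
        * np.pi
        * (t_unwrapped[None, :, None] - true_dlmo[:, None, None] - peak[None, None, :])
        / 24.0
    )  # sheep x time x metabolite

    cv_w = effect["cv_within_sheep"].to_numpy()
    resid = _lognormal_factor(rng, cv_w[None, None, :], (n_sheep, config.timepoints, n_met))
    if config.ar1_within > 0:
        rho = config.ar1_within
        logr = np.log(resid)
        for k in range(1, config.timepoints):
            logr[:, k, :] = rho * logr[:, k - 1, :] + np.sqrt(1 - rho**2) * logr[:, k, :]
        resid = np.exp(logr)

    values = (
        group_mean[:, None, :] * sheep_factor[:, None, :] * cos_term * resid
    )  # sheep x time x metabolite

    # plate structure: study samples assigned round-robin in randomized order
    n_study = n_sheep * config.timepoints
    plate_ids = [f"P{p+1}" for p in range(config.n_plates)]
    plate_bias = _lognormal_factor(
        rng, np.full(n_met, config.plate_bias_sd)[None, :], (config.n_plates, n_met)
    )
    order = rng.permutation(n_study)
    plate_of_sample = np.empty(n_study, dtype=int)
    plate_of_sample[order] = np.arange(n_study) % config.n_plates

    flat = values.reshape(n_study, n_met) * plate_bias[plate_of_sample]

    # LOD censoring: cells below LOD substituted at LOD/2 (still observable
    # to the QC flagging stage, unlike outright deletion)
    lod = annotation["lod"].to_numpy()
    flat = np.where(flat < lod[None, :], lod[None, :] / 2.0, flat)

    # uniform missingness
    miss = rng.random((n_study, n_met)) < config.missing_rate
    flat[miss] = np.nan

    meta_rows = []
    k = 0
    for i, sid in enumerate(sheep_ids):
        for ti in range(config.timepoints):
            meta_rows.append(
                {
                    "sample_id": f"{sid}_T{ti:02d}",
                    "sheep_id": sid,
                    "genotype": genotypes[i],
                    "clock_time": float(t_unwrapped[ti] % 24.0),
                    "sampling_index": ti,
                    "plate_id": plate_ids[plate_of_sample[k]],
                    "sample_type": "study",
                }
            )
            k += 1

    # QC2 wells: nominal value per metabolite (control mean) x plate bias x noise
    nominal = effect["control_mean"].to_numpy()
    qc_rows, qc_vals = [], []
    for p, pid in enumerate(plate_ids):
        for r in range(config.qc2_per_plate):
            qc_rows.append(
                {
                    "sample_id": f"QC2_{pid}_{r+1}",
                    "sheep_id": "",
                    "genotype": "",
                    "clock_time": 0.0,
                    "sampling_index": 0,
                    "plate_id": pid,
                    "sample_type": "QC2",
                }
            )
            qc_vals.append(
                nominal
                * plate_bias[p]
                * _lognormal_factor(rng, np.full(n_met, config.qc2_noise_cv), (n_met,))
            )

    samples = pd.DataFrame(meta_rows + qc_rows)
    all_vals = np.vstack([flat, np.array(qc_vals)])
    table = ConcentrationTable(samples, annotation, pd.DataFrame(all_vals, columns=abbr))

    melatonin = generate_melatonin(config, dict(zip(sheep_ids, true_dlmo)))

    truth = {
        "true_effect": {
            m: bool(c != h)
            for m, c, h in zip(abbr, effect["control_mean"], effect["hd_mean"])
        },
        "true_dlmo": {s: float(d) for s, d in zip(sheep_ids, true_dlmo)},
        "plate_factors": pd.DataFrame(plate_bias, index=plate_ids, columns=abbr),
    }
    return GeneratedCohort(table, melatonin, truth)


def generate_melatonin(
    config: SyntheticConfig, true_dlmo: Mapping[str, float]
) -> list[MelatoninProfile]:
    """Hourly melatonin profiles with a sigmoidal onset at each true DLMO.

    The rising logistic is positioned, per sheep, so that the noiseless
    hourly profile's interpolated 25%-of-peak crossing falls exactly at the
    true DLMO (the onset centre is solved by bisection, absorbing the assay
    floor and the curvature of the sigmoid between hourly samples).  A
    second logistic ends the nocturnal plateau ``melatonin_duration`` hours
    later.  Additive assay noise with SD ``melatonin_noise_cv`` x value is
    applied and values below the assay floor are reported at the floor.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    t = 14.0 + np.arange(26)  # hourly, 14:00 to 15:00 next day (25 h window)
    tau = config.melatonin_rise_tau
    floor, plateau = config.melatonin_floor, config.melatonin_plateau

    def clean_profile(dlmo: float, centre: float) -> np.ndarray:
        rise = 1.0 / (1.0 + np.exp(-(t - centre) / tau))
        fall = 1.0 / (1.0 + np.exp((t - (dlmo + config.melatonin_duration)) / 1.0))
        return floor + (plateau - floor) * rise * fall

    def hourly_crossing(profile: np.ndarray) -> float:
        thr = 0.25 * profile.max()
        below = profile < thr
        for i in range(len(t) - 1):
            if below[i] and not below[i + 1]:
                return float(t[i] + (thr - profile[i]) / (profile[i + 1] - profile[i]))
        return np.inf

    profiles = []
    for sid, dlmo in true_dlmo.items():
        lo, hi = dlmo - 2.0, dlmo + 2.0  # crossing is increasing in the centre
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if hourly_crossing(clean_profile(dlmo, mid)) < dlmo:
                lo = mid
            else:
                hi = mid
        clean = clean_profile(dlmo, 0.5 * (lo + hi))
        noisy = clean + rng.standard_normal(len(t)) * config.melatonin_noise_cv * clean
        noisy = np.maximum(noisy, floor)
        profiles.append(MelatoninProfile(sheep_id=sid, times=t % 24.0, concentrations=noisy))
    return profiles


# -- presets ---------------------------------------------------------------------


def _cv_from_sem(mean: np.ndarray, sem: np.ndarray, n_samples: int) -> np.ndarray:
    """Per-metabolite total CV implied by a printed group SEM.

    Printed SEMs are floored at half the printed precision (0.005) before
    back-computing sd = SEM * sqrt(n); the resulting CV is clipped to
    [0.05, 0.6] to avoid degenerate noise at near-zero printed SEMs.
    """
    sem = np.maximum(np.asarray(sem, dtype=float), 0.005)
    sd = sem * np.sqrt(n_samples)
    return np.clip(sd / np.asarray(mean, dtype=float), 0.05, 0.6)


def paperlike_config(
    seed: int,
    zero_effect: bool = False,
    markers_only: bool = False,
    effect_markers: tuple[str, ...] | list[str] | None = None,
    default_amplitude: float = 0.08,
    **overrides,
) -> SyntheticConfig:
    """Cohort preset calibrated to the packaged published screen table.

    Group means come straight from the table; per-metabolite total CV is
    derived from the control SEM (n = 10 sheep x 13 samples) and split
    equally in variance between the between- and within-sheep levels.
    ``zero_effect`` sets every HD mean equal to the control mean (global
    null); ``effect_markers`` keeps the table's genotype shift only for the
    listed metabolites and nulls all others (e.g. ``PANEL_MARKERS`` for the
    eight-marker discriminative set); ``markers_only`` restricts the panel
    to the eight published panel markers.  Circadian amplitudes default to
    ``default_amplitude`` with peak offsets spread deterministically over
    the 24 h.
    """
    ref = reference_screen_table()
    if markers_only:
        ref = ref[ref["abbreviation"].isin(PANEL_MARKERS)].reset_index(drop=True)
    cv_total = _cv_from_sem(ref["control_mean"], ref["control_sem"], 10 * 13)
    cv_split = cv_total / np.sqrt(2.0)
    hd_mean = ref["control_mean"] if zero_effect else ref["hd_mean"]
    if effect_markers is not None and not zero_effect:
        hd_mean = ref["hd_mean"].where(
            ref["abbreviation"].isin(list(effect_markers)), ref["control_mean"]
        )
    effect = pd.DataFrame(
        {
            "name": ref["metabolite"],
            "abbreviation": ref["abbreviation"],
            "metabolite_class": ref["metabolite_class"],
            "control_mean": ref["control_mean"],
            "hd_mean": hd_mean,
            "cv_between_sheep": cv_split,
            "cv_within_sheep": cv_split,
            "flags": ref["flags"],
        }
    )
    golden = 0.6180339887498949
    rhythm = {
        m: (default_amplitude, (i * golden % 1.0) * 24.0)
        for i, m in enumerate(effect["abbreviation"])
    }
    return SyntheticConfig(effect_table=effect, seed=seed, rhythm=rhythm, **overrides)


# -- QC kit fixture ---------------------------------------------------------------

N_KIT_CANDIDATES = 183
N_KIT_VIOLATORS = 53
_N_OOR_VIOLATORS = 27  # >25% of study samples below LOD
_N_CV_VIOLATORS = 26  # QC2 CV > 30%

KIT_FIXTURE_SEED = 20170222  # documented fixed seed for the packaged fixture


def generate_kit_fixture(seed: int = KIT_FIXTURE_SEED) -> ConcentrationTable:
    """A 183-candidate kit run in which exactly 53 analytes violate one QC rule.

    The 130 retained candidates carry the packaged panel's annotation
    (compound-class composition preserved); the 53 violators are synthetic
    analytes constructed to fail either the out-of-range-fraction rule
    (30% of study wells below LOD) or the QC2-CV rule (CV ~ 50%), never
    both.  Includes study wells for a 24-sheep cohort, 4 QC2 wells on each
    of 5 plates, and 2 blank wells.
    """
    rng = np.random.default_rng(seed)
    good = reference_screen_table()
    effect = pd.DataFrame(
        {
            "name": good["metabolite"],
            "abbreviation": good["abbreviation"],
            "metabolite_class": good["metabolite_class"],
            "control_mean": good["control_mean"],
            "hd_mean": good["hd_mean"],
            "cv_between_sheep": 0.05,
            "cv_within_sheep": 0.05,
            "flags": good["flags"],
        }
    )
    cohort = generate_cohort(
        SyntheticConfig(effect_table=effect, seed=int(rng.integers(2**31)), plate_bias_sd=0.01)
    )
    table = cohort.concentrations
    n_rows = len(table.samples)
    study_mask = (table.samples["sample_type"] == "study").to_numpy()
    qc2_mask = (table.samples["sample_type"] == "QC2").to_numpy()

    classes = list(pd.unique(good["metabolite_class"]))
    viol_ann, viol_cols = [], []
    for v in range(N_KIT_VIOLATORS):
        mean = 10.0 ** rng.uniform(-1, 2)
        kind = "oor" if v < _N_OOR_VIOLATORS else "cv"
        abbrv = f"X{kind.upper()}{v+1:02d}"
        vals = np.empty(n_rows)
        base = mean * (1.0 + 0.05 * rng.standard_normal(n_rows))
        vals[:] = np.abs(base)
        if kind == "oor":
            lod = mean / 10.0
            n_study = study_mask.sum()
            n_low = int(np.ceil(0.30 * n_study))
            low_idx = rng.choice(np.flatnonzero(study_mask), size=n_low, replace=False)
            vals[low_idx] = lod / 2.0
        else:
            lod = mean / 100.0
            # alternating half/one-and-a-half nominal: QC2 CV ~ 0.5 by construction
            alternating = np.where(np.arange(qc2_mask.sum()) % 2 == 0, 0.5, 1.5)
            vals[qc2_mask] = mean * alternating * (1.0 + 0.02 * rng.standard_normal(qc2_mask.sum()))
        viol_ann.append(
            {
                "name": f"synthetic violator {abbrv}",
                "abbreviation": abbrv,
                "metabolite_class": classes[v % len(classes)],
                "lod": lod,
                "lloq": lod * 2.0,
                "uloq": mean * 100.0,
                "flags": f"synthetic_violator_{kind}",
            }
        )
        viol_cols.append(vals)

    annotation = pd.concat(
        [table.annotation, pd.DataFrame(viol_ann)], ignore_index=True
    )
    values = pd.concat(
        [
            table.values.reset_index(drop=True),
            pd.DataFrame(
                np.column_stack(viol_cols), columns=[a["abbreviation"] for a in viol_ann]
            ),
        ],
        axis=1,
    )

    # two blank wells: trace signal far below every LOD
    blanks = pd.DataFrame(
        {
            "sample_id": ["BLANK_1", "BLANK_2"],
            "sheep_id": ["", ""],
            "genotype": ["", ""],
            "clock_time": [0.0, 0.0],
            "sampling_index": [0, 0],
            "plate_id": ["P1", "P2"],
            "sample_type": ["blank", "blank"],
        }
    )
    blank_vals = pd.DataFrame(
        np.zeros((2, len(annotation))), columns=annotation["abbreviation"]
    )
    samples = pd.concat([table.samples, blanks], ignore_index=True)
    values = pd.concat([values, blank_vals], ignore_index=True)
    assert len(annotation) == N_KIT_CANDIDATES
    return ConcentrationTable(samples, annotation, values)
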