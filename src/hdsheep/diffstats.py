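"""Per-metabolite two-way linear-model screening with BH-FDR and tabulation.

Each metabolite's concentration series is fitted by an ordinary linear
model with genotype, time of day (categorical, 13 levels in the study
design), animal (fixed, nested in genotype) and the genotype x time
interaction.  Sequential (type-I) sums of squares are taken in that
order; because the animal indicators span the genotype contrast, genotype
must enter first and its aliased animal columns are dropped.  F tests use
the residual mean square.  Genotype p-values across the panel are
corrected by the Benjamini-Hochberg step-up FDR, and significant
metabolites (FDR < alpha) are tabulated by compound class and direction
of change.  Urea-/NO-cycle activity ratios (Cit/Arg, Cit/Orn, Orn/Arg)
are formed per sample and screened through the same model.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ConcentrationTable, ValidationError, genotype_code

ANOVA_TERMS = ("genotype", "time", "animal", "genotype_x_time")


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full one-hot indicator matrix (no reference level dropped)."""
    levels, inv = np.unique(labels, return_inverse=True)
    return np.eye(len(levels))[inv]


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2)), int(rank)


def fit_metabolite_anova(
    values: Sequence[float], design: pd.DataFrame
) -> tuple[float, float, float]:
    """Sequential-SS two-way ANOVA p-values (genotype, time, interaction).

    ``design`` needs columns ``genotype`` ("control"/"HD"), ``time`` (any
    categorical label, e.g. sampling index) and ``sheep_id``.  Missing
    values are dropped row-wise.  Time is treated as categorical with the
    observed number of levels.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != len(design):
        raise ValidationError("values and design differ in length")
    keep = np.isfinite(y)
    y = y[keep]
    design = design.reset_index(drop=True).loc[keep]
    g = genotype_code(design["genotype"]).astype(float)
    time_labels = design["time"].to_numpy()
    animal_labels = design["sheep_id"].to_numpy()

    sheep_geno = pd.DataFrame({"sheep": animal_labels, "g": g}).drop_duplicates()
    per_geno = sheep_geno.groupby("g")["sheep"].count()
    if per_geno.size < 2 or (per_geno < 2).any():
        raise ValidationError("need at least 2 sheep per genotype")

    n = len(y)
    intercept = np.ones((n, 1))
    Xg = g[:, None]
    Xt = _dummies(time_labels)[:, 1:]  # drop one level; intercept carries it
    Xa_full = _dummies(animal_labels)
    # drop one animal per genotype: those columns are aliased with
    # intercept+genotype once genotype has entered the model
    sheep_order = pd.unique(animal_labels)
    sheep_g = dict(zip(sheep_geno["sheep"], sheep_geno["g"]))
    drop = set()
    for geno_val in (0.0, 1.0):
        for s in sheep_order:
            if sheep_g[s] == geno_val:
                drop.add(s)
                break
    keep_cols = [i for i, s in enumerate(np.unique(animal_labels)) if s not in drop]
    Xa = Xa_full[:, keep_cols]
    Xgt = Xt * g[:, None]

    blocks = [intercept, Xg, Xt, Xa, Xgt]
    rss = []
    ranks = []
    X = np.empty((n, 0))
    for b in blocks:
        X = np.hstack([X, b])
        r, rk = _rss_rank(X, y)
        rss.append(r)
        ranks.append(rk)
    df_terms = np.diff(ranks)  # genotype, time, animal, interaction
    ss_terms = -np.diff(rss)
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValidationError("zero residual degrees of freedom")
    ms_resid = rss[-1] / df_resid

    pvals = []
    for ss, df in zip(ss_terms, df_terms):
        if df == 0:
            pvals.append(np.nan)
            continue
        if ms_resid == 0:
            pvals.append(0.0 if ss > 0 else 1.0)
            continue
        F = (ss / df) / ms_resid
        pvals.append(float(stats.f.sf(F, df, df_resid)))
    # order: genotype, time, animal, interaction -> report genotype/time/interaction
    return pvals[0], pvals[1], pvals[3]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def group_means_sem(
    values: Sequence[float], design: pd.DataFrame, by_sheep: bool = False
) -> tuple[float, float, float, float]:
    """Group mean and SEM per genotype, pooled over sheep x time.

    With ``by_sheep=True`` the SEM is instead computed over per-sheep 24 h
    means (n = number of sheep), the alternative reading of a published
    summary table.
    """
    y = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        {"y": y, "genotype": design["genotype"].to_numpy(), "sheep": design["sheep_id"].to_numpy()}
    ).dropna(subset=["y"])
    out = {}
    for geno in ("control", "HD"):
        sub = df[df["genotype"] == geno]
        if by_sheep:
            sub = sub.groupby("sheep")["y"].mean().to_frame("y")
        if len(sub) < 2:
            raise ValidationError(f"fewer than 2 non-missing values for {geno}")
        vals = sub["y"].to_numpy()
        out[geno] = (float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals))))
    return out["control"][0], out["control"][1], out["HD"][0], out["HD"][1]


def screen_metabolites(
    table: ConcentrationTable, alpha: float = 0.05, sem_by_sheep: bool = False
) -> pd.DataFrame:
    """Per-metabolite ANOVA + BH-FDR across the panel.

    Returns one row per metabolite with raw p-values, FDR-adjusted values
    (adjusted within each term across the panel) and group means +/- SEM.
    """
    study = table.study_samples()
    design = pd.DataFrame(
        {
            "genotype": study["genotype"].to_numpy(),
            "time": study["sampling_index"].to_numpy(),
            "sheep_id": study["sheep_id"].to_numpy(),
        }
    )
    values = table.study_values()
    rows = []
    for _, ann in table.annotation.iterrows():
        m = ann["abbreviation"]
        y = values[m].to_numpy()
        pg, pt, pi = fit_metabolite_anova(y, design)
        cm, cs, hm, hs = group_means_sem(y, design, by_sheep=sem_by_sheep)
        rows.append(
            {
                "metabolite": ann["name"],
                "abbreviation": m,
                "metabolite_class": ann["metabolite_class"],
                "p_genotype": pg,
                "p_time": pt,
                "p_interaction": pi,
                "control_mean": cm,
                "control_sem": cs,
                "hd_mean": hm,
                "hd_sem": hs,
            }
        )
    res = pd.DataFrame(rows)
    for term in ("genotype", "time", "interaction"):
        res[f"fdr_{term}"] = bh_fdr(res[f"p_{term}"].to_numpy())
    return res


@dataclasses.dataclass(frozen=True)
class RatioDefinition:
    """A named per-sample concentration ratio (e.g. Cit/Arg for NOS activity)."""

    name: str
    numerator: str
    denominator: str
    interpretation: str = ""

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValidationError("numerator and denominator must differ")


#: urea-/NO-cycle activity indicator ratios
UREA_CYCLE_RATIOS = (
    RatioDefinition("Cit/Arg", "Cit", "Arg", "nitric oxide synthase activity"),
    RatioDefinition("Cit/Orn", "Cit", "Orn", "ornithine carbamoylphosphate transferase activity"),
    RatioDefinition("Orn/Arg", "Orn", "Arg", "arginase activity"),
)


def compute_ratio_series(table: ConcentrationTable, ratio: RatioDefinition) -> pd.Series:
    """Per-sample ratio; missing if either component missing or denominator 0."""
    cols = set(table.values.columns)
    for part in (ratio.numerator, ratio.denominator):
        if part not in cols:
            raise ValidationError(f"{part!r} not present in table (excluded by QC?)")
    num = table.values[ratio.numerator]
    den = table.values[ratio.denominator]
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero denominator(s) for {ratio.name}; set missing",
            RuntimeWarning,
            stacklevel=2,
        )
    out = num / den.where(~zero, np.nan)
    out.name = ratio.name
    return out


def summarize_significance(
    results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Tabulate genotype significance per compound class, with direction.

    A metabolite is significant iff ``fdr_genotype < alpha`` (strict).
    Direction compares ``hd_mean`` with ``control_mean`` at stored
    precision; exact ties are reported in ``n_tied_direction``, never
    silently assigned to either direction.  A ``total`` row is appended.
    """
    req = {"metabolite_class", "fdr_genotype", "control_mean", "hd_mean"}
    missing = req - set(results.columns)
    if missing:
        raise ValidationError(f"results missing column(s): {sorted(missing)}")
    rows = []
    classes = list(pd.unique(results["metabolite_class"]))
    for cls in classes + ["total"]:
        sub = results if cls == "total" else results[results["metabolite_class"] == cls]
        sig = sub[sub["fdr_genotype"] < alpha]
        inc = (sig["hd_mean"] > sig["control_mean"]).sum()
        dec = (sig["hd_mean"] < sig["control_mean"]).sum()
        tied = (sig["hd_mean"] == sig["control_mean"]).sum()
        rows.append(
            {
                "metabolite_class": cls,
                "n_total": len(sub),
                "n_significant": len(sig),
                "n_increased": int(inc),
                "n_decreased": int(dec),
                "n_tied_direction": int(tied),
            }
        )
    return pd.DataFrame(rows)
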