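"""Biomarker pre-selection and forward-stepwise logistic panel building.

Candidate markers must clear three filters: a genotype FDR below 0.05 in
the per-metabolite screen, a single-marker AUC significantly above a
sheep-level permutation null (labels are permuted per animal, since the
13 samples of one sheep are exchangeable only as a block), and a relative
group-mean difference above 5%.  Panels are then grown greedily: at each
step the candidate giving the largest strictly positive gain in pooled
leave-one-sheep-out cross-validated (LOSOCV) AUC joins the model, until
no candidate improves it.  Logistic models use natural-log concentrations
with training-fold mean imputation; time of day never enters the feature
set, so a prediction can be made from a single sample drawn at any time.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .circadian import phase_bin
from .data_model import ConcentrationTable, ValidationError, genotype_code


# -- AUC -----------------------------------------------------------------------


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC area by the Mann-Whitney formulation (ties count half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValidationError("scores and labels differ in length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(s)
    u1 = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def _pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) pair-count AUC; retained as an explicit reference formulation."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(cases) * len(controls)))


# -- sheep-level permutation null ----------------------------------------------


@dataclasses.dataclass(frozen=True)
class MarkerFilterCriteria:
    """Thresholds for the three marker pre-selection filters."""

    alpha_fdr: float = 0.05
    perm_alpha: float = 0.05
    n_permutations: int = 10_000
    min_relative_difference: float = 0.05
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_fdr, self.perm_alpha, self.min_relative_difference) <= 0:
            raise ValidationError("criteria thresholds must be positive")
        if self.n_permutations < 100:
            raise ValidationError("n_permutations must be >= 100")


def _oriented_auc_from_ranksums(
    rank_sums: np.ndarray, counts: np.ndarray, hd_mask: np.ndarray
) -> np.ndarray:
    """AUC of samples of sheep flagged in hd_mask (rows) vs the rest.

    ``hd_mask`` is (n_assignments x n_sheep) boolean; rank_sums/counts are
    per-sheep sums of global average ranks and sample counts.  Returns the
    orientation-free statistic max(AUC, 1-AUC) per assignment.
    """
    n1 = hd_mask @ counts
    n0 = counts.sum() - n1
    u1 = hd_mask @ rank_sums - n1 * (n1 + 1) / 2.0
    a = u1 / (n1 * n0)
    return np.maximum(a, 1.0 - a)


def permutation_auc_test(
    values: Sequence[float],
    design: pd.DataFrame,
    criteria: MarkerFilterCriteria | None = None,
) -> tuple[float, float]:
    """Single-marker AUC with a sheep-level label-permutation p-value.

    The observed statistic is the orientation-free raw (non-CV) AUC,
    max(AUC, 1-AUC), over all non-missing study samples.  The null is
    built by reassigning genotype labels to whole sheep (keeping the
    control/HD sheep counts) and recomputing the same statistic;
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    criteria = criteria or MarkerFilterCriteria()
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    sheep = design["sheep_id"].to_numpy()[keep]
    geno = genotype_code(design["genotype"].to_numpy()[keep])
    if geno.min() == geno.max():
        raise ValidationError("both genotypes must be present")

    sheep_ids = pd.unique(sheep)
    sheep_geno = np.array([geno[sheep == s][0] for s in sheep_ids])
    n_sheep = len(sheep_ids)
    n_hd = int(sheep_geno.sum())
    if math.comb(n_sheep, n_hd) < 20:
        raise ValidationError(
            "fewer than 20 distinct sheep-label assignments; "
            "use exact enumeration instead of Monte-Carlo permutation"
        )

    ranks = stats.rankdata(y)
    rank_sums = np.array([ranks[sheep == s].sum() for s in sheep_ids])
    counts = np.array([(sheep == s).sum() for s in sheep_ids])

    observed = float(
        _oriented_auc_from_ranksums(rank_sums, counts, sheep_geno[None, :].astype(bool))[0]
    )

    rng = np.random.default_rng(criteria.permutation_seed)
    masks = np.zeros((criteria.n_permutations, n_sheep), dtype=bool)
    for i in range(criteria.n_permutations):
        masks[i, rng.choice(n_sheep, size=n_hd, replace=False)] = True
    null = _oriented_auc_from_ranksums(rank_sums, counts, masks)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + criteria.n_permutations)
    return observed, float(p)


def preselect_markers(
    results: pd.DataFrame,
    table: ConcentrationTable,
    criteria: MarkerFilterCriteria | None = None,
) -> pd.DataFrame:
    """Apply the three pre-selection filters to every screened metabolite.

    Returns one row per metabolite with the per-criterion verdicts
    (``fdr_pass``, ``perm_pass`` with observed AUC and p, ``reldiff_pass``)
    and the conjunction ``selected``.
    """
    criteria = criteria or MarkerFilterCriteria()
    study = table.study_samples()
    design = pd.DataFrame(
        {"sheep_id": study["sheep_id"].to_numpy(), "genotype": study["genotype"].to_numpy()}
    )
    values = table.study_values()
    rows = []
    res = results.set_index("abbreviation")
    for m in table.annotation["abbreviation"]:
        r = res.loc[m]
        if r["control_mean"] == 0:
            raise ValidationError(f"relative difference undefined: control mean 0 for {m}")
        reldiff = abs(r["hd_mean"] - r["control_mean"]) / r["control_mean"]
        obs_auc, p_perm = permutation_auc_test(values[m].to_numpy(), design, criteria)
        rows.append(
            {
                "abbreviation": m,
                "fdr_genotype": float(r["fdr_genotype"]),
                "fdr_pass": bool(r["fdr_genotype"] < criteria.alpha_fdr),
                "observed_auc": obs_auc,
                "perm_p": p_perm,
                "perm_pass": bool(p_perm < criteria.perm_alpha),
                "relative_difference": float(reldiff),
                "reldiff_pass": bool(reldiff > criteria.min_relative_difference),
            }
        )
    out = pd.DataFrame(rows)
    out["selected"] = out["fdr_pass"] & out["perm_pass"] & out["reldiff_pass"]
    return out


# -- logistic regression by IRLS -----------------------------------------------


@dataclasses.dataclass
class LogisticFit:
    coefficients: np.ndarray  # intercept first
    converged: bool
    separation_flagged: bool
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = np.hstack([np.ones((len(X), 1)), X])
        return expit(Z @ self.coefficients)


def fit_logistic(
    features: np.ndarray,
    labels: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge_on_separation: float = 1e-6,
) -> LogisticFit:
    """Binomial MLE by iteratively reweighted least squares.

    Converged when the largest coefficient change drops below ``tol``.
    On detected (quasi-)separation — diverging coefficients or failure to
    converge — the fit is repeated with a fixed small ridge penalty on
    the non-intercept coefficients and flagged.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature values")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    Z = np.hstack([np.ones((len(X), 1)), X])

    def irls(penalty: float) -> tuple[np.ndarray, bool, bool, int]:
        beta = np.zeros(Z.shape[1])
        pen = np.full(Z.shape[1], penalty)
        pen[0] = 0.0
        for it in range(1, max_iter + 1):
            eta = Z @ beta
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z_work = eta + (y - mu) / w
            A = (Z * w[:, None]).T @ Z + np.diag(pen)
            b = (Z * w[:, None]).T @ z_work
            try:
                new = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                return beta, False, True, it
            delta = np.max(np.abs(new - beta))
            beta = new
            if np.max(np.abs(Z @ beta)) > 30.0 and penalty == 0.0:
                return beta, False, True, it
            if delta < tol:
                return beta, True, False, it
        return beta, False, penalty == 0.0, max_iter

    beta, converged, separated, n_iter = irls(0.0)
    if separated or not converged:
        beta, converged, _, n_iter = irls(ridge_on_separation)
        return LogisticFit(beta, converged, True, n_iter)
    return LogisticFit(beta, converged, False, n_iter)


# -- LOSOCV --------------------------------------------------------------------


def _log_features(
    raw: pd.DataFrame, train_means: pd.Series, train_floor: pd.Series
) -> np.ndarray:
    """Impute (train mean, raw scale), floor non-positives, then natural log."""
    filled = raw.fillna(train_means)
    filled = filled.where(filled > 0, train_floor, axis=1)
    return np.log(filled.to_numpy())


def _train_stats(raw: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    means = raw.mean(axis=0, skipna=True)
    min_pos = raw.where(raw > 0).min(axis=0, skipna=True)
    floor = (min_pos / 2.0).fillna(1e-12)
    return means, floor


class _FoldFeatures:
    """Per-fold imputed log-feature columns, shared across stepwise candidates.

    Imputation and log-floor statistics depend only on (marker, fold), so
    they are computed once; a candidate panel's fold design matrix is then
    a cheap column slice.
    """

    def __init__(
        self,
        table: ConcentrationTable,
        markers: Sequence[str],
        leaky_imputation: bool = False,
    ) -> None:
        self.markers = list(markers)
        if not self.markers:
            raise ValidationError("markers must be non-empty")
        study = table.study_samples()
        raw = table.study_values()[self.markers].reset_index(drop=True)
        self.y = genotype_code(study["genotype"])
        self.sheep = study["sheep_id"].to_numpy()
        self.sheep_ids = pd.unique(self.sheep)
        geno_by_sheep = pd.Series(self.y, index=self.sheep).groupby(level=0).first()
        counts = geno_by_sheep.value_counts()
        if len(counts) < 2 or counts.min() < 3:
            raise ValidationError("need >= 3 sheep per genotype for LOSOCV")
        self.study = study
        if "phase_offset" in study.columns and study["phase_offset"].notna().all():
            self.bins = phase_bin(study["phase_offset"].to_numpy())
        else:
            self.bins = study["sampling_index"].to_numpy().astype(float)

        global_means, global_floor = _train_stats(raw)
        self.folds = []
        for held in self.sheep_ids:
            test_mask = self.sheep == held
            train_mask = ~test_mask
            y_train = self.y[train_mask]
            if y_train.min() == y_train.max():
                raise ValidationError(f"fold holding out {held!r} loses a class")
            if leaky_imputation:
                means, floor = global_means, global_floor
            else:
                means, floor = _train_stats(raw[train_mask])
            self.folds.append(
                {
                    "test_mask": test_mask,
                    "y_train": y_train,
                    "X_train": _log_features(raw[train_mask], means, floor),
                    "X_test": _log_features(raw[test_mask], means, floor),
                }
            )
        self._col = {m: j for j, m in enumerate(self.markers)}

    def cv_probabilities(self, panel: Sequence[str]) -> np.ndarray:
        cols = [self._col[m] for m in panel]
        preds = np.full(len(self.y), np.nan)
        for fold in self.folds:
            fit = fit_logistic(fold["X_train"][:, cols], fold["y_train"])
            preds[fold["test_mask"]] = fit.predict_proba(fold["X_test"][:, cols])
        return preds

    def prediction_frame(self, probabilities: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.study["sample_id"].to_numpy(),
                "sheep_id": self.sheep,
                "genotype": self.study["genotype"].to_numpy(),
                "phase_bin": self.bins,
                "predicted_probability": probabilities,
            }
        )


def losocv_predictions(
    table: ConcentrationTable,
    markers: Sequence[str],
    leaky_imputation: bool = False,
) -> pd.DataFrame:
    """Held-out probability for every study sample, one fold per sheep.

    Each fold trains a logistic model on all samples of the other sheep
    and predicts the held-out sheep's samples.  Missing marker values are
    imputed as the cross-sample average on the raw scale before the log
    transform; imputation statistics come from the training fold (set
    ``leaky_imputation=True`` to use all samples, replicating analyses
    that pooled before splitting).
    """
    ff = _FoldFeatures(table, markers, leaky_imputation)
    return ff.prediction_frame(ff.cv_probabilities(list(markers)))


def pooled_cv_auc(predictions: pd.DataFrame) -> float:
    return auc(
        predictions["predicted_probability"].to_numpy(),
        genotype_code(predictions["genotype"]),
    )


def sheep_level_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Median held-out probability per sheep (animal-level classification)."""
    g = predictions.groupby("sheep_id", sort=True)
    out = g.agg(
        predicted_probability=("predicted_probability", "median"),
        genotype=("genotype", "first"),
    ).reset_index()
    return out


# -- stepwise panel search -----------------------------------------------------


@dataclasses.dataclass
class PanelModel:
    """An ordered marker panel with its full-data fit and CV performance."""

    markers: list[str]
    coefficients: np.ndarray  # intercept + one per marker, log-uM scale
    step_auc: list[float]  # LOSOCV pooled AUC after each step
    final_auc: float

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("panel markers must be distinct")
        if any(nxt <= cur for cur, nxt in zip(self.step_auc, self.step_auc[1:])):
            raise ValidationError("step_auc must be strictly increasing")


def _full_data_fit(table: ConcentrationTable, markers: list[str]) -> np.ndarray:
    study = table.study_samples()
    raw = table.study_values()[markers].reset_index(drop=True)
    means, floor = _train_stats(raw)
    X = _log_features(raw, means, floor)
    fit = fit_logistic(X, genotype_code(study["genotype"]))
    return fit.coefficients


def stepwise_build_panels(
    table: ConcentrationTable,
    candidates: Sequence[str],
    max_size: int = 12,
    fdr_by_marker: Mapping[str, float] | None = None,
    leaky_imputation: bool = False,
) -> list[PanelModel]:
    """Greedy forward selection maximizing pooled LOSOCV AUC.

    Step 1 picks the single best candidate; each later step adds the
    candidate with the largest strictly positive AUC gain; the search
    stops when no candidate improves the AUC or ``max_size`` is reached.
    Ties break by smaller genotype FDR (if supplied), then alphabetically.
    All intermediate panels are returned.
    """
    remaining = sorted(set(candidates))
    if not remaining:
        raise ValidationError("candidates must be non-empty")
    fdr_by_marker = dict(fdr_by_marker or {})
    ff = _FoldFeatures(table, remaining, leaky_imputation)
    y = genotype_code(ff.study["genotype"])

    def sort_key(m: str) -> tuple[float, str]:
        return (fdr_by_marker.get(m, 1.0), m)

    selected: list[str] = []
    step_aucs: list[float] = []
    models: list[PanelModel] = []
    current_auc = -np.inf
    while remaining and len(selected) < max_size:
        best_marker, best_auc = None, current_auc
        for m in sorted(remaining, key=sort_key):
            a = auc(ff.cv_probabilities(selected + [m]), y)
            if a > best_auc + 1e-12:
                best_marker, best_auc = m, a
        if best_marker is None:
            break
        selected = selected + [best_marker]
        remaining.remove(best_marker)
        current_auc = best_auc
        step_aucs = step_aucs + [best_auc]
        models.append(
            PanelModel(
                markers=list(selected),
                coefficients=_full_data_fit(table, selected),
                step_auc=list(step_aucs),
                final_auc=best_auc,
            )
        )
    return models


# -- ROC reporting -------------------------------------------------------------


@dataclasses.dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC over all observed thresholds (positive iff score >= t)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    thr = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(s[y == 1] >= t).mean() for t in thr])
    spec = np.array([(s[y == 0] < t).mean() for t in thr])
    return RocCurve(thr, sens, spec, auc(s, y))


def sensitivity_at_specificity(
    predictions: pd.DataFrame, target_specificity: float = 0.90
) -> tuple[float, float]:
    """Best sensitivity among thresholds achieving the target specificity.

    Predicted positive iff probability >= threshold; among thresholds with
    specificity >= target, the one maximizing sensitivity is returned
    (no interpolation between operating points).
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValidationError("target specificity must be in (0,1)")
    s = predictions["predicted_probability"].to_numpy()
    y = genotype_code(predictions["genotype"])
    curve = roc_curve(s, y)
    ok = curve.specificity >= target_specificity
    if not ok.any():
        return 0.0, float("inf")
    best_sens = curve.sensitivity[ok].max()
    # ties broken toward the lowest qualifying threshold
    idx = np.flatnonzero(ok & (curve.sensitivity == best_sens))[-1]
    return float(curve.sensitivity[idx]), float(curve.thresholds[idx])


def auc_by_timepoint(predictions: pd.DataFrame) -> pd.DataFrame:
    """Pooled CV AUC within each phase bin; one-class bins reported as NaN."""
    rows = []
    for b, grp in predictions.groupby("phase_bin", sort=True):
        y = genotype_code(grp["genotype"])
        if y.min() == y.max():
            rows.append({"phase_bin": b, "auc": np.nan, "n": len(grp)})
        else:
            rows.append(
                {
                    "phase_bin": b,
                    "auc": auc(grp["predicted_probability"].to_numpy(), y),
                    "n": len(grp),
                }
            )
    return pd.DataFrame(rows)
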