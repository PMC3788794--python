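"""Validation of predicted occupancy against observed presence-absence.

Threshold-dependent metrics (sensitivity, specificity, correct
classification rate, true skill statistic) use an optimised threshold —
the 0.01-step grid point where sensitivity and specificity cross; the
threshold-free AUC uses the Mann-Whitney formulation with ties counted
half.  Internal validation is k-fold cross-validation over patches;
external validation scores first-season predictions on an independent
patch network at a supplied threshold.

Observed "truth" here is naive presence over a season's combined surveys,
which is itself contaminated by false absences when detection is imperfect;
every report therefore carries the expected false-absence rate
``prod_j (1 - p_j)`` implied by the fitted detection probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import MetapopDataset, naive_presence
from .design import ModelSpec
from .exceptions import AlignmentError, UndefinedValueError
from .model import FittedModel, fit, predict_occupancy_by_season, predict_patch_parameters

THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted_prob, observed, threshold: float) -> ConfusionCounts:
    """Tally a 2x2 confusion table; predicted presence means probability >=
    threshold."""
    prob = np.asarray(predicted_prob, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if prob.shape != obs.shape:
        raise AlignmentError("predicted and observed sequences differ in length")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    pred = prob >= threshold
    return ConfusionCounts(
        tp=int((pred & (obs == 1)).sum()),
        fp=int((pred & (obs == 0)).sum()),
        tn=int((~pred & (obs == 0)).sum()),
        fn=int((~pred & (obs == 1)).sum()),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        raise UndefinedValueError("sensitivity undefined: no observed presences")
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    if counts.tn + counts.fp == 0:
        raise UndefinedValueError("specificity undefined: no observed absences")
    return counts.tn / (counts.tn + counts.fp)


def ccr(counts: ConfusionCounts) -> float:
    """Correct classification rate (tp + tn) / total."""
    if counts.total == 0:
        raise UndefinedValueError("CCR undefined: no evaluated patches")
    return (counts.tp + counts.tn) / counts.total


def tss(counts: ConfusionCounts) -> float:
    """True skill statistic, sensitivity + specificity - 1; ranges from -1 to
    +1 with 0 no better than random."""
    return sensitivity(counts) + specificity(counts) - 1.0


def roc_auc(predicted_prob, observed) -> float:
    """Area under the ROC curve: the probability a random presence outranks
    a random absence, ties counted half (Mann-Whitney form)."""
    prob = np.asarray(predicted_prob, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if prob.shape != obs.shape:
        raise AlignmentError("predicted and observed sequences differ in length")
    n_pos = int((obs == 1).sum())
    n_neg = int((obs == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedValueError("AUC undefined: both classes must be present")
    ranks = rankdata(prob)
    rank_sum = ranks[obs == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(predicted_prob, observed) -> pd.DataFrame:
    """Sensitivity and specificity over the threshold grid, for plotting."""
    rows = [
        (t, *_sens_spec(predicted_prob, observed, t)) for t in THRESHOLD_GRID
    ]
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])


def _sens_spec(prob, obs, threshold) -> tuple[float, float]:
    c = confusion_counts(prob, obs, threshold)
    return sensitivity(c), specificity(c)


def optimize_threshold(predicted_prob, observed) -> float:
    """The grid threshold (step 0.01) where sensitivity and specificity
    cross, i.e. minimising |sensitivity - specificity|; ties go to the lower
    threshold."""
    diffs = [
        abs(s - sp) for s, sp in (_sens_spec(predicted_prob, observed, t) for t in THRESHOLD_GRID)
    ]
    return float(THRESHOLD_GRID[int(np.argmin(diffs))])


def expected_false_absence_rate(p_per_survey) -> float:
    """Probability an occupied patch yields an all-zero detection history:
    ``prod_j (1 - p_j)`` over the surveys."""
    p = np.asarray(p_per_survey, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one survey detection probability")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("detection probabilities must lie in [0, 1]")
    return float(np.prod(1.0 - p))


@dataclass
class ValidationReport:
    """Validation summary: threshold used, overall metrics, and optional
    per-year, per-fold and per-stratum breakdowns."""

    threshold: float | None
    overall: dict[str, float]
    per_year: pd.DataFrame | None = None
    per_fold: pd.DataFrame | None = None
    strata: pd.DataFrame | None = None
    expected_false_absence: float | None = None

    def to_json(self, path) -> None:
        blob = {
            "threshold": self.threshold,
            "overall": self.overall,
            "expected_false_absence": self.expected_false_absence,
        }
        for name in ("per_year", "per_fold", "strata"):
            frame = getattr(self, name)
            if frame is not None:
                blob[name] = json.loads(frame.to_json(orient="records"))
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=2, default=float)


def _year_metrics(prob, obs, threshold) -> dict[str, float]:
    ok = ~np.isnan(obs)
    prob, obs = prob[ok], obs[ok]
    if len(np.unique(obs)) < 2:
        warnings.warn("single-class validation data: metrics undefined")
        return {"ccr": np.nan, "tss": np.nan, "auc": np.nan}
    c = confusion_counts(prob, obs, threshold)
    return {"ccr": ccr(c), "tss": tss(c), "auc": roc_auc(prob, obs)}


def _mean_false_absence(fitted: FittedModel, patches: pd.DataFrame, n_surveys: int) -> float:
    params = predict_patch_parameters(fitted, patches)
    p1 = params["p_1"].to_numpy()
    return float(np.mean((1.0 - p1) ** n_surveys))


def kfold_cross_validate(
    dataset: MetapopDataset,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> ValidationReport:
    """k-fold cross-validation of a model specification.

    Patches are partitioned at random into k folds.  For each fold the
    model is refitted on the training patches, the threshold optimised on
    pooled training predictions, and the held-out patches scored per year —
    season-1 occupancy from covariates, later seasons via the occupancy
    recursion with patch-specific colonisation/extinction estimates —
    against naive presence.  Reports per-fold metrics and their mean/SD.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if dataset.n_patches < k:
        raise ValueError("need at least k patches")
    rng = np.random.default_rng(seed)
    order = rng.permutation(dataset.n_patches)
    folds = np.array_split(order, k)

    observed = np.column_stack(
        [naive_presence(dataset, t) for t in range(dataset.n_seasons)]
    )
    rows = []
    fa_rates = []
    for fold_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        train = dataset.subset(train_idx)
        fitted = fit(train, spec, compute_se=False, **fit_kwargs)
        if not fitted.converged:
            warnings.warn(f"fold {fold_idx}: fit did not converge; fold skipped")
            continue
        psi_train = predict_occupancy_by_season(fitted, train.covariates).to_numpy()
        obs_train = observed[train_idx]
        ok = ~np.isnan(obs_train.ravel())
        threshold = optimize_threshold(psi_train.ravel()[ok], obs_train.ravel()[ok])

        psi_test = predict_occupancy_by_season(
            fitted, dataset.subset(test_idx).covariates
        ).to_numpy()
        fa_rates.append(_mean_false_absence(fitted, dataset.subset(test_idx).covariates,
                                            dataset.n_surveys))
        for t in range(dataset.n_seasons):
            metrics = _year_metrics(psi_test[:, t], observed[test_idx, t], threshold)
            rows.append({"fold": fold_idx, "year": t + 1, "threshold": threshold, **metrics})

    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise UndefinedValueError("no fold produced defined metrics")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN year slices
        per_year = per_fold.groupby("year")[["ccr", "tss", "auc"]].agg(["mean", "std"])
    per_year.columns = ["_".join(c) for c in per_year.columns]
    overall = {
        f"{m}_{s}": float(getattr(np, f"nan{s}")(per_fold[m].to_numpy()))
        for m in ("ccr", "tss", "auc")
        for s in ("mean", "std")
    }
    return ValidationReport(
        threshold=None,
        overall=overall,
        per_year=per_year.reset_index(),
        per_fold=per_fold,
        expected_false_absence=float(np.mean(fa_rates)) if fa_rates else None,
    )


def external_validate(
    fitted: FittedModel, new_dataset: MetapopDataset, threshold: float
) -> ValidationReport:
    """Score first-season occupancy predictions on an independent patch
    network at a fixed threshold.

    Observed presence is naive presence over the new dataset's combined
    surveys (all seasons pooled).  Metrics are reported overall and
    stratified by matrix type.
    """
    patches = new_dataset.covariates
    psi1 = predict_patch_parameters(fitted, patches)["psi1"].to_numpy()
    combined = np.nansum(new_dataset.detections.reshape(new_dataset.n_patches, -1), axis=1) > 0
    all_missing = np.isnan(new_dataset.detections).all(axis=(1, 2))
    observed = np.where(all_missing, np.nan, combined.astype(float))

    ok = ~np.isnan(observed)
    c = confusion_counts(psi1[ok], observed[ok], threshold)
    overall = {
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "ccr": ccr(c),
        "tss": tss(c),
        "auc": roc_auc(psi1[ok], observed[ok]),
    }
    strata_rows = []
    for stratum in ("pasture", "tussock"):
        mask = (patches["matrix"].to_numpy() == stratum) & ok
        row: dict = {"matrix": stratum, "n_patches": int(mask.sum())}
        if len(np.unique(observed[mask])) < 2:
            warnings.warn(f"stratum {stratum!r} is single-class; metrics undefined")
            row.update({"sensitivity": np.nan, "specificity": np.nan,
                        "tss": np.nan, "auc": np.nan})
        else:
            cs = confusion_counts(psi1[mask], observed[mask], threshold)
            row.update({
                "sensitivity": sensitivity(cs), "specificity": specificity(cs),
                "tss": tss(cs), "auc": roc_auc(psi1[mask], observed[mask]),
            })
        strata_rows.append(row)
    return ValidationReport(
        threshold=threshold,
        overall=overall,
        strata=pd.DataFrame(strata_rows),
        expected_false_absence=_mean_false_absence(fitted, patches, new_dataset.n_surveys),
    )
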