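"""Machine-learning confirmation: correlation filters + RFE Random Forest.

Confirms candidate proteins by predicting the 6-month disease-activity
outcome (low vs high, with the secondary-high group counted as high) from
the quantification values of one collection time point.  Missing cells are
set to zero for this stage only — the classifier does not handle missing
values, and zero-imputation deliberately converts group-dependent
missingness into group-dependent means.  Feature selection removes proteins
with |r| < 0.3 against the outcome, then greedily prunes pairs with mutual
|r| > 0.75; recursive feature elimination under a repeated cross-validated
Random Forest ranks what remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .core_data import QuantMatrix, SampleMetadata, ValidationError, align
from .correlation import fisher_ci
from .profiles import ThresholdSpec, apply_threshold

__all__ = [
    "FeatureSelectionSpec",
    "MlResult",
    "zero_impute",
    "build_feature_table",
    "univariate_filter",
    "redundancy_filter",
    "rfe_random_forest",
    "threshold_sweep",
]

#: outcome encoding: low disease activity vs any high disease activity at 6 months
OUTCOME_ENCODING = {"LD": 0, "HD": 1, "2HD": 1}


@dataclass(frozen=True)
class FeatureSelectionSpec:
    """Filter thresholds and resampling plan for the confirmation stage."""

    univariate_min_abs_r: float = 0.3
    pairwise_max_abs_r: float = 0.75
    n_folds: int = 5
    n_repeats: int = 5
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("univariate_min_abs_r", "pairwise_max_abs_r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_folds < 2 or self.n_repeats < 1 or self.n_trees < 1:
            raise ValidationError("need n_folds >= 2, n_repeats >= 1, n_trees >= 1")


@dataclass(frozen=True)
class MlResult:
    """RFE outcome: accuracy per candidate subset size and the chosen subset."""

    selected_proteins: tuple[str, ...]  # ordered by importance, best first
    importances: pd.Series
    accuracy_by_size: pd.Series  # mean CV accuracy, indexed by subset size
    chosen_size: int
    n_folds: int
    n_repeats: int


def zero_impute(matrix: QuantMatrix) -> QuantMatrix:
    """Replace every missing cell with 0; observed cells are untouched.

    Used only by the ML stage — missingness profiles are always computed
    before imputation.
    """
    return QuantMatrix(matrix.values.fillna(0.0))


def build_feature_table(
    matrix: QuantMatrix, meta: SampleMetadata, timepoint: str = "baseline"
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x proteins feature frame for one time point plus the binary outcome.

    The outcome is the participant's disease-activity class (LD -> 0,
    HD/2HD -> 1).  Missing cells pass through as NaN; call
    :func:`zero_impute` on the matrix first for a complete design.
    """
    matrix, meta = align(matrix, meta)
    samples = meta.samples_where("timepoint", timepoint)
    if len(samples) == 0:
        raise ValidationError(f"no samples at timepoint {timepoint!r}")
    X = matrix.values.loc[:, samples].T
    y = meta.table.loc[samples, "group"].map(OUTCOME_ENCODING).astype(int)
    y.name = "outcome"
    return X, y


def univariate_filter(
    X: pd.DataFrame, y: pd.Series, spec: FeatureSelectionSpec = FeatureSelectionSpec()
) -> list[str]:
    """Retain features with |Pearson r| >= the univariate threshold against the outcome.

    Zero-variance features are excluded with a warning (their correlation is
    undefined).  Returns retained feature names in input order.
    """
    yv = y.to_numpy(dtype=float)
    if yv.std() == 0:
        raise ValidationError("outcome has a single class; univariate filter undefined")
    retained: list[str] = []
    degenerate: list[str] = []
    Xv = X.to_numpy(dtype=float)
    stds = Xv.std(axis=0)
    yc = yv - yv.mean()
    for j, name in enumerate(X.columns):
        if stds[j] < 1e-12:
            degenerate.append(str(name))
            continue
        xc = Xv[:, j] - Xv[:, j].mean()
        r = float(xc @ yc / (len(yc) * stds[j] * yv.std()))
        if abs(r) >= spec.univariate_min_abs_r:
            retained.append(str(name))
    if degenerate:
        warnings.warn(
            f"excluded {len(degenerate)} zero-variance feature(s), e.g. {degenerate[:3]}",
            stacklevel=2,
        )
    return retained


def redundancy_filter(
    X: pd.DataFrame, spec: FeatureSelectionSpec = FeatureSelectionSpec()
) -> list[str]:
    """Greedy pruning of mutually correlated features (pairwise |r| > threshold).

    While any pair exceeds the threshold, the member of the worst offending
    pair with the larger mean absolute correlation to all other surviving
    features is dropped (ties broken by lexicographically larger name), so
    the result is independent of column order.
    """
    if X.shape[1] < 2:
        return [str(c) for c in X.columns]
    cols = sorted(str(c) for c in X.columns)
    corr = X[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)  # zero-variance features correlate with nothing
    alive = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        worst = sub.max()
        if worst <= spec.pairwise_max_abs_r:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i_loc].sum() / (len(alive) - 1)
        mean_j = sub[j_loc].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            drop_loc = i_loc
        elif mean_j > mean_i:
            drop_loc = j_loc
        else:
            drop_loc = i_loc if cols[alive[i_loc]] > cols[alive[j_loc]] else j_loc
        alive.pop(drop_loc)
    survivors = {cols[i] for i in alive}
    return [str(c) for c in X.columns if str(c) in survivors]


def _elimination_order(
    X: np.ndarray, y: np.ndarray, names: list[str], spec: FeatureSelectionSpec, seed: int
) -> list[str]:
    """Recursive elimination ranking: repeatedly drop the least important
    quarter of surviving features under a Random Forest fit; returns names
    ordered best-first."""
    alive = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(alive) > 1:
        rf = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=seed, n_jobs=1
        ).fit(X[:, alive], y)
        imp = rf.feature_importances_
        n_drop = max(1, len(alive) // 4)
        order = np.argsort(imp)  # least important first; ties keep lower index
        for loc in sorted(order[:n_drop], reverse=True):
            eliminated.append(alive.pop(loc))
    ranking = alive + eliminated[::-1]  # best first
    return [names[i] for i in ranking]


def _candidate_sizes(n_features: int) -> list[int]:
    sizes = {1, n_features}
    s = n_features
    while s > 1:
        s = max(1, s // 2)
        sizes.add(s)
    return sorted(sizes)


def rfe_random_forest(
    X: pd.DataFrame, y: pd.Series, spec: FeatureSelectionSpec = FeatureSelectionSpec()
) -> MlResult:
    """Repeated cross-validated recursive feature elimination with Random Forest.

    Within each training fold, features are ranked by recursive elimination
    and a fresh forest is scored on the held-out fold for each candidate
    subset size; the size with the best mean accuracy (smaller on ties) is
    selected, and the final subset comes from re-ranking on the full data.
    Deterministic given ``spec.seed``.
    """
    names = [str(c) for c in X.columns]
    if not names:
        raise ValidationError("no features supplied to RFE")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=int)
    min_class = int(np.bincount(yv).min())
    if spec.n_folds > min_class:
        raise ValidationError(
            f"{spec.n_folds}-fold CV impossible with a class of {min_class} samples"
        )
    sizes = _candidate_sizes(len(names))
    cv = RepeatedStratifiedKFold(
        n_splits=spec.n_folds, n_repeats=spec.n_repeats, random_state=spec.seed
    )
    acc = {s: [] for s in sizes}
    for fold_i, (train, test) in enumerate(cv.split(Xv, yv)):
        ranked = _elimination_order(Xv[train], yv[train], names, spec, seed=spec.seed + fold_i)
        idx_of = {n: j for j, n in enumerate(names)}
        for s in sizes:
            top = [idx_of[n] for n in ranked[:s]]
            rf = RandomForestClassifier(
                n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
            ).fit(Xv[np.ix_(train, top)], yv[train])
            acc[s].append(rf.score(Xv[np.ix_(test, top)], yv[test]))
    accuracy_by_size = pd.Series({s: float(np.mean(v)) for s, v in acc.items()}).sort_index()
    best = accuracy_by_size.max()
    chosen_size = int(min(s for s, a in accuracy_by_size.items() if a >= best - 1e-12))

    full_rank = _elimination_order(Xv, yv, names, spec, seed=spec.seed)
    selected = tuple(full_rank[:chosen_size])
    sel_idx = [names.index(n) for n in selected]
    rf = RandomForestClassifier(
        n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
    ).fit(Xv[:, sel_idx], yv)
    importances = pd.Series(rf.feature_importances_, index=list(selected)).sort_values(
        ascending=False
    )
    return MlResult(
        selected_proteins=tuple(importances.index),
        importances=importances,
        accuracy_by_size=accuracy_by_size,
        chosen_size=chosen_size,
        n_folds=spec.n_folds,
        n_repeats=spec.n_repeats,
    )


def run_confirmation(
    matrix: QuantMatrix,
    meta: SampleMetadata,
    spec: FeatureSelectionSpec = FeatureSelectionSpec(),
    timepoint: str = "baseline",
) -> tuple[MlResult, dict]:
    """Full confirmation stage on an (already thresholded) matrix.

    zero-impute -> univariate filter -> redundancy filter -> RFE; returns the
    result plus a step-by-step feature-count trace.
    """
    X, y = build_feature_table(zero_impute(matrix), meta, timepoint=timepoint)
    uni = univariate_filter(X, y, spec)
    if len(uni) == 0:
        raise ValidationError("no features pass the univariate correlation filter")
    kept = redundancy_filter(X[uni], spec)
    result = rfe_random_forest(X[kept], y, spec)
    trace = {
        "n_input": X.shape[1],
        "n_after_univariate": len(uni),
        "n_after_redundancy": len(kept),
        "n_selected": len(result.selected_proteins),
    }
    return result, trace


def threshold_sweep(
    matrix: QuantMatrix,
    meta: SampleMetadata,
    thresholds: list[ThresholdSpec],
    spec: FeatureSelectionSpec = FeatureSelectionSpec(),
    timepoint: str = "baseline",
) -> pd.DataFrame:
    """Confirmation accuracy as a function of the observation threshold.

    For each threshold: filter proteins, zero-impute, run both correlation
    filters and RFE, and record the best mean CV accuracy and feature
    counts.  Thresholds leaving fewer than two usable features are reported
    as not evaluable.  When at least four thresholds are evaluable, the
    correlation between retained-feature count and accuracy is appended as
    frame attrs ``feature_count_accuracy_r`` (with CI) — a check that
    accuracy differences are not merely feature-count effects.
    """
    rows = []
    for t in thresholds:
        filtered, removed = apply_threshold(matrix, t)
        row = {
            "mode": t.mode,
            "value": t.value,
            "n_proteins_retained": filtered.n_proteins,
            "evaluable": True,
            "accuracy": np.nan,
            "chosen_size": np.nan,
        }
        try:
            if filtered.n_proteins < 2:
                raise ValidationError("fewer than 2 proteins retained")
            result, trace = run_confirmation(filtered, meta, spec, timepoint)
            row["accuracy"] = float(result.accuracy_by_size.max())
            row["chosen_size"] = result.chosen_size
            row["n_after_filters"] = trace["n_after_redundancy"]
        except ValidationError as exc:
            row["evaluable"] = False
            row["reason"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out[out["evaluable"]]
    if len(ok) >= 4 and ok["n_proteins_retained"].std() > 0 and ok["accuracy"].std() > 0:
        r = float(np.corrcoef(ok["n_proteins_retained"], ok["accuracy"])[0, 1])
        lo, hi = fisher_ci(r, len(ok))
        out.attrs["feature_count_accuracy_r"] = r
        out.attrs["feature_count_accuracy_ci"] = (lo, hi)
    return out
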