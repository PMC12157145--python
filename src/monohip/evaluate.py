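"""Validation machinery: Bland-Altman agreement, regression and
classification metrics, grouped and nested cross-validation, and report
generation.

Agreement between a predicted and a reference hip ROM is summarized the
Bland-Altman way: the systematic bias is the mean of the differences
(predicted minus reference), the limits of agreement (LoA) are
bias +/- 1.96 SD of the differences (sample SD, n-1 denominator), and the
validity criterion is a LoA range — upper minus lower limit — strictly
below a clinically motivated threshold of 27.8 degrees.

Cross-validation treats each participant-side (across all visits) as one
indivisible group, so a model is always evaluated on people it never saw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, f1_score

LOA_MULTIPLIER = 1.96


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    bias: float          # mean(predicted - reference), deg
    sd_diff: float       # sample SD of the differences, deg
    loa_low: float
    loa_high: float
    loa_range: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("bias", "sd_diff", "loa_low", "loa_high", "loa_range", "n")}

    def summary(self) -> str:
        return (f"bias {self.bias:+.2f} deg, "
                f"LoA [{self.loa_low:+.2f}, {self.loa_high:+.2f}] deg, "
                f"range {self.loa_range:.2f} deg (n = {self.n})")


@dataclass
class ValidityCriterion:
    """Maximum acceptable LoA range (deg)."""

    max_loa_range: float = 27.8

    def __post_init__(self) -> None:
        if self.max_loa_range <= 0:
            raise ValueError("max_loa_range must be positive")


def bland_altman(pred, ref) -> AgreementResult:
    """Bland-Altman agreement of predicted vs reference values.

    Differences are taken as predicted minus reference, so a measurement
    that underestimates shows a negative bias.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("pred and ref must be 1-D arrays of equal length")
    if len(p) < 3:
        raise ValueError("need at least 3 paired values")
    d = p - r
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = LOA_MULTIPLIER * sd
    return AgreementResult(bias=bias, sd_diff=sd, loa_low=bias - half,
                           loa_high=bias + half, loa_range=2.0 * half,
                           n=len(d))


def check_validity(res: AgreementResult,
                   crit: ValidityCriterion | float | None = None) -> bool:
    """Valid iff the LoA range is strictly below the criterion."""
    if crit is None:
        crit = ValidityCriterion()
    if not isinstance(crit, ValidityCriterion):
        crit = ValidityCriterion(float(crit))
    return res.loa_range < crit.max_loa_range


def ba_points(pred, ref) -> pd.DataFrame:
    """Mean-vs-difference pairs for Bland-Altman plotting."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    return pd.DataFrame({"mean": 0.5 * (p + r), "difference": p - r})


def plot_bland_altman(pred, ref, ax=None,
                      criterion: "ValidityCriterion | None" = None):
    """Mean-vs-difference scatter with bias and LoA lines.

    Returns the matplotlib axes; each point is one gait cycle."""
    import matplotlib.pyplot as plt

    res = bland_altman(pred, ref)
    pts = ba_points(pred, ref)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pts["mean"], pts["difference"], s=8, alpha=0.5)
    ax.axhline(res.bias, color="k", lw=1.2)
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of predicted and reference ROM (deg)")
    ax.set_ylabel("predicted - reference ROM (deg)")
    ax.set_title(res.summary(), fontsize=9)
    return ax


def regression_metrics(pred, ref) -> dict:
    """MAE, RMSE, R^2 (1 - SS_res/SS_tot) and Pearson R."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError("pred and ref must have the same shape")
    resid = p - r
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    pearson = (float(stats.pearsonr(p, r).statistic)
               if np.std(p) > 1e-12 and np.std(r) > 1e-12 else np.nan)
    return {"mae": float(np.mean(np.abs(resid))),
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
            "pearson_r": pearson}


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVSpec:
    outer_folds: int = 5
    inner_folds: int = 4
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")


def group_kfold(groups, k: int = 5, seed: int = 0
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-disjoint k-fold assignments, deterministic for a seed.

    Unique groups are canonically sorted, shuffled with the seed and split
    into k folds balanced to within one group; the result is therefore
    independent of the row order of the input.
    """
    groups = np.asarray(groups)
    uniq = np.array(sorted(set(groups.tolist())))
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} groups, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    folds = []
    for part in np.array_split(perm, k):
        test = np.isin(groups, part)
        folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
    return folds


def stratified_group_kfold(groups, classes, k: int = 5, seed: int = 0
                           ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-disjoint folds that approximately preserve class proportions.

    Backed by scikit-learn's StratifiedGroupKFold: groups are assigned to
    folds so that per-fold class shares deviate as little as possible from
    the global shares while never splitting a group.
    """
    from sklearn.model_selection import StratifiedGroupKFold

    groups = np.asarray(groups)
    classes = np.asarray(classes)
    if len(groups) != len(classes):
        raise ValueError("groups and classes must align")
    if len(set(groups.tolist())) < k:
        raise ValueError(
            f"need at least k={k} groups, got {len(set(groups.tolist()))}")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=seed)
    X_dummy = np.zeros((len(groups), 1))
    return [(np.asarray(tr), np.asarray(te))
            for tr, te in splitter.split(X_dummy, classes, groups)]


def audit_folds(folds, groups, n_rows: int) -> None:
    """Raise unless the folds are exhaustive, non-overlapping and
    group-disjoint."""
    groups = np.asarray(groups)
    all_test = np.concatenate([test for _, test in folds])
    if len(np.unique(all_test)) != len(all_test):
        raise ValueError("folds overlap")
    if len(all_test) != n_rows:
        raise ValueError("folds do not cover all rows")
    for train, test in folds:
        leak = set(groups[train]) & set(groups[test])
        if leak:
            raise ValueError(f"group leakage: {sorted(leak)}")


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _inner_loss(pred_or_proba: np.ndarray, y: np.ndarray, task: str
                ) -> float:
    if task == "regression":
        return float(np.mean((np.asarray(pred_or_proba, float) - y) ** 2))
    # sparse categorical cross-entropy over class probabilities
    proba = np.asarray(pred_or_proba, dtype=float)
    idx = np.asarray(y, dtype=int) - 1
    p = np.clip(proba[np.arange(len(idx)), idx], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


_SIZE_KEYS = ("units", "n_trees", "min_leaf")


def _grid_order(grid: list[dict]) -> list[dict]:
    """Stable-sort the grid so ties in inner loss resolve toward the
    smaller model (fewer units/trees, larger leaves last)."""
    def key(params: dict):
        return tuple(params.get(k, 0) for k in _SIZE_KEYS)
    return sorted(grid, key=key)


def nested_cv(model_factory, X, y, groups, grid: list[dict],
              spec: CVSpec | None = None, task: str = "regression",
              classes=None) -> dict:
    """Nested cross-validation with hyperparameter selection.

    `model_factory(params, X_train, y_train)` returns a fitted object with
    ``predict`` (and ``predict_proba`` for classification). For each outer
    fold a grid search over inner folds of the outer-training groups picks
    the hyperparameters with the lowest mean inner loss (MSE or sparse
    categorical cross-entropy); the winner is refitted on the full
    outer-training set and evaluated on the held-out fold. Test groups are
    never seen during tuning.

    Returns a dict with per-fold records and pooled out-of-fold
    predictions in the original row order.
    """
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    spec = spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    strat_classes = np.asarray(classes) if classes is not None else None

    if spec.stratified and strat_classes is not None:
        outer = stratified_group_kfold(groups, strat_classes,
                                       spec.outer_folds, spec.seed)
    else:
        outer = group_kfold(groups, spec.outer_folds, spec.seed)
    audit_folds(outer, groups, len(y))

    grid = _grid_order(list(grid))
    oof = np.full(len(y), np.nan)
    records = []
    for fold_i, (train_idx, test_idx) in enumerate(outer):
        Xtr, ytr, gtr = X[train_idx], y[train_idx], groups[train_idx]
        if spec.stratified and strat_classes is not None:
            inner = stratified_group_kfold(
                gtr, strat_classes[train_idx], spec.inner_folds, spec.seed)
        else:
            inner = group_kfold(gtr, spec.inner_folds, spec.seed)
        audit_folds(inner, gtr, len(ytr))

        best_params, best_loss = None, np.inf
        for params in grid:
            losses = []
            for itr, ite in inner:
                fitted = model_factory(params, Xtr[itr], ytr[itr])
                if task == "regression":
                    out = fitted.predict(Xtr[ite])
                else:
                    out = fitted.predict_proba(Xtr[ite])
                losses.append(_inner_loss(out, ytr[ite], task))
            mean_loss = float(np.mean(losses))
            if mean_loss < best_loss:  # strict: ties keep the smaller model
                best_loss, best_params = mean_loss, params
        fitted = model_factory(best_params, Xtr, ytr)
        pred = np.asarray(fitted.predict(X[test_idx]))
        oof[test_idx] = pred
        if task == "regression":
            metrics = regression_metrics(pred, y[test_idx])
        else:
            rep = classification_report(pred.astype(int),
                                        y[test_idx].astype(int))
            metrics = {"accuracy": rep.accuracy, "f1_macro": rep.f1_macro}
        records.append({"fold": fold_i, "params": best_params,
                        "inner_loss": best_loss, "metrics": metrics})
    return {"folds": records, "oof_pred": oof, "outer_folds": outer}


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassReport:
    confusion: np.ndarray      # rows reference, columns predicted
    accuracy: float
    f1_macro: float
    labels: tuple = (1, 2, 3)

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(),
                "accuracy": self.accuracy, "f1_macro": self.f1_macro,
                "labels": list(self.labels)}


def classification_report(class_pred, class_ref,
                          labels=(1, 2, 3)) -> ClassReport:
    """Confusion matrix (rows reference, columns predicted), accuracy and
    macro F1; a class absent from both sides contributes F1 = 0."""
    pred = np.asarray(class_pred)
    ref = np.asarray(class_ref)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference classes must align")
    conf = confusion_matrix(ref, pred, labels=list(labels))
    acc = float(np.trace(conf) / conf.sum()) if conf.sum() else np.nan
    f1 = float(f1_score(ref, pred, labels=list(labels), average="macro",
                        zero_division=0))
    return ClassReport(confusion=conf, accuracy=acc, f1_macro=f1,
                       labels=tuple(labels))


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------

@dataclass
class ModelEvaluation:
    name: str
    agreement: AgreementResult
    metrics: dict
    valid: bool
    class_report: ClassReport | None = None
    ba: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def report(evaluations: list[ModelEvaluation],
           criterion: ValidityCriterion | None = None
           ) -> tuple[dict, str]:
    """Bundle per-model agreement and metrics as JSON-ready dict plus a
    markdown table."""
    if not evaluations:
        raise ValueError("empty results bundle")
    crit = criterion or ValidityCriterion()
    payload = {"criterion_max_loa_range": crit.max_loa_range, "models": {}}
    lines = ["| model | bias (deg) | LoA low | LoA high | LoA range "
             "| MAE | R^2 | valid |",
             "|---|---|---|---|---|---|---|---|"]
    for ev in evaluations:
        a = ev.agreement
        payload["models"][ev.name] = {
            "agreement": a.to_dict(), "metrics": ev.metrics,
            "valid": bool(ev.valid), **(
                {"classification": ev.class_report.to_dict()}
                if ev.class_report else {}),
            **ev.extras}
        lines.append(
            f"| {ev.name} | {a.bias:+.2f} | {a.loa_low:+.2f} | "
            f"{a.loa_high:+.2f} | {a.loa_range:.2f} | "
            f"{ev.metrics.get('mae', float('nan')):.2f} | "
            f"{ev.metrics.get('r2', float('nan')):.3f} | "
            f"{'yes' if ev.valid else 'no'} |")
    return payload, "\n".join(lines)


def write_report(evaluations: list[ModelEvaluation], out_dir: str | Path,
                 criterion: ValidityCriterion | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload, md = report(evaluations, criterion)
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    (out / "report.md").write_text(md + "\n")
    for ev in evaluations:
        if ev.ba is not None:
            ev.ba.to_csv(out / f"ba_points_{ev.name}.csv", index=False)
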