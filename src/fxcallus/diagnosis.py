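"""Early non-union diagnosis from morphometric indices.

Ten indices per sample (avg CT of hematoma and cartilage, BS/TS of all four
tissues, BS/TV of mineralized cartilage and osteogenic tissue, BV/TV of
osteogenic and mineralized cartilage) feed four classifiers — SVM (RBF),
MLP, decision tree, random forest — evaluated per post-fracture day with
subject-grouped five-fold cross-validation. Features are standardized on
each training fold only; out-of-fold scores are pooled, and AUC, accuracy,
precision and F1 are computed from the pooled predictions with seeded
percentile-bootstrap intervals.

Day-1 samples are excluded by default: immediately after surgery the indices
are dominated by inter-individual variation rather than healing trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import ConfusionCounts, auc as auc_metric, bootstrap_ci, clf_metrics
from .phantom import FEATURE_NAMES

__all__ = ["MODEL_KINDS", "build_features", "run_diagnosis", "report_all"]

MODEL_KINDS = ("svm", "mlp", "decision_tree", "random_forest")

GROUP_LABELS = {"F": 0, "F+S": 1}

# pivot map: feature column -> (index kind, tissue) of the morphometry table
_FEATURE_SOURCES = {
    "avg_ct_hematoma": ("avg_ct_hu", "hematoma"),
    "avg_ct_cartilage": ("avg_ct_hu", "cartilage"),
    "bs_ts_hematoma": ("bs_ts_pct", "hematoma"),
    "bs_ts_cartilage": ("bs_ts_pct", "cartilage"),
    "bs_ts_mineralized": ("bs_ts_pct", "mineralized_cartilage"),
    "bs_ts_osteogenic": ("bs_ts_pct", "osteogenic"),
    "bs_tv_mineralized": ("bs_tv_per_mm", "mineralized_cartilage"),
    "bs_tv_osteogenic": ("bs_tv_per_mm", "osteogenic"),
    "bv_tv_osteogenic": ("bv_tv_pct", "osteogenic"),
    "bv_tv_mineralized": ("bv_tv_pct", "mineralized_cartilage"),
}


def build_features(
    records: pd.DataFrame,
    unit: str = "subject_day",
    include_day1: bool = False,
    include_tenth_index: bool = True,
) -> pd.DataFrame:
    """Pivot a long morphometry table into one feature row per sample.

    ``records`` has one row per (sample, tissue) with the morphometry columns
    (see :func:`fxcallus.morphometry.batch_morphometry`). ``unit`` is
    ``"subject_day"`` (one row per scan) or ``"slice"`` (requires a
    ``slice`` column carrying per-slice records). Missing tissue cells are
    mean-imputed within (group, day). The tenth index (BV/TV of mineralized
    cartilage) can be dropped to use the nine unambiguous indices only.
    """
    feature_names = list(FEATURE_NAMES)
    if not include_tenth_index:
        feature_names.remove("bv_tv_mineralized")
    keys = ["subject_id", "group", "day"]
    if unit == "slice":
        if "slice" not in records.columns:
            raise ValueError("unit='slice' requires per-slice records with a 'slice' column")
        keys = keys + ["slice"]
    elif unit != "subject_day":
        raise ValueError(f"unknown unit {unit!r}")

    rows = []
    for key_vals, grp in records.groupby(keys, sort=True):
        row = dict(zip(keys, key_vals))
        by_tissue = {t: sub.iloc[0] for t, sub in grp.groupby("tissue")}
        for fname in feature_names:
            col, tissue = _FEATURE_SOURCES[fname]
            row[fname] = by_tissue[tissue][col] if tissue in by_tissue else np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["label"] = frame["group"].map(GROUP_LABELS)
    if frame["label"].isna().any():
        raise ValueError("records contain groups other than F / F+S")
    if not include_day1:
        frame = frame[frame["day"] != 1].reset_index(drop=True)

    # mean imputation within (group, day) for undefined cells, logged via the count
    for fname in feature_names:
        if frame[fname].isna().any():
            frame[fname] = frame.groupby(["group", "day"])[fname].transform(
                lambda s: s.fillna(s.mean())
            )
    return frame


def _make_model(kind: str, seed: int):
    if kind == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=800, random_state=seed)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown model kind {kind!r} (expected one of {MODEL_KINDS})")


def _score(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def run_diagnosis(
    features: pd.DataFrame,
    model_kind: str,
    day: int | None = None,
    folds: int = 5,
    seed: int = 0,
    group_folds: bool = True,
    n_boot: int = 1000,
    feature_names: Sequence[str] | None = None,
) -> dict:
    """Cross-validated evaluation of one classifier on one day's samples.

    Folds are subject-grouped by default (no subject appears in two folds);
    ``group_folds=False`` gives plain stratified sample-level folds. Returns a
    report row with pooled AUC/accuracy/precision/F1, bootstrap intervals,
    fold assignments and the pooled confusion counts.
    """
    frame = features if day is None else features[features["day"] == day]
    frame = frame.reset_index(drop=True)
    if feature_names is None:
        feature_names = [f for f in FEATURE_NAMES if f in frame.columns]
    x = frame[list(feature_names)].to_numpy(dtype=np.float64)
    y = frame["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"day {day}: both classes must be present")
    if len(y) < folds:
        raise ValueError(f"day {day}: n={len(y)} smaller than {folds} folds")

    if group_folds:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        groups = frame["subject_id"].to_numpy()
        split_iter = splitter.split(x, y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(x, y)

    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    fold_of = np.full(len(y), -1, dtype=int)
    for fold, (tr, te) in enumerate(split_iter):
        scaler = StandardScaler().fit(x[tr])  # train-fold statistics only
        model = _make_model(model_kind, seed)
        model.fit(scaler.transform(x[tr]), y[tr])
        xs = scaler.transform(x[te])
        preds[te] = model.predict(xs)
        scores[te] = _score(model, xs)
        fold_of[te] = fold
    if (fold_of < 0).any():
        raise RuntimeError("cross-validation did not cover every sample")

    counts = ConfusionCounts.from_predictions(preds, y)
    point = clf_metrics(counts)
    auc_value = auc_metric(scores, y)

    rng = np.random.default_rng(seed)
    boot = {"auc": [], "accuracy": [], "precision": [], "f1": []}
    idx_all = np.arange(len(y))
    for _ in range(n_boot):
        idx = rng.choice(idx_all, size=len(y), replace=True)
        if len(np.unique(y[idx])) < 2:
            continue
        boot["auc"].append(auc_metric(scores[idx], y[idx]))
        m = clf_metrics(ConfusionCounts.from_predictions(preds[idx], y[idx]))
        boot["accuracy"].append(m.accuracy)
        boot["precision"].append(m.precision if m.precision is not None else np.nan)
        boot["f1"].append(m.f1 if m.f1 is not None else np.nan)

    def _ci(vals):
        vals = np.asarray(vals, dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return (float("nan"), float("nan"))
        return tuple(float(v) for v in np.percentile(vals, [2.5, 97.5]))

    auc_lo, auc_hi = _ci(boot["auc"])
    acc_lo, acc_hi = _ci(boot["accuracy"])
    prec_lo, prec_hi = _ci(boot["precision"])
    f1_lo, f1_hi = _ci(boot["f1"])
    return {
        "model": model_kind,
        "day": day,
        "auc": auc_value,
        "auc_lo": auc_lo,
        "auc_hi": auc_hi,
        "accuracy": point.accuracy,
        "acc_lo": acc_lo,
        "acc_hi": acc_hi,
        "precision": point.precision,
        "prec_lo": prec_lo,
        "prec_hi": prec_hi,
        "f1": point.f1,
        "f1_lo": f1_lo,
        "f1_hi": f1_hi,
        "n": int(len(y)),
        "folds": fold_of,
        "confusion": counts,
        "scores": scores,
        "predictions": preds,
        "labels": y,
        "seed": seed,
    }


def report_all(
    features: pd.DataFrame,
    models: Sequence[str] = MODEL_KINDS,
    days: Sequence[int] = (7, 14, 21, 28, 35),
    seed: int = 0,
    out_csv: str | Path | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Full per-(model, day) report; failed cells are kept as NA rows.

    The returned frame carries a ``best_cell`` attribute naming the
    (model, day) with the highest AUC.
    """
    rows = []
    for model in models:
        for day in days:
            try:
                row = run_diagnosis(features, model, day=day, seed=seed, **kwargs)
                rows.append({k: row[k] for k in (
                    "model", "day", "auc", "auc_lo", "auc_hi", "accuracy", "acc_lo", "acc_hi",
                    "precision", "prec_lo", "prec_hi", "f1", "f1_lo", "f1_hi",
                )})
            except ValueError:
                rows.append({"model": model, "day": day})
    frame = pd.DataFrame(rows)
    if frame["auc"].notna().any():
        best = frame.loc[frame["auc"].idxmax()]
        frame.attrs["best_cell"] = {"model": best["model"], "day": int(best["day"]), "auc": float(best["auc"])}
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
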