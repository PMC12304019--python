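"""Vigilance-state discrimination and PeEn/EoD agreement statistics.

A single entropy feature is scored with linear discriminant analysis
(LDA) under stratified 10-fold cross-validation; the point AUC is the
mean of the per-fold AUCs and the 95% confidence interval is the
normal approximation mean +/- 1.96 sd / sqrt(folds).  The classifier
"has an effect" iff 0.5 lies outside that interval.  Agreement between
the two entropy measures is quantified by the Pearson correlation of
their per-window values over jointly valid windows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .entropy import EntropySeries

__all__ = [
    "AUCResult",
    "lda_cv_auc",
    "pairwise_state_aucs",
    "measure_correlation",
    "correlation_by_recording",
    "downsample_majority",
]


@dataclass(frozen=True)
class AUCResult:
    """Cross-validated AUC of a one-feature LDA classifier."""

    auc: float
    ci_low: float
    ci_high: float
    fold_aucs: tuple
    n_pos: int
    n_neg: int
    seed: int

    @property
    def significant(self) -> bool:
        """True iff 0.5 is outside the 95% CI (p < 0.05 convention)."""
        return not (self.ci_low <= 0.5 <= self.ci_high)


def lda_cv_auc(feature, labels, folds: int = 10, seed: int = 0) -> AUCResult:
    """Stratified k-fold cross-validated AUC of one feature under LDA.

    Parameters
    ----------
    feature : array-like of float, shape (n,)
        Per-window entropy values (NaNs must be removed beforehand).
    labels : array-like, shape (n,)
        Binary state labels; the lexically larger label is the positive
        class.
    folds : int
        Number of stratified folds; reduced with a warning when the
        smaller class has fewer members than ``folds``.
    seed : int
        Fold-assignment seed; results are bit-identical per seed.
    """
    x = np.asarray(feature, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    if np.any(np.isnan(x)):
        raise ValueError("feature contains NaN; drop invalid windows first")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    y_bin = (y == classes[1]).astype(int)
    n_pos = int(y_bin.sum())
    n_neg = int(y_bin.size - n_pos)
    smallest = min(n_pos, n_neg)
    if smallest < 2:
        raise ValueError("each class needs at least 2 members")
    if smallest < folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds "
            f"{folds} -> {smallest}",
            stacklevel=2,
        )
        folds = smallest
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train, test in cv.split(x, y_bin):
        lda = LinearDiscriminantAnalysis()
        lda.fit(x[train], y_bin[train])
        scores = lda.decision_function(x[test])
        # orient the discriminant score along the ascending feature axis
        # so the AUC has a fixed orientation (P(feature_pos > feature_neg));
        # swapping class labels then maps auc -> 1 - auc
        if lda.coef_[0][0] < 0:
            scores = -scores
        fold_aucs.append(roc_auc_score(y_bin[test], scores))
    fold_aucs = np.asarray(fold_aucs)
    point = float(fold_aucs.mean())
    half_width = 1.96 * fold_aucs.std(ddof=1) / np.sqrt(folds)
    return AUCResult(
        auc=point,
        ci_low=float(max(0.0, point - half_width)),
        ci_high=float(min(1.0, point + half_width)),
        fold_aucs=tuple(float(a) for a in fold_aucs),
        n_pos=n_pos,
        n_neg=n_neg,
        seed=seed,
    )


def pairwise_state_aucs(
    features: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    value_column: str = "normalized",
) -> pd.DataFrame:
    """AUC for every unordered state pair, per measure and order.

    ``features`` is a feature table with columns ``label``, ``measure``,
    ``m`` and ``value_column`` (one row per valid window).  The output
    has one row per (state pair, measure, m) and mirrors the layout of
    per-order AUC tables; empty states are skipped with a warning.
    """
    required = {"label", "measure", "m", value_column}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    states = sorted(features["label"].dropna().unique())
    if len(states) < 2:
        raise ValueError(f"need >= 2 states, got {states}")
    rows = []
    for (measure, m), group in features.groupby(["measure", "m"]):
        for a, b in itertools.combinations(states, 2):
            sub = group[group["label"].isin([a, b])].dropna(subset=[value_column])
            counts = sub["label"].value_counts()
            if counts.get(a, 0) < 2 or counts.get(b, 0) < 2:
                warnings.warn(
                    f"state pair ({a}, {b}) has too few windows at "
                    f"measure={measure}, m={m}; skipped",
                    stacklevel=2,
                )
                continue
            res = lda_cv_auc(sub[value_column], sub["label"], folds=folds, seed=seed)
            rows.append(
                {
                    "state_a": a,
                    "state_b": b,
                    "measure": measure,
                    "m": m,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "significant": res.significant,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "seed": res.seed,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        # mark, per (pair, m), which measure scored higher — the bold-font
        # column of per-order comparison tables
        key = ["state_a", "state_b", "m"]
        out["higher_measure"] = out.groupby(key)["auc"].transform(
            lambda s: s.max() == s
        )
    return out


def measure_correlation(series_a: EntropySeries, series_b: EntropySeries) -> float:
    """Pearson correlation of two entropy series over jointly valid
    windows; NaN (flagged) when fewer than 3 windows are jointly valid."""
    if series_a.n_windows != series_b.n_windows:
        raise ValueError(
            f"series have {series_a.n_windows} vs {series_b.n_windows} windows"
        )
    joint = series_a.valid & series_b.valid
    if joint.sum() < 3:
        warnings.warn("fewer than 3 jointly valid windows; correlation undefined",
                      stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(series_a.normalized[joint], series_b.normalized[joint])
    return float(r)


def correlation_by_recording(
    features: pd.DataFrame, value_column: str = "normalized"
) -> pd.DataFrame:
    """Per-recording, per-order Pearson correlation between the two
    measures' window values, plus the cohort median as an extra row
    (recording_id = "__median__")."""
    rows = []
    for (rec, m), group in features.groupby(["recording_id", "m"]):
        pivot = group.pivot_table(
            index="window_index", columns="measure", values=value_column
        )
        if {"peen", "eod"} - set(pivot.columns) or len(pivot.dropna()) < 3:
            continue
        both = pivot.dropna()
        r, _ = stats.pearsonr(both["peen"], both["eod"])
        rows.append({"recording_id": rec, "m": m, "pearson_r": float(r)})
    out = pd.DataFrame(rows)
    if not out.empty:
        medians = out.groupby("m")["pearson_r"].median().reset_index()
        medians["recording_id"] = "__median__"
        out = pd.concat([out, medians], ignore_index=True)
    return out


def downsample_majority(labels, seed: int = 0) -> np.ndarray:
    """Indices balancing a binary label vector by randomly discarding
    majority-class entries (optional class-imbalance handling)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("downsample_majority expects binary labels")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(
        np.flatnonzero(y == majority), size=counts.min(), replace=False
    )
    idx = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_major]))
    return idx
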