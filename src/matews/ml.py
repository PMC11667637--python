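"""Marker-combination evaluation with statistical classifiers.

Protocol: hold out a test fraction with the outcome prevalence balanced
across the split, rank candidate markers by information gain against the
outcome, build nested feature subsets (prefixes of the ranking), and
cross-validate naive Bayes and logistic regression on the training part,
reporting fold-averaged sensitivity, specificity, false positive/negative
rates and AUROC per (classifier, subset size).

AUROC is the rank (Mann–Whitney) statistic — the probability that a random
positive case outranks a random negative one, ties counted one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB

from .cohort import PatientRecord, Severity, classify_severity

__all__ = [
    "MLProtocolConfig",
    "feature_table",
    "stratified_split",
    "information_gain",
    "rank_attributes",
    "auroc",
    "cross_validate",
]

#: Routine sepsis markers offered to the classifiers by default.
DEFAULT_MARKERS = (
    "heart_rate", "respiratory_rate", "temperature", "systolic_bp",
    "diastolic_bp", "spo2", "wbc", "lactate", "gcs",
)


@dataclass
class MLProtocolConfig:
    train_fraction: float = 0.8
    cv_folds: int = 10
    seed: int = 0
    classifiers: tuple[str, ...] = ("naive_bayes", "logistic_regression")
    ranking: str = "info_gain"
    n_bins: int = 10
    #: metric cut-offs used to nominate the "best" classifier rows
    selection_min_specificity: float = 0.90
    selection_min_auroc: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        unknown = set(self.classifiers) - {"naive_bayes", "logistic_regression"}
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


def feature_table(
    cohort: Sequence[PatientRecord],
    day: int = 0,
    markers: Sequence[str] = DEFAULT_MARKERS,
) -> pd.DataFrame:
    """One row per woman: marker values from the given day plus the SMO label."""
    rows = []
    for rec in cohort:
        obs = rec.days.get(day)
        row = {m: (np.nan if obs is None else _num(getattr(obs, m))) for m in markers}
        row["smo"] = int(classify_severity(rec) is Severity.SMO)
        rows.append(row)
    return pd.DataFrame(rows)


def _num(v):
    return np.nan if v is None else float(v)


def stratified_split(
    features: pd.DataFrame, labels: Sequence[int], cfg: MLProtocolConfig
):
    """Train/test split with label prevalence balanced across both parts."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to split")
    if counts.min() >= 2:
        X_tr, X_te, y_tr, y_te = train_test_split(
            features, y,
            train_size=cfg.train_fraction,
            stratify=y,
            random_state=cfg.seed,
            shuffle=True,
        )
        return X_tr, X_te, y_tr, y_te
    # degenerate classes (a single member): allocate per class by rounding
    rng = np.random.default_rng(cfg.seed)
    train_idx: list[int] = []
    for i, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        # alternate the rounding direction across classes so exact halves
        # spread over both parts instead of piling into one
        n_train = int(np.floor(cfg.train_fraction * len(idx) + (0.5 if i % 2 == 0 else 0.0) + 1e-9))
        train_idx.extend(idx[:n_train])
    mask = np.zeros(len(y), dtype=bool)
    mask[train_idx] = True
    return features.iloc[mask], features.iloc[~mask], y[mask], y[~mask]


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _discretise(x: pd.Series, n_bins: int) -> pd.Series:
    vals = x.dropna()
    if vals.nunique() <= n_bins:
        return x
    binned = pd.qcut(x, q=n_bins, duplicates="drop", labels=False)
    return binned


def information_gain(x: pd.Series, y: pd.Series, n_bins: int = 10) -> float:
    """Information gain of a feature against the label, in bits.

    Continuous features are discretised into equal-frequency bins; rows with
    a missing feature value are dropped (complete-case per feature).
    """
    mask = x.notna()
    x, y = x[mask], y[mask]
    if len(x) == 0:
        return 0.0
    xb = _discretise(x, n_bins)
    h_y = _entropy(y.value_counts().to_numpy())
    h_y_given_x = 0.0
    n = len(y)
    for _, idx in y.groupby(xb, observed=True).groups.items():
        sub = y.loc[idx]
        h_y_given_x += len(sub) / n * _entropy(sub.value_counts().to_numpy())
    return max(0.0, h_y - h_y_given_x)


def rank_attributes(
    features: pd.DataFrame, labels: Sequence[int], n_bins: int = 10
) -> list[str]:
    """Features ordered by decreasing information gain; ties and the
    constant-label case fall back to alphabetical order."""
    y = pd.Series(np.asarray(labels), index=features.index)
    gains = {c: information_gain(features[c], y, n_bins) for c in features.columns}
    return sorted(gains, key=lambda c: (-gains[c], c))


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney rank formulation."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _make_classifier(name: str, seed: int):
    if name == "naive_bayes":
        return GaussianNB()
    return LogisticRegression(max_iter=2000, random_state=seed)


def cross_validate(
    train_features: pd.DataFrame,
    train_labels: Sequence[int],
    cfg: MLProtocolConfig,
    ranked: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fold-averaged metrics per classifier and nested feature subset.

    Subsets are the prefixes of the information-gain ranking. Rows with a
    missing value in a subset are dropped for that subset (complete case).
    Folds where a class is absent from train or test are skipped with a
    warning and recorded in ``n_folds_skipped``.
    """
    y_all = pd.Series(np.asarray(train_labels), index=train_features.index)
    if ranked is None:
        ranked = rank_attributes(train_features, y_all, cfg.n_bins)
    rows = []
    for size in range(1, len(ranked) + 1):
        subset = list(ranked[:size])
        sub = train_features[subset].dropna()
        y = y_all.loc[sub.index]
        if y.nunique() < 2 or len(sub) < cfg.cv_folds:
            continue
        X = sub.to_numpy(dtype=float)
        yv = y.to_numpy()
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        for clf_name in cfg.classifiers:
            sens_l, spec_l, auc_l = [], [], []
            skipped = 0
            for tr_idx, te_idx in skf.split(X, yv):
                y_tr, y_te = yv[tr_idx], yv[te_idx]
                if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                    skipped += 1
                    warnings.warn(
                        f"{clf_name}/{size} features: fold with a single class skipped",
                        stacklevel=2,
                    )
                    continue
                clf = _make_classifier(clf_name, cfg.seed)
                clf.fit(X[tr_idx], y_tr)
                pred = clf.predict(X[te_idx])
                prob = clf.predict_proba(X[te_idx])[:, 1]
                tp = int(((pred == 1) & (y_te == 1)).sum())
                fn = int(((pred == 0) & (y_te == 1)).sum())
                tn = int(((pred == 0) & (y_te == 0)).sum())
                fp = int(((pred == 1) & (y_te == 0)).sum())
                sens_l.append(tp / (tp + fn))
                spec_l.append(tn / (tn + fp))
                auc_l.append(auroc(prob, y_te))
            if not sens_l:
                continue
            sens = float(np.mean(sens_l))
            spec = float(np.mean(spec_l))
            rows.append(
                {
                    "classifier": clf_name,
                    "n_features": size,
                    "features": "+".join(subset),
                    "n_rows": len(sub),
                    "sensitivity": sens,
                    "specificity": spec,
                    "fpr": 1.0 - spec,
                    "fnr": 1.0 - sens,
                    "auroc": float(np.mean(auc_l)),
                    "n_folds_used": len(sens_l),
                    "n_folds_skipped": skipped,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["selected"] = (
            (out["specificity"] >= cfg.selection_min_specificity)
            & (out["auroc"] >= cfg.selection_min_auroc)
        )
    return out
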