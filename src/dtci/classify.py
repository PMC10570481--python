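"""SVM classification of subjects from class-occupancy log-ratios.

Subjects are classified low vs high grade (or lower vs higher MIB-1 LI;
positive class = high grade / MIB-1 >= 5%) from their K smoothed log-ratio
features with a linear-kernel SVM (C = 1 by default; with N = 27 subjects
and K-dimensional features a linear margin is the conservative choice)
under leave-one-out cross-validation.  Features are standardized with
training-fold statistics only.  AUC is computed from the pooled held-out
decision values; sensitivity, specificity and accuracy from the pooled hard
predictions.

The LOOCV is repeated 100 times.  The pipeline is deterministic once the
clustering is fixed, so repetitions are made meaningful by re-seeding the
K-means++ partition of the fixed SOM per repetition and rebuilding the
features — callers pass a ``feature_builder(seed)`` for this; with a fixed
feature matrix all repetitions coincide and the CIs collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._common import derive_seed

__all__ = [
    "CVResult",
    "RocCurve",
    "loocv_once",
    "repeat_loocv",
    "sweep_k",
    "roc_with_ci",
    "auc_mann_whitney",
    "delong_variance",
]

METRICS = ("auc", "sensitivity", "specificity", "accuracy")


@dataclass
class CVResult:
    """Repeated-LOOCV metrics for one K and one grouping."""

    K: int
    grouping: str
    records: pd.DataFrame  # one row per repetition
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {
                m: {
                    "mean": float(self.records[m].mean()),
                    "ci_lower": float(np.percentile(self.records[m], 2.5)),
                    "ci_upper": float(np.percentile(self.records[m], 97.5)),
                }
                for m in METRICS
            }


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float
    method: str


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per group for LOOCV")
    return y


def auc_mann_whitney(decisions: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U probability: P(score+ > score-) + ties/2."""
    d = np.asarray(decisions, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = d[y == 1], d[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def loocv_once(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    kernel: str = "linear",
    seed: int = 0,
) -> dict:
    """One leave-one-out pass: per-subject decision values and pooled metrics."""
    X = np.asarray(features, dtype=float)
    y = _validate_labels(labels)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and labels must align")
    decisions = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.arange(n) != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(kernel=kernel, C=C, random_state=seed % (2**31))
        clf.fit(scaler.transform(X[tr]), y[tr])
        Xi = scaler.transform(X[i : i + 1])
        decisions[i] = clf.decision_function(Xi)[0]
        preds[i] = clf.predict(Xi)[0]
    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    return {
        "auc": auc_mann_whitney(decisions, y),
        "sensitivity": tp / (y == 1).sum(),
        "specificity": tn / (y == 0).sum(),
        "accuracy": (tp + tn) / n,
        "decisions": decisions,
        "predictions": preds,
        "seed": seed,
    }


FeatureBuilder = Callable[[int], np.ndarray]


def repeat_loocv(
    features: np.ndarray | FeatureBuilder,
    labels: np.ndarray,
    K: int,
    grouping: str = "who_grade",
    n_rep: int = 100,
    master_seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> CVResult:
    """Repeat LOOCV ``n_rep`` times and summarize metric distributions.

    ``features`` is either a fixed (n_subjects, K) matrix (all repetitions
    identical; degenerate CIs) or a callable ``builder(seed) -> matrix``
    that re-derives the features per repetition — the default pipeline
    passes a builder that re-runs K-means++ on the fixed SOM.  Summary CIs
    are 2.5/97.5 percentiles across repetitions.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2 to summarize a CI")
    y = _validate_labels(labels)
    rows = []
    for rep in range(n_rep):
        seed = derive_seed(master_seed, grouping, K, "rep", rep)
        X = features(seed) if callable(features) else np.asarray(features)
        rec = loocv_once(X, y, C=C, kernel=kernel, seed=seed)
        rows.append(
            {"repetition": rep, "seed": seed, **{m: rec[m] for m in METRICS},
             "decisions": rec["decisions"], "predictions": rec["predictions"]}
        )
    return CVResult(K=K, grouping=grouping, records=pd.DataFrame(rows))


def sweep_k(
    builders: Mapping[int, np.ndarray | FeatureBuilder],
    labels: np.ndarray,
    grouping: str = "who_grade",
    n_rep: int = 100,
    master_seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> tuple[dict[int, CVResult], pd.DataFrame]:
    """Run repeated LOOCV for every K; return results and a tidy AUC table.

    The table has one row per (K, repetition) with all four metrics — the
    input to the one-way ANOVA across the K sweep.
    """
    results: dict[int, CVResult] = {}
    rows = []
    for K in sorted(builders):
        res = repeat_loocv(
            builders[K], labels, K=K, grouping=grouping, n_rep=n_rep,
            master_seed=master_seed, C=C, kernel=kernel,
        )
        results[K] = res
        for _, r in res.records.iterrows():
            rows.append({"K": K, "repetition": int(r["repetition"]),
                         **{m: r[m] for m in METRICS}})
    return results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC with confidence intervals


def _delong_components(decisions: np.ndarray, labels: np.ndarray):
    d = np.asarray(decisions, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = d[y == 1], d[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    # structural components: V10[i] = P(pos_i > neg) est., V01[j] = P(pos > neg_j)
    cmp_ = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    auc = cmp_.mean()
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    return auc, v10, v01


def delong_variance(decisions: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimate from its structural components."""
    auc, v10, v01 = _delong_components(decisions, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_with_ci(
    decisions: np.ndarray,
    labels: np.ndarray,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 95.0,
) -> RocCurve:
    """Full ROC curve with an AUC confidence interval.

    ``method="delong"`` (default) uses the DeLong asymptotic variance;
    ``method="bootstrap"`` a stratified percentile bootstrap of subjects.
    The AUC equals the trapezoidal area under the returned curve.
    """
    y = np.asarray(labels).astype(int)
    d = np.asarray(decisions, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, thr = roc_curve(y, d)
    auc = auc_mann_whitney(d, y)
    alpha = 1.0 - ci / 100.0
    if method == "delong":
        se = np.sqrt(delong_variance(d, y))
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = auc - z * se, auc + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([pi, ni])
            aucs[b] = auc_mann_whitney(d[idx], y[idx])
        lo = float(np.percentile(aucs, 100 * alpha / 2))
        hi = float(np.percentile(aucs, 100 * (1 - alpha / 2)))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
        ci_lower=float(np.clip(lo, 0.0, 1.0)),
        ci_upper=float(np.clip(hi, 0.0, 1.0)),
        method=method,
    )
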