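"""DTcI label volumes, class-occupancy profiles, and class intensity profiles.

A DTcI (diffusion-tensor-based clustered image) relabels every in-scope
voxel with the class of its best-matching SOM node, turning six continuous
parameter maps into one categorical volume.  Per subject, the tumor-ROI
class occupancies (counts, ratios, smoothed log-ratios) form the K-vector
the SVM classifies.  Per class, the mean normalized intensity of each of
the six features — with a percentile-bootstrap CI — gives the radar-chart
signature of that tissue class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._common import FEATURES, N_FEATURES, logger
from .clustering import ClassPartition, SOMGrid, assign_voxel_classes, bmu_assign
from .features import ParameterMaps, TumorROI, VoxelFeatureMatrix

__all__ = [
    "DTcIVolume",
    "SubjectClassProfile",
    "ClassIntensityProfile",
    "build_dtci",
    "class_profile",
    "profiles_from_counts",
    "node_count_matrix",
    "class_counts_from_nodes",
    "class_intensity_profiles",
    "profiles_to_frame",
]

DEFAULT_EPSILON = 1e-3


@dataclass
class DTcIVolume:
    """Integer label volume: 0 outside the scope mask, 1..K inside."""

    subject_id: str
    labels: np.ndarray
    K: int
    scope: str

    def __post_init__(self) -> None:
        lab = np.unique(self.labels)
        if lab.min() < 0 or lab.max() > self.K:
            raise ValueError(f"DTcI labels must lie in 0..{self.K}")


@dataclass
class SubjectClassProfile:
    """Tumor-ROI class occupancy for one subject at one K."""

    subject_id: str
    K: int
    counts: np.ndarray
    ratios: np.ndarray
    log_ratios: np.ndarray
    total_voxels: int
    epsilon: float

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.total_voxels:
            raise ValueError("class counts must sum to total_voxels")
        if abs(self.ratios.sum() - 1.0) > 1e-9:
            raise ValueError("class ratios must sum to 1")


@dataclass
class ClassIntensityProfile:
    """Per-class mean normalized intensity of the six features, with CIs."""

    class_label: int
    mean: np.ndarray  # (6,)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_voxels: int

    @property
    def empty(self) -> bool:
        return self.n_voxels == 0


# ---------------------------------------------------------------------------
# DTcI volumes


def build_dtci(
    maps: ParameterMaps,
    grid: SOMGrid,
    partition: ClassPartition,
    scope: str = "brain",
    roi: TumorROI | None = None,
) -> DTcIVolume:
    """Label every in-scope voxel with the class of its best-matching unit.

    ``maps`` must be normalized with the same scheme the SOM was trained on
    (enforced by requiring a normalization record).
    """
    if maps.normalization is None:
        raise ValueError(
            f"subject {maps.subject_id}: DTcI requires normalized maps "
            "(normalization record missing)"
        )
    if scope == "brain":
        mask = maps.brain_mask
    elif scope == "roi":
        if roi is None:
            raise ValueError("scope='roi' requires a TumorROI")
        mask = roi.mask
    else:
        raise ValueError(f"scope must be 'brain' or 'roi', got {scope!r}")
    X = maps.feature_array(mask)
    labels = np.zeros(maps.shape, dtype=np.int16)
    labels[mask] = assign_voxel_classes(grid, partition, X)
    return DTcIVolume(maps.subject_id, labels, K=partition.K, scope=scope)


# ---------------------------------------------------------------------------
# Class-occupancy profiles


def _smoothed_log_ratios(counts: np.ndarray, total: int, K: int, epsilon: float) -> np.ndarray:
    # additive smoothing proportional to total so absent classes stay finite
    # and profiles are comparable across tumor sizes; at epsilon=0 an absent
    # class is -inf by definition (ln 0)
    with np.errstate(divide="ignore"):
        return np.log((counts + epsilon * total / K) / (total + epsilon * total))


def class_profile(
    dtci: DTcIVolume, roi: TumorROI, epsilon: float = DEFAULT_EPSILON
) -> SubjectClassProfile:
    """Class counts, ratios and smoothed log-ratios over the tumor ROI.

    ``log_ratios[k] = ln((counts[k] + eps*T/K) / (T + eps*T))`` with T the
    ROI voxel total; as ``epsilon -> 0`` this tends to ``ln(ratio)`` for
    occupied classes.
    """
    if roi.n_voxels == 0:
        raise ValueError(f"subject {roi.subject_id}: empty tumor ROI")
    in_roi = dtci.labels[roi.mask]
    if (in_roi == 0).any():
        raise ValueError(
            f"subject {roi.subject_id}: DTcI does not cover the whole ROI"
        )
    counts = np.bincount(in_roi, minlength=dtci.K + 1)[1:].astype(np.int64)
    total = int(counts.sum())
    return SubjectClassProfile(
        subject_id=dtci.subject_id,
        K=dtci.K,
        counts=counts,
        ratios=counts / total,
        log_ratios=_smoothed_log_ratios(counts, total, dtci.K, epsilon),
        total_voxels=total,
        epsilon=epsilon,
    )


def profiles_from_counts(
    counts: np.ndarray, subject_ids: list[str], K: int, epsilon: float = DEFAULT_EPSILON
) -> list[SubjectClassProfile]:
    """Build profiles from a precomputed (n_subjects, K) count matrix."""
    out = []
    for sid, c in zip(subject_ids, np.asarray(counts, dtype=np.int64)):
        total = int(c.sum())
        if total == 0:
            raise ValueError(f"subject {sid}: empty tumor ROI")
        out.append(
            SubjectClassProfile(
                subject_id=sid, K=K, counts=c, ratios=c / total,
                log_ratios=_smoothed_log_ratios(c, total, K, epsilon),
                total_voxels=total, epsilon=epsilon,
            )
        )
    return out


def node_count_matrix(grid: SOMGrid, matrix: VoxelFeatureMatrix) -> tuple[np.ndarray, list[str]]:
    """Per-subject BMU histogram over an ROI voxel pool.

    Returns an (n_subjects, n_nodes) count matrix and the subject order.
    The per-node histogram is partition-independent, so re-partitioning the
    same SOM (e.g. per LOOCV repetition) only needs a cheap regrouping.
    """
    bmu = bmu_assign(grid, matrix.X)
    sids = list(dict.fromkeys(matrix.subject_ids.tolist()))
    counts = np.zeros((len(sids), grid.n_nodes), dtype=np.int64)
    for i, sid in enumerate(sids):
        counts[i] = np.bincount(bmu[matrix.subject_ids == sid], minlength=grid.n_nodes)
    return counts, sids


def class_counts_from_nodes(
    node_counts: np.ndarray, partition: ClassPartition
) -> np.ndarray:
    """Regroup per-node counts into per-class counts (n_subjects, K)."""
    onehot = np.zeros((node_counts.shape[1], partition.K), dtype=np.int64)
    onehot[np.arange(node_counts.shape[1]), partition.node_to_class - 1] = 1
    return node_counts @ onehot


# ---------------------------------------------------------------------------
# Class intensity profiles (radar-chart data)


def class_intensity_profiles(
    X: np.ndarray,
    labels: np.ndarray,
    K: int,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 95.0,
    boot_max_voxels: int = 20000,
) -> list[ClassIntensityProfile]:
    """Per-class mean normalized intensity per feature with bootstrap CIs.

    ``labels`` (1..K) align with the rows of ``X``.  CIs are percentile
    bootstrap over voxel resamples (``n_boot`` replicates).  For classes
    larger than ``boot_max_voxels`` the CI (not the mean) is computed on a
    seeded subsample of that size; at that size the CI half-width is already
    below ~0.003 normalized-intensity units, so the truncation is
    negligible.  Classes with no member voxels are returned flagged empty
    (NaN means) so callers can exclude them from radar exports.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels must align with feature rows")
    rng = np.random.default_rng(seed)
    alpha = (100.0 - ci) / 2.0
    out = []
    for k in range(1, K + 1):
        Xk = X[labels == k]
        n = Xk.shape[0]
        if n == 0:
            logger.warning("class %d has no member voxels; profile flagged empty", k)
            nanv = np.full(N_FEATURES, np.nan)
            out.append(ClassIntensityProfile(k, nanv, nanv.copy(), nanv.copy(), 0))
            continue
        mean = Xk.mean(axis=0)
        Xb = Xk
        if n > boot_max_voxels:
            Xb = Xk[rng.choice(n, size=boot_max_voxels, replace=False)]
        nb = Xb.shape[0]
        boot_means = np.empty((n_boot, N_FEATURES))
        chunk = max(1, int(3e6 // max(nb, 1)))  # bound resample memory
        for start in range(0, n_boot, chunk):
            b = min(chunk, n_boot - start)
            idx = rng.integers(0, nb, size=(b, nb))
            boot_means[start : start + b] = Xb[idx].mean(axis=1)
        # recentre on the full-class mean (exact even when the CI uses a
        # subsample) and clamp so the interval always brackets the mean
        shift = mean - Xb.mean(axis=0)
        lo = np.minimum(np.percentile(boot_means, alpha, axis=0) + shift, mean)
        hi = np.maximum(np.percentile(boot_means, 100.0 - alpha, axis=0) + shift, mean)
        out.append(ClassIntensityProfile(k, mean, lo, hi, n))
    return out


# ---------------------------------------------------------------------------
# Tidy export


def profiles_to_frame(profiles: list[SubjectClassProfile]) -> pd.DataFrame:
    """Long-format table: (subject_id, K, class, count, ratio, log_ratio)."""
    rows = []
    for p in profiles:
        for k in range(p.K):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "K": p.K,
                    "class": k + 1,
                    "count": int(p.counts[k]),
                    "ratio": p.ratios[k],
                    "log_ratio": p.log_ratios[k],
                }
            )
    return pd.DataFrame(rows)


def intensity_profiles_to_frame(profiles: list[ClassIntensityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for j, f in enumerate(FEATURES):
            rows.append(
                {
                    "class": p.class_label,
                    "feature": f,
                    "mean": p.mean[j],
                    "ci_lower": p.ci_lower[j],
                    "ci_upper": p.ci_upper[j],
                    "n_voxels": p.n_voxels,
                }
            )
    return pd.DataFrame(rows)
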