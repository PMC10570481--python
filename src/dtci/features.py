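"""Parameter-map I/O, intensity normalization, and voxel-feature pooling.

The pipeline works on six co-registered scalar maps per subject — DWI, FA,
S0 (the b=0 T2 signal), and the tensor diffusivities MD, AD, RD — plus a
brain mask and a manually traced tumor ROI, all on one grid.  Because DWI
and S0 are in arbitrary scanner units, every feature is rescaled per
subject to [0, 1] before clustering; the default is percentile-clipped
min-max (p1–p99 within the brain mask).  Normalized in-mask voxels are then
pooled across subjects into the matrix the SOM trains on (``scope="brain"``)
or the tumor-only matrix the SVM features derive from (``scope="roi"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

from ._common import FA, FEATURES, MD, N_FEATURES, ROI_VOXEL_RANGE, logger

__all__ = [
    "ParameterMaps",
    "TumorROI",
    "VoxelFeatureMatrix",
    "read_subject",
    "write_subject",
    "normalize_features",
    "pool_voxels",
    "split_by_subject",
]

AFFINE_TOL = 1e-4


@dataclass
class ParameterMaps:
    """Six co-registered scalar volumes plus a brain mask for one subject.

    ``volumes`` is keyed by the canonical feature names in order
    (dwi, fa, s0, md, ad, rd).  ``normalization`` is None for raw maps and a
    per-feature parameter record after :func:`normalize_features`.
    """

    subject_id: str
    volumes: dict[str, np.ndarray]
    brain_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    normalization: dict | None = None

    def __post_init__(self) -> None:
        missing = [f for f in FEATURES if f not in self.volumes]
        if missing:
            raise ValueError(
                f"subject {self.subject_id}: missing parameter maps {missing}"
            )
        shape = self.brain_mask.shape
        for name, vol in self.volumes.items():
            if vol.shape != shape:
                raise ValueError(
                    f"subject {self.subject_id}: volume {name!r} shape {vol.shape} "
                    f"!= mask shape {shape}"
                )
        self.brain_mask = self.brain_mask.astype(bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.brain_mask.shape

    def feature_array(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack the six volumes into an (n_voxels, 6) array over ``mask``.

        Voxels are taken in C-order scan of the mask; columns follow the
        canonical feature order.
        """
        m = self.brain_mask if mask is None else mask.astype(bool)
        return np.column_stack([self.volumes[f][m] for f in FEATURES])


@dataclass
class TumorROI:
    subject_id: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = self.mask.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VoxelFeatureMatrix:
    """Pooled voxel features: one row per voxel, six normalized columns.

    ``subject_ids`` and ``ijk`` index each row back to (subject, voxel);
    row order is deterministic: subjects in input order, voxels in C-order.
    """

    X: np.ndarray
    subject_ids: np.ndarray  # (n,) str
    ijk: np.ndarray  # (n, 3) int
    normalization: dict[str, dict]  # subject_id -> record

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be (n, {N_FEATURES})")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if len(self.subject_ids) != len(self.X) or len(self.ijk) != len(self.X):
            raise ValueError("row index arrays must match feature matrix length")

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _paths_for(directory: Path, subject_id: str) -> dict[str, Path]:
    d = Path(directory)
    paths = {f: d / f"{subject_id}_{f}.nii" for f in FEATURES}
    paths["brain_mask"] = d / f"{subject_id}_brain_mask.nii"
    paths["roi"] = d / f"{subject_id}_roi.nii"
    return paths


def write_subject(
    maps: ParameterMaps, roi: TumorROI, directory: str | Path
) -> dict[str, Path]:
    """Write one subject's maps, brain mask and ROI as uncompressed NIfTI-1."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = _paths_for(directory, maps.subject_id)
    for f in FEATURES:
        img = nib.Nifti1Image(maps.volumes[f].astype(np.float32), maps.affine)
        nib.save(img, paths[f])
    nib.save(
        nib.Nifti1Image(maps.brain_mask.astype(np.uint8), maps.affine),
        paths["brain_mask"],
    )
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), maps.affine), paths["roi"])
    return paths


def read_subject(
    paths: Mapping[str, str | Path] | str | Path, subject_id: str | None = None
) -> tuple[ParameterMaps, TumorROI]:
    """Read one subject from NIfTI files.

    ``paths`` is either a mapping with keys (dwi, fa, s0, md, ad, rd,
    brain_mask, roi) or a directory written by :func:`write_subject`
    (``subject_id`` then required).  All images must share shape and affine
    (affine entries within 1e-4).
    """
    if not isinstance(paths, Mapping):
        if subject_id is None:
            raise ValueError("subject_id required when reading from a directory")
        paths = _paths_for(Path(paths), subject_id)
    missing = [k for k in (*FEATURES, "brain_mask", "roi") if k not in paths]
    if missing:
        raise FileNotFoundError(f"missing input paths: {missing}")
    imgs = {}
    for key, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"missing input file for {key!r}: {p}")
        imgs[key] = nib.load(str(p))

    ref = imgs[FEATURES[0]]
    for key, img in imgs.items():
        if img.shape[:3] != ref.shape[:3]:
            raise ValueError(
                f"grid mismatch for {key!r}: shape {img.shape} != {ref.shape}"
            )
        if np.abs(img.affine - ref.affine).max() > AFFINE_TOL:
            raise ValueError(f"grid mismatch for {key!r}: affines differ > {AFFINE_TOL}")

    sid = subject_id or Path(paths[FEATURES[0]]).name.split("_")[0]
    brain = np.asarray(imgs["brain_mask"].dataobj).astype(bool)
    roi_mask = np.asarray(imgs["roi"].dataobj).astype(bool)
    if (roi_mask & ~brain).any():
        raise ValueError(
            f"subject {sid}: tumor ROI extends outside the brain mask "
            f"({int((roi_mask & ~brain).sum())} voxels)"
        )
    volumes = {f: np.asarray(imgs[f].dataobj, dtype=np.float64) for f in FEATURES}
    maps = ParameterMaps(sid, volumes, brain, affine=np.asarray(ref.affine))
    roi = TumorROI(sid, roi_mask)
    n = roi.n_voxels
    logger.info("subject %s: %d brain voxels, %d ROI voxels", sid, brain.sum(), n)
    lo, hi = ROI_VOXEL_RANGE
    if not lo <= n <= hi:
        logger.warning(
            "subject %s: ROI has %d voxels, outside the expected range %d-%d",
            sid, n, lo, hi,
        )
    return maps, roi


# ---------------------------------------------------------------------------
# Normalization


def normalize_features(
    maps: ParameterMaps,
    method: str = "pminmax",
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> ParameterMaps:
    """Rescale each feature to [0, 1] per subject within the brain mask.

    ``pminmax`` (default): percentile-clipped min-max — values at or below
    the lower percentile map to 0, at or above the upper to 1.  ``zscore``:
    z-score within the mask, then a fixed logistic-free affine squeeze of
    ±3 SD onto [0, 1] (alternative scaling for comparison runs).

    FA is clipped to [0, 1] and negative diffusivities (possible in real
    tensor fits) are clipped to 0 before scaling; clip counts are logged.
    A feature that is constant within the mask maps to 0.5 with a warning.
    """
    mask = maps.brain_mask
    if not mask.any():
        raise ValueError(f"subject {maps.subject_id}: empty brain mask")
    record: dict = {"method": method, "percentiles": list(percentiles), "features": {}}
    out: dict[str, np.ndarray] = {}
    for idx, f in enumerate(FEATURES):
        vol = maps.volumes[f].astype(np.float64).copy()
        if idx == FA:
            n_clip = int(((vol < 0) | (vol > 1))[mask].sum())
            if n_clip:
                logger.info(
                    "subject %s: clipped %d FA voxels into [0,1]",
                    maps.subject_id, n_clip,
                )
            vol = np.clip(vol, 0.0, 1.0)
        elif idx >= MD:  # md, ad, rd: physically non-negative
            n_neg = int((vol[mask] < 0).sum())
            if n_neg:
                logger.info(
                    "subject %s: clipped %d negative %s voxels to 0",
                    maps.subject_id, n_neg, f,
                )
            vol = np.clip(vol, 0.0, None)
        inmask = vol[mask]
        if method == "pminmax":
            lo, hi = np.percentile(inmask, percentiles)
        elif method == "zscore":
            mu, sd = inmask.mean(), inmask.std()
            lo, hi = mu - 3.0 * sd, mu + 3.0 * sd
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        if hi <= lo:
            logger.warning(
                "subject %s: feature %s constant within mask; set to 0.5",
                maps.subject_id, f,
            )
            scaled = np.full_like(vol, 0.5)
            lo = hi = float(inmask[0])
        else:
            scaled = np.clip((vol - lo) / (hi - lo), 0.0, 1.0)
        scaled[~mask] = 0.0
        out[f] = scaled
        record["features"][f] = {"lo": float(lo), "hi": float(hi)}
    return ParameterMaps(
        maps.subject_id, out, mask, affine=maps.affine, normalization=record
    )


def save_normalization_record(maps_list: Iterable[ParameterMaps], path: str | Path) -> None:
    rec = {m.subject_id: m.normalization for m in maps_list}
    Path(path).write_text(json.dumps(rec, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Pooling


def pool_voxels(
    subjects: Sequence[tuple[ParameterMaps, TumorROI]],
    scope: str = "brain",
) -> VoxelFeatureMatrix:
    """Pool normalized in-mask voxels over subjects into one feature matrix.

    ``scope="brain"`` pools every brain-mask voxel (SOM training set, and
    support for whole-brain DTcIs); ``scope="roi"`` pools tumor-ROI voxels
    only (the SVM feature source).  Row order: subjects in input order,
    voxels in C-order scan — fixed so downstream seeds are meaningful.
    """
    if scope not in ("brain", "roi"):
        raise ValueError(f"scope must be 'brain' or 'roi', got {scope!r}")
    blocks, sids, ijks, records = [], [], [], {}
    for maps, roi in subjects:
        if maps.normalization is None:
            raise ValueError(
                f"subject {maps.subject_id}: normalize_features must run before pooling"
            )
        mask = maps.brain_mask if scope == "brain" else roi.mask
        X = maps.feature_array(mask)
        blocks.append(X)
        sids.append(np.repeat(maps.subject_id, X.shape[0]))
        ijks.append(np.argwhere(mask))
        records[maps.subject_id] = maps.normalization
    if not blocks or sum(b.shape[0] for b in blocks) == 0:
        raise ValueError(f"empty voxel pool for scope {scope!r}")
    return VoxelFeatureMatrix(
        X=np.vstack(blocks),
        subject_ids=np.concatenate(sids),
        ijk=np.vstack(ijks),
        normalization=records,
    )


def split_by_subject(matrix: VoxelFeatureMatrix) -> dict[str, np.ndarray]:
    """Inverse of pooling: per-subject feature blocks in pooled row order."""
    out: dict[str, np.ndarray] = {}
    for sid in dict.fromkeys(matrix.subject_ids.tolist()):
        out[sid] = matrix.X[matrix.subject_ids == sid]
    return out
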