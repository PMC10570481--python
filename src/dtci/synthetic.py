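"""Synthetic multiparameter-DTI cohort generator with planted ground truth.

The patient data behind this analysis is not publicly deposited, so the
package ships a generator that emulates its statistical structure: 27
subjects (19 low-grade vs 8 high-grade meningiomas; 18 vs 9 when split at a
MIB-1 labeling index of 5%), tumor ROIs of 100–17,463 voxels (drawn around
a mean of ~9,564), and six-feature voxel vectors (DWI, FA, S0, MD, AD, RD,
normalized intensities in [0, 1]) sampled from tissue-class archetypes.

Each subject's tumor is a mixture over a palette of archetypes; the two
diagnostic groups differ in their expected mixture — by default the
high-grade group carries extra weight on a "necrosis-like" archetype (low
DWI and FA, high S0/MD/AD/RD), the signature that distinguishes high-grade
tumors in this analysis.  Voxels are i.i.d. Gaussian around their archetype
mean: the pipeline is voxel-wise, so spatial texture is cosmetic and the ROI
is simply a compact ellipsoid inside a brain-mask blob.  Planted per-voxel
archetype labels and per-subject mixtures are returned for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._common import FEATURES, N_FEATURES, ROI_VOXEL_RANGE, VOXEL_SIZE_MM, derive_seed, logger
from .features import ParameterMaps, TumorROI, write_subject

__all__ = [
    "TissueArchetype",
    "SyntheticSubjectSpec",
    "SyntheticTruth",
    "SimulatedSubject",
    "make_archetype_palette",
    "necrosis_shift",
    "simulate_subject",
    "simulate_cohort",
    "simulate_null_profiles",
    "write_cohort",
]

#: ROI voxel-count distribution (mean, sd) matching the observed per-subject
#: feature counts; draws are truncated to ROI_VOXEL_RANGE.
ROI_SIZE_MEAN_SD = (9564.0, 4260.0)

#: brain mask volume as a multiple of the tumor ROI volume (normal-tissue
#: margin around the tumor; spatial realism is not the point of the phantom)
DEFAULT_BRAIN_FACTOR = 1.5

#: Dirichlet concentration for per-subject mixtures about their group mean
DEFAULT_CONCENTRATION = 60.0

#: default shift of mixture weight onto the necrosis-like archetype in the
#: high-grade / high-MIB-1 group ("strong" group contrast)
DEFAULT_SHIFT_MAGNITUDE = 0.25

_FIXED_DIRECTIONS = {
    # unit-norm displacement patterns in feature space (dwi, fa, s0, md, ad, rd)
    "normal-tissue": np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0]),
    "necrosis-like": np.array([-1.0, -1.0, 1.0, 1.0, 1.0, 1.0]) / np.sqrt(6.0),
    "dense-cellular": np.array([1.0, 0.0, 0.0, -1.0, -1.0, -1.0]) / 2.0,
}


@dataclass
class TissueArchetype:
    """One tissue-class signature: mean and noise scale per feature."""

    id: int
    mean: np.ndarray
    sd: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_FEATURES,) or self.sd.shape != (N_FEATURES,):
            raise ValueError("archetype mean and sd must be 6-vectors")
        if (self.mean < 0).any() or (self.mean > 1).any():
            raise ValueError("archetype mean components must lie in [0, 1]")
        if (self.sd < 0).any():
            raise ValueError("archetype sd components must be non-negative")


@dataclass
class SyntheticSubjectSpec:
    subject_id: str
    group: str  # "low" / "high"
    mixture_weights: np.ndarray
    n_tumor_voxels: int
    n_brain_voxels: int
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"subject {self.subject_id}: mixture weights must be a simplex vector"
            )
        self.mixture_weights = w
        lo, hi = ROI_VOXEL_RANGE
        if not lo <= self.n_tumor_voxels <= hi:
            raise ValueError(
                f"subject {self.subject_id}: n_tumor_voxels {self.n_tumor_voxels} "
                f"outside [{lo}, {hi}]"
            )
        if self.n_tumor_voxels > self.n_brain_voxels:
            raise ValueError(
                f"subject {self.subject_id}: n_tumor_voxels exceeds n_brain_voxels"
            )


@dataclass
class SimulatedSubject:
    spec: SyntheticSubjectSpec
    maps: ParameterMaps
    roi: TumorROI
    labels: np.ndarray  # planted archetype id per voxel; -1 outside brain


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    palette: list[TissueArchetype]
    mixture_weights: dict[str, np.ndarray]
    group_means: dict[str, np.ndarray]
    subject_seeds: dict[str, int]
    master_seed: int


# ---------------------------------------------------------------------------
# Archetype palette


def make_archetype_palette(
    n_archetypes: int = 6,
    separation: float = 0.5,
    seed: int = 0,
    noise: float = 0.05,
) -> list[TissueArchetype]:
    """Build a palette of tissue archetypes with controlled separation.

    Archetype means sit at ``0.5 + (separation/2) * u`` for unit direction
    vectors ``u`` chosen pairwise at least one unit apart, so for
    ``0 <= separation <= 1`` every pairwise mean distance is at least
    ``separation / 2`` and all means stay inside [0, 1].  The first three
    archetypes are fixed tissue signatures: ``normal-tissue`` (the designated
    non-tumor class), ``necrosis-like`` (low DWI/FA, high S0/MD/AD/RD) and
    ``dense-cellular`` (low diffusivities); the rest are seeded random
    directions.  ``separation=0`` is the degenerate case with all means at
    0.5.  ``noise`` sets each archetype's per-feature Gaussian sd.
    """
    if n_archetypes < 2:
        raise ValueError("n_archetypes must be at least 2")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    directions = [v.copy() for v in _FIXED_DIRECTIONS.values()]
    labels = list(_FIXED_DIRECTIONS.keys())
    min_dist, tries = 1.0, 0
    while len(directions) < n_archetypes:
        u = rng.standard_normal(N_FEATURES)
        u /= np.linalg.norm(u)
        if all(np.linalg.norm(u - v) >= min_dist for v in directions):
            directions.append(u)
            labels.append(f"signature-{len(directions) - 1}")
        else:
            tries += 1
            if tries > 200:  # relax packing if the sphere gets crowded
                min_dist *= 0.95
                tries = 0
    palette = []
    for i in range(n_archetypes):
        mean = np.clip(0.5 + 0.5 * separation * directions[i], 0.0, 1.0)
        palette.append(
            TissueArchetype(
                id=i, mean=mean, sd=np.full(N_FEATURES, noise), label=labels[i]
            )
        )
    return palette


def _normal_index(palette: Sequence[TissueArchetype]) -> int:
    for i, a in enumerate(palette):
        if a.label == "normal-tissue":
            return i
    return 0


def necrosis_shift(
    base_weights: np.ndarray,
    palette: Sequence[TissueArchetype],
    magnitude: float = DEFAULT_SHIFT_MAGNITUDE,
) -> np.ndarray:
    """Simplex-difference vector moving ``magnitude`` of weight onto the
    necrosis-like archetype, taken proportionally from the other classes."""
    base = np.asarray(base_weights, dtype=float)
    idx = next(i for i, a in enumerate(palette) if a.label == "necrosis-like")
    shift = np.zeros_like(base)
    others = np.arange(len(base)) != idx
    shift[idx] = magnitude
    shift[others] = -magnitude * base[others] / base[others].sum()
    return shift


def default_group_weights(palette: Sequence[TissueArchetype]) -> np.ndarray:
    """Low-grade group mean mixture: mostly solid-tumor signatures, a small
    normal-tissue partial-volume fraction and little necrosis."""
    n = len(palette)
    w = np.full(n, 0.9 / max(n - 2, 1))
    w[_normal_index(palette)] = 0.06
    nec = next(i for i, a in enumerate(palette) if a.label == "necrosis-like")
    w[nec] = 0.04
    return w / w.sum()


# ---------------------------------------------------------------------------
# Voxel geometry


def _compact_masks(n_tumor: int, n_brain: int) -> tuple[np.ndarray, np.ndarray]:
    """Nested compact masks: tumor = n_tumor voxels closest to the center in
    an anisotropic ellipsoidal metric, brain = n_brain closest (superset)."""
    axes = np.array([1.2, 1.0, 0.8])
    s = (3.0 * n_brain / (4.0 * np.pi * axes.prod())) ** (1.0 / 3.0)
    half = np.ceil(axes * s * 1.35).astype(int) + 1
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    r2 = sum((g / (a * s)) ** 2 for g, a in zip(grids, axes))
    flat = r2.ravel()
    order = np.argsort(flat, kind="stable")  # C-order tie-break
    if len(order) < n_brain:  # pragma: no cover - margin factor prevents this
        raise RuntimeError("candidate box too small for requested brain volume")
    shape = r2.shape
    brain = np.zeros(shape, dtype=bool)
    brain.ravel()[order[:n_brain]] = True
    tumor = np.zeros(shape, dtype=bool)
    tumor.ravel()[order[:n_tumor]] = True
    return tumor, brain


# ---------------------------------------------------------------------------
# Subject / cohort simulation


def simulate_subject(
    spec: SyntheticSubjectSpec, palette: Sequence[TissueArchetype]
) -> SimulatedSubject:
    """Draw one subject's six parameter volumes, masks and planted labels.

    Tumor voxels get archetypes multinomially from ``spec.mixture_weights``
    and values Gaussian around the archetype mean (clipped to [0, 1]);
    non-tumor brain voxels come from the normal-tissue archetype.  Fully
    reproducible from ``spec.seed``.
    """
    if len(palette) == 0:
        raise ValueError("palette must not be empty")
    if len(spec.mixture_weights) != len(palette):
        raise ValueError(
            f"subject {spec.subject_id}: mixture has {len(spec.mixture_weights)} "
            f"weights for a palette of {len(palette)}"
        )
    rng = np.random.default_rng(spec.seed)
    tumor, brain = _compact_masks(spec.n_tumor_voxels, spec.n_brain_voxels)
    labels = np.full(brain.shape, -1, dtype=np.int16)
    labels[brain] = _normal_index(palette)
    tumor_ids = rng.choice(
        len(palette), size=spec.n_tumor_voxels, p=spec.mixture_weights
    )
    labels[tumor] = tumor_ids

    means = np.stack([a.mean for a in palette])
    sds = np.stack([a.sd for a in palette])
    lab_in_brain = labels[brain]
    vals = means[lab_in_brain] + sds[lab_in_brain] * rng.standard_normal(
        (int(brain.sum()), N_FEATURES)
    )
    np.clip(vals, 0.0, 1.0, out=vals)

    affine = np.diag([VOXEL_SIZE_MM] * 3 + [1.0])
    volumes = {}
    for j, f in enumerate(FEATURES):
        vol = np.zeros(brain.shape, dtype=np.float64)
        vol[brain] = vals[:, j]
        volumes[f] = vol
    maps = ParameterMaps(spec.subject_id, volumes, brain, affine=affine)
    roi = TumorROI(spec.subject_id, tumor)
    return SimulatedSubject(spec=spec, maps=maps, roi=roi, labels=labels)


_LOW_SUBTYPES = ["meningothelial", "transitional", "fibrous", "psammomatous", "angiomatous"]
_LOW_SUBTYPE_P = np.array([12, 3, 2, 1, 1]) / 19.0
#: lognormal MIB-1 LI (%) parameters (mu, sigma of log) conditional on grade,
#: chosen so the 5% threshold misclassifies a few subjects in each direction
#: (groupings correlated but not identical)
_MIB1_LOGNORM = {"low": (np.log(2.0), 0.8), "high": (np.log(9.0), 0.9)}
_AGE_DIST = {"low": (59.5, 11.9), "high": (55.4, 19.5)}


def simulate_cohort(
    n_per_group: tuple[int, int] = (19, 8),
    group_weight_shift: np.ndarray | None = None,
    palette: Sequence[TissueArchetype] | None = None,
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
    brain_factor: float = DEFAULT_BRAIN_FACTOR,
    roi_size_range: tuple[int, int] | None = None,
) -> tuple[list[SimulatedSubject], pd.DataFrame, SyntheticTruth]:
    """Simulate a two-group cohort of subjects plus metadata and truth.

    Group "low" subjects have expected tumor mixture
    :func:`default_group_weights`; group "high" adds ``group_weight_shift``
    (default: :func:`necrosis_shift` of magnitude 0.25).  Per-subject
    mixtures are Dirichlet about the group mean with the given
    concentration.  ROI sizes are drawn from a truncated normal matching the
    observed per-subject voxel counts (``roi_size_range`` narrows the
    truncation for fast test runs).  The metadata table carries WHO grade,
    subtype, MIB-1 LI (lognormal conditional on grade, so the grade and
    MIB-1 groupings correlate without coinciding), age and sex.
    """
    palette = list(
        palette
        if palette is not None
        else make_archetype_palette(seed=derive_seed(seed, "palette"))
    )
    w_low = default_group_weights(palette)
    shift = (
        np.asarray(group_weight_shift, dtype=float)
        if group_weight_shift is not None
        else necrosis_shift(w_low, palette)
    )
    if shift.shape != w_low.shape or abs(shift.sum()) > 1e-9:
        raise ValueError("group_weight_shift must be a zero-sum vector over the palette")
    w_high = w_low + shift
    if (w_high < -1e-12).any() or (w_high > 1 + 1e-12).any():
        raise ValueError("group_weight_shift pushes a mixture weight outside [0, 1]")
    w_high = np.clip(w_high, 0.0, None)
    w_high /= w_high.sum()
    group_means = {"low": w_low, "high": w_high}

    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    lo, hi = roi_size_range if roi_size_range is not None else ROI_VOXEL_RANGE
    mu_n, sd_n = ROI_SIZE_MEAN_SD
    subjects: list[SimulatedSubject] = []
    rows = []
    truth_weights: dict[str, np.ndarray] = {}
    subject_seeds: dict[str, int] = {}
    i = 0
    for group, n_group in zip(("low", "high"), n_per_group):
        for _ in range(n_group):
            sid = f"sub-{i + 1:02d}"
            weights = rng.dirichlet(concentration * group_means[group])
            while True:  # truncated normal ROI size
                n_tumor = int(round(rng.normal(mu_n, sd_n)))
                if lo <= n_tumor <= hi:
                    break
            n_brain = int(np.ceil(n_tumor * brain_factor)) + 25
            sseed = derive_seed(seed, "subject", i)
            spec = SyntheticSubjectSpec(
                subject_id=sid,
                group=group,
                mixture_weights=weights,
                n_tumor_voxels=n_tumor,
                n_brain_voxels=n_brain,
                seed=sseed,
            )
            subjects.append(simulate_subject(spec, palette))
            truth_weights[sid] = weights
            subject_seeds[sid] = sseed

            if group == "low":
                who = "I"
                subtype = _LOW_SUBTYPES[rng.choice(len(_LOW_SUBTYPES), p=_LOW_SUBTYPE_P)]
            else:
                who = "III" if rng.random() < 0.25 else "II"
                subtype = "anaplastic" if who == "III" else "atypical"
            mu_m, sig_m = _MIB1_LOGNORM[group]
            mib1 = float(np.clip(rng.lognormal(mu_m, sig_m), 0.1, 60.0))
            mu_a, sd_a = _AGE_DIST[group]
            age = int(np.clip(round(rng.normal(mu_a, sd_a)), 24, 87))
            sex = "M" if rng.random() < 13 / 27 else "F"
            rows.append(
                {
                    "subject_id": sid,
                    "who_grade": who,
                    "subtype": subtype,
                    "mib1_li_percent": round(mib1, 1),
                    "age": age,
                    "sex": sex,
                    "grade_group": group,
                    "mib1_group": "ge5" if mib1 >= 5.0 else "lt5",
                }
            )
            i += 1
    cohort = pd.DataFrame(rows)
    truth = SyntheticTruth(
        palette=palette,
        mixture_weights=truth_weights,
        group_means=group_means,
        subject_seeds=subject_seeds,
        master_seed=seed,
    )
    logger.info(
        "simulated cohort: %d low + %d high grade, %d/%d MIB-1 split",
        n_per_group[0],
        n_per_group[1],
        (cohort.mib1_group == "lt5").sum(),
        (cohort.mib1_group == "ge5").sum(),
    )
    return subjects, cohort, truth


# ---------------------------------------------------------------------------
# Null profile generator (statistical calibration)


def simulate_null_profiles(
    n_cohorts: int,
    K: int,
    n_per_group: tuple[int, int] = (19, 8),
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
    epsilon: float = 1e-3,
):
    """Yield ``(log_ratio_matrix, labels)`` for exchangeable null cohorts.

    Per-subject class proportions are Dirichlet about a common mean and
    class counts multinomial over an ROI-sized voxel draw — the same
    count-generating process the voxel pipeline induces on class-occupancy
    profiles, with no group difference.  Used to calibrate the type-I error
    of the per-class tests without re-running the voxel-level pipeline per
    cohort.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(n_per_group)
    labels = np.array([0] * n_per_group[0] + [1] * n_per_group[1])
    mean = np.full(K, 1.0 / K)
    lo, hi = ROI_VOXEL_RANGE
    mu_n, sd_n = ROI_SIZE_MEAN_SD
    for _ in range(n_cohorts):
        F = np.empty((n_total, K))
        for s in range(n_total):
            p = rng.dirichlet(concentration * mean)
            while True:
                n_vox = int(round(rng.normal(mu_n, sd_n)))
                if lo <= n_vox <= hi:
                    break
            counts = rng.multinomial(n_vox, p)
            F[s] = np.log(
                (counts + epsilon * n_vox / K) / (n_vox + epsilon * n_vox)
            )
        yield F, labels


# ---------------------------------------------------------------------------
# On-disk cohort


def write_cohort(
    subjects: Sequence[SimulatedSubject],
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write per-subject NIfTI volumes, the cohort CSV, and the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        write_subject(sub.maps, sub.roi, directory)
    cohort_path = directory / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    truth_path = directory / "truth.json"
    truth_doc = {
        "master_seed": truth.master_seed,
        "palette": [
            {
                "id": a.id,
                "label": a.label,
                "mean": a.mean.tolist(),
                "sd": a.sd.tolist(),
            }
            for a in truth.palette
        ],
        "group_means": {g: w.tolist() for g, w in truth.group_means.items()},
        "mixture_weights": {s: w.tolist() for s, w in truth.mixture_weights.items()},
        "subject_seeds": truth.subject_seeds,
    }
    truth_path.write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return {"cohort": cohort_path, "truth": truth_path}
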