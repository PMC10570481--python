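"""Two-level clustering: batch SOM on pooled voxels, K-means++ on protoclusters.

Level one trains a rectangular self-organizing map (default 20x20 = 400
nodes, "protoclusters") on the pooled six-feature voxel vectors.  The SOM
quantizes and topologically orders the voxel cloud, filtering voxel noise
before the second level.  Level two partitions the 400 codebook vectors
with K-means (K-means++ seeding, best of 10 restarts) for each K in the
sweep, each node weighted by the number of voxels it won so that empty
corners of the map cannot dominate the partition.

Class labels 1..K are then canonically ordered by a composite diffusivity
score of the class centroid — mean(S0, MD, AD, RD) - mean(DWI, FA) — so
that the highest label is the free-water / necrosis-like end of the
spectrum (high diffusivity, low anisotropy) and labels are reproducible
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._common import AD, DWI, FA, FEATURES, MD, N_FEATURES, RD, S0, derive_seed, logger
from .features import VoxelFeatureMatrix

__all__ = [
    "SOMGrid",
    "ClassPartition",
    "ComponentPlanes",
    "train_som",
    "best_matching_unit",
    "bmu_assign",
    "node_voxel_counts",
    "cluster_protoclusters",
    "order_classes",
    "assign_voxel_classes",
    "export_component_planes",
]

_BMU_CHUNK = 65536


@dataclass
class SOMGrid:
    """Trained SOM: codebook plus grid topology and training metadata."""

    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, 6)
    seed: int
    epochs: int
    quantization_errors: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.codebook.shape != (self.rows * self.cols, N_FEATURES):
            raise ValueError("codebook shape must be (rows*cols, 6)")
        if not np.isfinite(self.codebook).all():
            raise ValueError("codebook contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_coordinates(self) -> np.ndarray:
        """(n_nodes, 2) grid coordinates, row-major node indexing."""
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c]).astype(float)

    @property
    def quantization_error(self) -> float:
        return self.quantization_errors[-1] if self.quantization_errors else np.nan


@dataclass
class ClassPartition:
    """Protocluster-to-class map for one K with canonical ordering applied."""

    K: int
    node_to_class: np.ndarray  # (n_nodes,) labels in 1..K
    class_centroids: np.ndarray  # (K, 6)
    seed: int
    wcss: float
    ordering: str = "diffusivity-score"

    def __post_init__(self) -> None:
        labels = np.unique(self.node_to_class)
        if not np.array_equal(labels, np.arange(1, self.K + 1)):
            raise ValueError(
                f"partition must use every label 1..{self.K} exactly; got {labels}"
            )


@dataclass
class ComponentPlanes:
    """Per-feature codebook values on the node grid, plus the class map."""

    planes: dict[str, np.ndarray]  # feature -> (rows, cols)
    class_map: np.ndarray  # (rows, cols) labels 1..K


# ---------------------------------------------------------------------------
# SOM


def _bmu_indices(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Index of the nearest codebook row for each row of X (ties -> lowest)."""
    n = X.shape[0]
    out = np.empty(n, dtype=np.int64)
    c_sq = np.einsum("ij,ij->i", codebook, codebook)
    for start in range(0, n, _BMU_CHUNK):
        chunk = X[start : start + _BMU_CHUNK]
        # squared distance up to a per-row constant; argmin is tie-stable
        d = c_sq[None, :] - 2.0 * (chunk @ codebook.T)
        out[start : start + _BMU_CHUNK] = np.argmin(d, axis=1)
    return out


def _bmu_indices_f32(codebook: np.ndarray, X32: np.ndarray) -> np.ndarray:
    """Single-precision BMU search used inside SOM training epochs only.

    Halves the memory traffic of the dominant distance computation; the
    codebook update itself stays double precision.  Deterministic for a
    given input, like the double-precision path.
    """
    c32 = codebook.astype(np.float32)
    n = X32.shape[0]
    out = np.empty(n, dtype=np.int64)
    c_sq = np.einsum("ij,ij->i", c32, c32)
    for start in range(0, n, _BMU_CHUNK):
        chunk = X32[start : start + _BMU_CHUNK]
        d = c_sq[None, :] - np.float32(2.0) * (chunk @ c32.T)
        out[start : start + _BMU_CHUNK] = np.argmin(d, axis=1)
    return out


def train_som(
    features: VoxelFeatureMatrix | np.ndarray,
    rows: int = 20,
    cols: int = 20,
    epochs: int = 50,
    seed: int = 0,
    tuning_epochs: int | None = None,
) -> SOMGrid:
    """Train a batch SOM with a Gaussian neighborhood on the voxel pool.

    The neighborhood radius shrinks linearly from ``max(rows, cols)/2`` to 1
    over the ``epochs`` ordering phase; a fine-tuning tail of
    ``tuning_epochs`` (default ``max(5, epochs // 5)``) then runs with a
    vanishing neighborhood, i.e. plain Lloyd updates of the codebook, which
    sharpen each protocluster onto its own data and cannot increase the
    quantization error.  The codebook is initialized by sampling input rows
    (without replacement when possible) under ``seed``; training is then
    deterministic given the seed and input row order.  The mean distance of
    each input to its best-matching unit (quantization error) is recorded
    per epoch.
    """
    X = features.X if isinstance(features, VoxelFeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"input must be (n, {N_FEATURES})")
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot train SOM on an empty voxel pool")
    n_nodes = rows * cols
    if n < n_nodes:
        logger.warning(
            "SOM input has %d vectors for %d nodes; codebook will be redundant",
            n, n_nodes,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=n_nodes, replace=n < n_nodes)
    codebook = X[init_idx].astype(np.float64).copy()

    coords = np.column_stack(np.divmod(np.arange(n_nodes), cols)).astype(float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    if tuning_epochs is None:
        tuning_epochs = max(5, epochs // 5)
    r_max = max(rows, cols) / 2.0
    X32 = X.astype(np.float32)
    qerrors: list[float] = []
    for epoch in range(epochs + tuning_epochs):
        bmu = _bmu_indices_f32(codebook, X32)
        qerrors.append(float(np.linalg.norm(X - codebook[bmu], axis=1).mean()))
        sums = np.column_stack(
            [np.bincount(bmu, weights=X[:, j], minlength=n_nodes)
             for j in range(N_FEATURES)]
        )
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        if epoch < epochs:
            frac = epoch / max(epochs - 1, 1)
            sigma = r_max + (1.0 - r_max) * frac  # linear decay r_max -> 1
            # batch update: weighted mean of inputs under the kernel
            h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # (nodes, nodes)
            numer = h @ sums
            denom = h @ counts
        else:  # tuning tail: Lloyd step (neighborhood -> 0)
            numer = sums
            denom = counts
        nonzero = denom > 0
        codebook[nonzero] = numer[nonzero] / denom[nonzero, None]
    # dead-unit resolution: a node that wins no voxel after fine-tuning would
    # keep an interpolated position between tissue clusters and stand for no
    # observed tissue; snap each such node onto its nearest observed voxel
    bmu = _bmu_indices_f32(codebook, X32)
    dead = np.flatnonzero(np.bincount(bmu, minlength=n_nodes) == 0)
    if dead.size:
        d = ((X[:, None, :] - codebook[None, dead, :]) ** 2).sum(axis=2) \
            if n * dead.size <= 5_000_000 else None
        if d is not None:
            codebook[dead] = X[np.argmin(d, axis=0)]
        else:  # chunk over data rows for large pools
            best = np.full(dead.size, np.inf)
            best_idx = np.zeros(dead.size, dtype=np.int64)
            for start in range(0, n, _BMU_CHUNK):
                chunk = X[start : start + _BMU_CHUNK]
                dc = ((chunk[:, None, :] - codebook[None, dead, :]) ** 2).sum(axis=2)
                cmin = dc.min(axis=0)
                upd = cmin < best
                best_idx[upd] = start + np.argmin(dc, axis=0)[upd]
                best[upd] = cmin[upd]
            codebook[dead] = X[best_idx]
    # final quantization error after the last update
    bmu = _bmu_indices(codebook, X)
    qerrors.append(float(np.linalg.norm(X - codebook[bmu], axis=1).mean()))
    return SOMGrid(
        rows=rows, cols=cols, codebook=codebook, seed=seed, epochs=epochs,
        quantization_errors=qerrors,
    )


def best_matching_unit(grid: SOMGrid, vector: np.ndarray) -> int:
    """Node index of the codebook row nearest ``vector`` (ties -> lowest)."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (N_FEATURES,):
        raise ValueError(f"vector must have {N_FEATURES} components")
    if not np.isfinite(v).all():
        raise ValueError("vector must be finite")
    d = np.linalg.norm(grid.codebook - v, axis=1)
    return int(np.argmin(d))


def bmu_assign(grid: SOMGrid, X: np.ndarray) -> np.ndarray:
    """Vectorized BMU assignment for an (n, 6) array."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("input vectors must be finite")
    return _bmu_indices(grid.codebook, X)


def node_voxel_counts(grid: SOMGrid, X: np.ndarray) -> np.ndarray:
    """Number of voxels of ``X`` mapped to each node (KM++ node weights)."""
    return np.bincount(bmu_assign(grid, X), minlength=grid.n_nodes).astype(float)


# ---------------------------------------------------------------------------
# K-means++ on protoclusters


def cluster_protoclusters(
    grid: SOMGrid,
    K: int,
    seed: int = 0,
    node_weights: np.ndarray | None = None,
    n_init: int = 10,
    max_restarts: int = 20,
) -> ClassPartition:
    """Partition the codebook into K classes with weighted K-means++.

    Runs K-means (K-means++ seeding, ``n_init`` restarts, best by weighted
    within-class sum of squares) on the 400 codebook vectors, each weighted
    by its mapped-voxel count when ``node_weights`` is given.  If a run ever
    returns an empty class it is retried with a derived seed (up to
    ``max_restarts``).  Labels are canonically ordered on return.
    """
    n_distinct = np.unique(grid.codebook, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(
            f"K={K} exceeds the {n_distinct} distinct codebook vectors"
        )
    if node_weights is not None:
        node_weights = np.asarray(node_weights, dtype=float)
        if node_weights.shape != (grid.n_nodes,):
            raise ValueError("node_weights must have one entry per node")
        if (node_weights < 0).any() or node_weights.sum() <= 0:
            raise ValueError("node_weights must be non-negative with positive sum")
    for attempt in range(max_restarts):
        km_seed = seed if attempt == 0 else derive_seed(seed, "km-retry", attempt)
        km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                    random_state=km_seed % (2**31))
        labels0 = km.fit_predict(grid.codebook, sample_weight=node_weights)
        if len(np.unique(labels0)) == K:
            break
    else:  # pragma: no cover - KMeans relocates empty clusters itself
        raise RuntimeError(f"K-means produced an empty class in {max_restarts} attempts")
    partition = ClassPartition(
        K=K,
        node_to_class=labels0 + 1,
        class_centroids=km.cluster_centers_.copy(),
        seed=seed,
        wcss=float(km.inertia_),
        ordering="unordered",
    )
    return order_classes(partition, grid)


def _ordering_scores(centroids: np.ndarray) -> np.ndarray:
    return centroids[:, [S0, MD, AD, RD]].mean(axis=1) - centroids[:, [DWI, FA]].mean(
        axis=1
    )


def order_classes(partition: ClassPartition, grid: SOMGrid) -> ClassPartition:
    """Relabel classes so the label increases with the diffusivity score.

    Score = centroid mean over (S0, MD, AD, RD) minus mean over (DWI, FA);
    the top label is therefore the high-diffusivity / low-anisotropy
    (necrosis-like) end.  Ties break by centroid MD, then RD.  Idempotent
    and invariant to the input labeling.
    """
    c = partition.class_centroids
    score = _ordering_scores(c)
    # lexsort: last key is primary
    order = np.lexsort((c[:, RD], c[:, MD], score))
    # order[i] = old (0-based) class that receives new label i+1
    new_label_of_old = np.empty(partition.K, dtype=np.int64)
    new_label_of_old[order] = np.arange(1, partition.K + 1)
    return ClassPartition(
        K=partition.K,
        node_to_class=new_label_of_old[partition.node_to_class - 1],
        class_centroids=c[order],
        seed=partition.seed,
        wcss=partition.wcss,
        ordering="diffusivity-score",
    )


def assign_voxel_classes(
    grid: SOMGrid, partition: ClassPartition, X: np.ndarray
) -> np.ndarray:
    """Class labels (1..K) for voxel vectors via their best-matching units."""
    return partition.node_to_class[bmu_assign(grid, X)]


# ---------------------------------------------------------------------------
# Component planes


def export_component_planes(grid: SOMGrid, partition: ClassPartition) -> ComponentPlanes:
    """Six per-feature codebook heat maps plus the node->class matrix."""
    planes = {
        f: grid.codebook[:, j].reshape(grid.rows, grid.cols)
        for j, f in enumerate(FEATURES)
    }
    class_map = partition.node_to_class.reshape(grid.rows, grid.cols)
    return ComponentPlanes(planes=planes, class_map=class_map)


def plot_component_planes(
    planes: ComponentPlanes, path: str | None = None
):  # pragma: no cover - cosmetic
    """Render the six component planes with class borderlines (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 8))
    for ax, (name, plane) in zip(axes.ravel(), planes.planes.items()):
        ax.imshow(plane, cmap="jet", vmin=0, vmax=1)
        ax.set_title(name.upper())
        cm = planes.class_map
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1] - 1):
                if cm[i, j] != cm[i, j + 1]:
                    ax.plot([j + 0.5, j + 0.5], [i - 0.5, i + 0.5], color="w", lw=0.8)
        for i in range(cm.shape[0] - 1):
            for j in range(cm.shape[1]):
                if cm[i, j] != cm[i + 1, j]:
                    ax.plot([j - 0.5, j + 0.5], [i + 0.5, i + 0.5], color="w", lw=0.8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    plt.close(fig)
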