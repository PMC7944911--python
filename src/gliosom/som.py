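"""Two-level clustering: batch self-organizing map, then K-means.

Level one quantizes the cohort voxel cloud with a rectangular batch SOM
whose nodes (default 20 x 20 = 400) act as protoclusters.  Each batch epoch
assigns every input vector to its best-matching unit (BMU) and replaces
every node weight by the Gaussian-neighborhood-weighted mean of all inputs,
with the neighborhood radius shrinking from half the grid diagonal to 1.
Level two groups the 400 protocluster weight vectors into K classes with
K-means (k-means++, best of several restarts); the allowed K values default
to {4, 6, 8, 10, 12, 16, 20}.

Distances are unweighted Euclidean in the normalized 6-D intensity space at
both levels.  Class ids are relabeled in decreasing order of cluster size so
partition labels are deterministic and comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .preprocess import VoxelFeatureMatrix

DEFAULT_GRID = (20, 20)
DEFAULT_EPOCHS = 50
DEFAULT_K_SET = (4, 6, 8, 10, 12, 16, 20)
DEFAULT_RESTARTS = 10


@dataclass
class SOMModel:
    """Fitted SOM: grid geometry plus one weight vector per node.

    ``weights`` is (rows*cols, n_features) in row-major node order, so node
    ``(i, j)`` lives at row ``i * cols + j``.
    """

    grid_shape: tuple[int, int]
    weights: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        rows, cols = self.grid_shape
        if self.weights.shape[0] != rows * cols:
            raise ValueError(
                f"weights rows ({self.weights.shape[0]}) must equal rows*cols ({rows * cols})"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("SOM weights must be finite")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def node_coordinates(self) -> np.ndarray:
        rows, cols = self.grid_shape
        ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel()])


@dataclass
class ProtoclusterPartition:
    """K-class labeling of the protoclusters (labels are 1-based)."""

    K: int
    labels: np.ndarray
    centroids: np.ndarray
    kmeans_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in 1..K")
        if len(np.unique(self.labels)) != self.K:
            raise ValueError("every class must be non-empty")


def _as_input_matrix(features: VoxelFeatureMatrix | np.ndarray) -> np.ndarray:
    """Accept a VoxelFeatureMatrix or a raw channel-major array; return (N, d)."""
    values = features.values if isinstance(features, VoxelFeatureMatrix) else np.asarray(features, dtype=float)
    if values.ndim != 2:
        raise ValueError("features must be a 2-D channel-by-voxel matrix")
    return values.T


def _grid_distance_sq(grid_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = grid_shape
    coords = np.column_stack(
        [np.repeat(np.arange(rows), cols), np.tile(np.arange(cols), rows)]
    ).astype(float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sum(diff**2, axis=-1)


def _linear_init(X: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Initialize weights on the plane of the first two principal components.

    Node (i, j) is placed at mean + a_i * 2*sd1 * pc1 + b_j * 2*sd2 * pc2 with
    a, b spanning [-1, 1] over the grid.  Degenerate directions (zero
    variance) collapse to the mean, which is the correct fixed point.
    """
    rows, cols = grid_shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; directions with ~zero singular value contribute nothing
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n = max(X.shape[0] - 1, 1)
    sd = s / np.sqrt(n)
    axes = np.zeros((2, X.shape[1]))
    for k in range(min(2, vt.shape[0])):
        if sd[k] > 0:
            axes[k] = 2.0 * sd[k] * vt[k]
    a = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.zeros(1)
    b = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.zeros(1)
    w = mean[None, None, :] + a[:, None, None] * axes[0] + b[None, :, None] * axes[1]
    return w.reshape(rows * cols, X.shape[1])


def train_som(
    features: VoxelFeatureMatrix | np.ndarray,
    grid_shape: tuple[int, int] = DEFAULT_GRID,
    epochs: int = DEFAULT_EPOCHS,
    initial_radius: float | None = None,
    final_radius: float = 1.0,
    seed: int = 0,
) -> SOMModel:
    """Fit a batch SOM to the stacked voxel features.

    The neighborhood is Gaussian on the grid with radius decaying linearly
    from ``initial_radius`` (default: half the grid diagonal) to
    ``final_radius`` across epochs.  Training is fully deterministic given
    the inputs (PCA initialization, batch updates); the seed is recorded in
    the metadata for provenance.
    """
    X = _as_input_matrix(features)
    if np.any(~np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    rows, cols = grid_shape
    n_nodes = rows * cols
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"{X.shape[0]} input vectors cannot train {n_nodes} nodes; "
            "use a smaller grid"
        )
    if initial_radius is None:
        initial_radius = 0.5 * float(np.hypot(rows, cols))

    weights = _linear_init(X, grid_shape)
    d2_grid = _grid_distance_sq(grid_shape)
    qe_init = _quantization_error_raw(weights, X)

    sq_x = np.sum(X**2, axis=1)
    for epoch in range(epochs):
        t = epoch / max(epochs - 1, 1)
        sigma = initial_radius + t * (final_radius - initial_radius)
        # BMU assignment: argmin ||x - w||^2 via the expanded form
        cross = X @ weights.T
        d2 = sq_x[:, None] - 2.0 * cross + np.sum(weights**2, axis=1)[None, :]
        bmu = np.argmin(d2, axis=1)
        # per-node sufficient statistics, then neighborhood smoothing
        sums = np.zeros((n_nodes, X.shape[1]))
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        h = np.exp(-d2_grid / (2.0 * sigma**2))
        weights = (h @ sums) / (h @ counts)[:, None]

    model = SOMModel(
        grid_shape=grid_shape,
        weights=weights,
        training_meta={
            "epochs": epochs,
            "initial_radius": initial_radius,
            "final_radius": final_radius,
            "seed": seed,
            "n_inputs": int(X.shape[0]),
            "initial_quantization_error": float(qe_init),
            "final_quantization_error": float(_quantization_error_raw(weights, X)),
        },
    )
    return model


def _bmu_raw(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        - 2.0 * X @ weights.T
        + np.sum(weights**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def bmu_index(som: SOMModel, vector: np.ndarray) -> int:
    """Index of the best-matching unit (nearest node, Euclidean).

    Ties break toward the lowest row-major node index.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (som.weights.shape[1],):
        raise ValueError(
            f"vector length {vector.shape} does not match weight dimension "
            f"{som.weights.shape[1]}"
        )
    d2 = np.sum((som.weights - vector) ** 2, axis=1)
    return int(np.argmin(d2))


def bmu_indices(som: SOMModel, vectors: np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup for an (n, d) stack of vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != som.weights.shape[1]:
        raise ValueError("vectors must be (n, d) with d matching the SOM")
    return _bmu_raw(som.weights, vectors)


def _quantization_error_raw(weights: np.ndarray, X: np.ndarray) -> float:
    bmu = _bmu_raw(weights, X)
    return float(np.mean(np.linalg.norm(X - weights[bmu], axis=1)))


def quantization_error(som: SOMModel, features: VoxelFeatureMatrix | np.ndarray) -> float:
    """Mean Euclidean distance from each input vector to its BMU weight."""
    X = _as_input_matrix(features)
    if X.shape[0] == 0:
        raise ValueError("cannot compute quantization error on empty features")
    return _quantization_error_raw(som.weights, X)


def _relabel_by_size(raw_labels: np.ndarray, centroids: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Map raw k-means labels to 1..K in decreasing order of cluster size."""
    sizes = np.bincount(raw_labels, minlength=K)
    order = np.argsort(-sizes, kind="stable")  # stable: ties keep raw order
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(1, K + 1)
    return remap[raw_labels], centroids[order]


def cluster_protoclusters(
    som: SOMModel,
    K: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    allowed_k: tuple[int, ...] | None = DEFAULT_K_SET,
) -> ProtoclusterPartition:
    """Second-level K-means over the protocluster weight vectors.

    Lloyd's algorithm with k-means++ seeding, best of ``restarts`` runs by
    within-cluster sum of squares.  Pass ``allowed_k=None`` to lift the
    default restriction to K in {4, 6, 8, 10, 12, 16, 20}.
    """
    if allowed_k is not None and K not in allowed_k:
        raise ValueError(f"K={K} is not in the allowed set {sorted(allowed_k)}")
    if K > som.n_nodes:
        raise ValueError(f"K={K} exceeds the number of protoclusters ({som.n_nodes})")
    for attempt in range(5):
        km = KMeans(
            n_clusters=K,
            init="k-means++",
            n_init=restarts,
            random_state=(seed + attempt) % (2**31),
            algorithm="lloyd",
        ).fit(som.weights)
        if len(np.unique(km.labels_)) == K:
            break
    else:  # pragma: no cover - sklearn reassigns empty clusters internally
        raise RuntimeError(f"k-means left an empty cluster after 5 reseeds (K={K})")
    labels, centroids = _relabel_by_size(km.labels_, km.cluster_centers_, K)
    return ProtoclusterPartition(
        K=K,
        labels=labels,
        centroids=centroids,
        kmeans_meta={
            "restarts": restarts,
            "seed": seed,
            "inertia": float(km.inertia_),
        },
    )


def component_planes(
    som: SOMModel,
    partition: ProtoclusterPartition | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray] | None]:
    """Weight components as grid images, plus inter-class borderlines.

    Returns ``(planes, borders)`` where ``planes`` is (n_features, rows,
    cols) and ``borders`` marks grid edges whose endpoint nodes carry
    different K-class labels: ``borders["horizontal"][i, j]`` is the edge
    between nodes (i, j) and (i+1, j); ``borders["vertical"][i, j]`` between
    (i, j) and (i, j+1).  ``borders`` is None when no partition is given.
    """
    rows, cols = som.grid_shape
    planes = som.weights.T.reshape(som.weights.shape[1], rows, cols)
    if partition is None:
        return planes, None
    if partition.labels.shape[0] != som.n_nodes:
        raise ValueError("partition was fitted on a different grid")
    grid_labels = partition.labels.reshape(rows, cols)
    borders = {
        "horizontal": grid_labels[:-1, :] != grid_labels[1:, :],
        "vertical": grid_labels[:, :-1] != grid_labels[:, 1:],
    }
    return planes, borders


def save_model(
    path: str | Path,
    som: SOMModel,
    partitions: dict[int, ProtoclusterPartition] | None = None,
    config_hash: str = "",
) -> None:
    """Persist the SOM and its per-K partitions into one .npz archive."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"weights": som.weights}
    meta = {
        "grid_shape": list(som.grid_shape),
        "training_meta": som.training_meta,
        "config_hash": config_hash,
        "k_values": sorted(partitions) if partitions else [],
        "kmeans_meta": {},
    }
    if partitions:
        for K, part in partitions.items():
            arrays[f"labels_k{K}"] = part.labels
            arrays[f"centroids_k{K}"] = part.centroids
            meta["kmeans_meta"][str(K)] = part.kmeans_meta
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)


def load_model(path: str | Path) -> tuple[SOMModel, dict[int, ProtoclusterPartition]]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        som = SOMModel(
            grid_shape=tuple(meta["grid_shape"]),
            weights=data["weights"],
            training_meta=meta["training_meta"],
        )
        partitions = {
            int(K): ProtoclusterPartition(
                K=int(K),
                labels=data[f"labels_k{K}"],
                centroids=data[f"centroids_k{K}"],
                kmeans_meta=meta["kmeans_meta"].get(str(K), {}),
            )
            for K in meta["k_values"]
        }
    return som, partitions
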