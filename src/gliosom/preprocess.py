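"""Per-subject intensity normalization and stride-sampled voxel features.

Each channel is rescaled by an upper bound ``u = P75 + 1.5 * IQR`` of its
in-brain-mask intensities so that ``[0, u]`` maps onto ``[0, 1]``; values
above ``u`` are retained (no clipping of outliers).  Training voxels for
the cohort-level clustering are taken on a stride-4 lattice (one voxel per
4 x 4 x 4 block) restricted to the whole-brain mask, then column-stacked
across subjects into one 6 x N feature matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed channel order used everywhere in the package.
CHANNEL_NAMES: tuple[str, ...] = ("cet1", "t2", "flair", "adc", "rcbv", "fdopa")
N_CHANNELS = len(CHANNEL_NAMES)

#: Lattice stride: one sample per 4 x 4 x 4 voxel block.
DEFAULT_STRIDE = 4


@dataclass
class MultiparametricStudy:
    """One subject's six aligned channel volumes plus masks and metadata.

    ``channels`` has shape ``(6, nx, ny, nz)`` in the fixed order
    CE-T1WI, T2WI, FLAIR, ADC, rCBV, FDOPA-SUV.
    """

    subject_id: str
    channels: np.ndarray
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    genotype: str
    age: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.tumor_mask = np.asarray(self.tumor_mask).astype(bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.brain_mask.shape

    def validate(self) -> None:
        """Raise ValueError if the study violates its structural invariants."""
        if self.channels.ndim != 4 or self.channels.shape[0] != N_CHANNELS:
            raise ValueError(
                f"channels must have shape (6, nx, ny, nz); got {self.channels.shape}"
            )
        if self.channels.shape[1:] != self.brain_mask.shape:
            raise ValueError("channel volumes and brain mask shapes differ")
        if self.brain_mask.shape != self.tumor_mask.shape:
            raise ValueError("brain mask and tumor mask shapes differ")
        if not self.tumor_mask.any():
            raise ValueError(f"subject {self.subject_id}: tumor mask is empty")
        if np.any(self.tumor_mask & ~self.brain_mask):
            raise ValueError(
                f"subject {self.subject_id}: tumor mask extends outside brain mask"
            )
        if self.genotype not in ("wildtype", "mutant"):
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass
class NormalizationParams:
    """Per-channel upper bounds ``u = P75 + 1.5 * IQR`` (native units)."""

    upper: np.ndarray  # shape (6,)

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        if self.upper.shape != (N_CHANNELS,):
            raise ValueError("upper must hold one bound per channel")


@dataclass
class VoxelFeatureMatrix:
    """Cohort-stacked normalized voxel features.

    ``values`` is 6 x N (channel-major); column ``j`` is one sampled voxel,
    ``subject_index[j]`` maps it to ``subject_ids`` and ``voxel_coords[j]``
    to its integer grid coordinate inside that subject's brain mask.
    """

    values: np.ndarray
    subject_index: np.ndarray
    voxel_coords: np.ndarray
    subject_ids: tuple[str, ...] = field(default_factory=tuple)
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_index = np.asarray(self.subject_index, dtype=int)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def save(self, path: str | Path, *, stride: int = DEFAULT_STRIDE,
             norm_params: dict[str, Sequence[float]] | None = None) -> None:
        """Write the matrix as Parquet with a JSON sidecar of provenance."""
        path = Path(path)
        df = pd.DataFrame(self.values.T, columns=list(self.channel_names))
        df.insert(0, "subject_index", self.subject_index)
        for ax, name in enumerate(("i", "j", "k")):
            df[name] = self.voxel_coords[:, ax]
        df.to_parquet(path, index=False)
        sidecar = {
            "channel_order": list(self.channel_names),
            "stride": stride,
            "subject_ids": list(self.subject_ids),
            "normalization_upper": norm_params or {},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelFeatureMatrix":
        path = Path(path)
        df = pd.read_parquet(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        names = tuple(sidecar.get("channel_order", CHANNEL_NAMES))
        values = df[list(names)].to_numpy().T
        coords = df[["i", "j", "k"]].to_numpy()
        return cls(values, df["subject_index"].to_numpy(), coords,
                   tuple(sidecar.get("subject_ids", ())), names)


def compute_normalization(study: MultiparametricStudy) -> NormalizationParams:
    """Per-channel upper bound over in-brain-mask voxels.

    Percentiles use linear interpolation between order statistics; the bound
    is ``P75 + 1.5 * (P75 - P25)``.  A non-positive bound (e.g. an all-zero
    channel) is rejected because the subsequent division would be undefined.
    """
    if not study.brain_mask.any():
        raise ValueError(f"subject {study.subject_id}: brain mask is empty")
    upper = np.empty(N_CHANNELS)
    for c, name in enumerate(CHANNEL_NAMES):
        vals = study.channels[c][study.brain_mask]
        p25, p75 = np.percentile(vals, [25.0, 75.0])
        u = p75 + 1.5 * (p75 - p25)
        if not np.isfinite(u) or u <= 0:
            raise ValueError(
                f"subject {study.subject_id}: normalization bound for channel "
                f"{name!r} is {u!r} (must be > 0)"
            )
        upper[c] = u
    return NormalizationParams(upper)


def normalize_channel(volume: np.ndarray, params: NormalizationParams, channel_id: int | str) -> np.ndarray:
    """Divide a channel volume by its upper bound; no clipping anywhere.

    Values above the bound map above 1 and negative values map below 0 —
    outliers are retained by design.
    """
    c = CHANNEL_NAMES.index(channel_id) if isinstance(channel_id, str) else int(channel_id)
    return np.asarray(volume, dtype=float) / params.upper[c]


def normalize_study(study: MultiparametricStudy, params: NormalizationParams) -> np.ndarray:
    """All six channels normalized at once; returns a (6, nx, ny, nz) array."""
    return study.channels / params.upper[:, None, None, None]


def _stride_lattice_mask(mask: np.ndarray, stride: int) -> np.ndarray:
    """Boolean mask of stride-lattice points (anchored at index 0) inside mask."""
    lattice = np.zeros_like(mask, dtype=bool)
    lattice[::stride, ::stride, ::stride] = True
    return lattice & mask


def channel_indices(channel_subset: Sequence[str] | None) -> np.ndarray:
    """Row indices of a channel-name subset (None means all six)."""
    if channel_subset is None:
        return np.arange(N_CHANNELS)
    idx = []
    for name in channel_subset:
        if name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}")
        idx.append(CHANNEL_NAMES.index(name))
    if not idx:
        raise ValueError("channel subset must not be empty")
    return np.array(sorted(set(idx)), dtype=int)


def extract_training_voxels(
    study: MultiparametricStudy,
    params: NormalizationParams,
    stride: int = DEFAULT_STRIDE,
    channel_subset: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized features on the stride lattice inside the brain mask.

    Returns ``(block, coords)`` where ``block`` is n_channels x n and
    ``coords`` is n x 3 integer grid coordinates.  The lattice is anchored
    at (0, 0, 0) and samples one voxel per ``stride**3`` block.  A channel
    subset restricts the feature rows (ablation runs, e.g. without FDOPA).
    """
    sampled = _stride_lattice_mask(study.brain_mask, stride)
    coords = np.argwhere(sampled)
    if coords.shape[0] == 0:
        raise ValueError(
            f"subject {study.subject_id}: no stride-{stride} lattice point "
            "falls inside the brain mask"
        )
    normalized = normalize_study(study, params)
    block = normalized[:, coords[:, 0], coords[:, 1], coords[:, 2]]
    return block[channel_indices(channel_subset)], coords


def stack_cohort_features(
    blocks: Sequence[tuple[np.ndarray, np.ndarray]],
    subject_ids: Sequence[str] | None = None,
    channel_names: Sequence[str] = CHANNEL_NAMES,
) -> VoxelFeatureMatrix:
    """Column-concatenate per-subject (block, coords) pairs in given order."""
    if len(blocks) == 0:
        raise ValueError("need at least one subject block")
    n_rows = len(channel_names)
    for block, _ in blocks:
        if block.shape[0] != n_rows:
            raise ValueError(
                f"channel-count mismatch: expected {n_rows} rows, got {block.shape[0]}"
            )
    values = np.concatenate([b for b, _ in blocks], axis=1)
    coords = np.concatenate([c for _, c in blocks], axis=0)
    subject_index = np.concatenate(
        [np.full(b.shape[1], i, dtype=int) for i, (b, _) in enumerate(blocks)]
    )
    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        f"subject_{i:03d}" for i in range(len(blocks))
    )
    return VoxelFeatureMatrix(values, subject_index, coords, ids, tuple(channel_names))
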