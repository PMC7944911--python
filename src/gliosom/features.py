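"""Tumor label maps and per-subject log-ratio label-fraction features.

Every tumor-ROI voxel (full native resolution, not the training lattice) is
painted with the K-class label of its nearest protocluster.  Per subject and
class k, the percentage p_k of tumor voxels labeled k is transformed to
log10(p_k + 1e-2), giving a K x n_subjects feature table for the SVM.
The 1e-2 offset puts absent classes at exactly -2 while keeping the
transform strictly increasing on [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import (
    MultiparametricStudy,
    NormalizationParams,
    channel_indices,
    normalize_study,
)
from .som import SOMModel, ProtoclusterPartition, bmu_indices

LOG_OFFSET = 1e-2


@dataclass
class TumorLabelMap:
    """Per-voxel K-class labels on the full grid: 0 outside the tumor ROI,
    1..K inside."""

    subject_id: str
    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        inside = self.labels[self.labels > 0]
        if inside.size == 0:
            raise ValueError(f"subject {self.subject_id}: label map has no tumor voxels")
        if inside.max() > self.K:
            raise ValueError("label values must lie in 1..K")

    @property
    def tumor_voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), np.eye(4)), str(path))


@dataclass
class LabelRatioFeatureTable:
    """K x n_subjects label percentages and their log10(p + 1e-2) features,
    with aligned genotype and age vectors in manifest order."""

    ratios: np.ndarray
    log_ratios: np.ndarray
    subject_ids: tuple[str, ...]
    genotype: np.ndarray
    age: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        self.genotype = np.asarray(self.genotype)
        self.age = np.asarray(self.age, dtype=float)
        K, n = self.ratios.shape
        if self.log_ratios.shape != (K, n) or len(self.subject_ids) != n:
            raise ValueError("inconsistent table dimensions")

    @property
    def K(self) -> int:
        return self.ratios.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.ratios.shape[1]

    def subset(self, indices: Sequence[int], subject_ids: Sequence[str] | None = None) -> "LabelRatioFeatureTable":
        """Column subset/resample (used by the bootstrap)."""
        idx = np.asarray(indices, dtype=int)
        ids = tuple(subject_ids) if subject_ids is not None else tuple(
            self.subject_ids[i] for i in idx
        )
        return LabelRatioFeatureTable(
            ratios=self.ratios[:, idx],
            log_ratios=self.log_ratios[:, idx],
            subject_ids=ids,
            genotype=self.genotype[idx],
            age=self.age[idx],
        )

    def to_csv(self, path: str | Path) -> None:
        """Rows label_1..label_K of log-ratios plus ratio/genotype/age rows."""
        rows: dict[str, list] = {}
        for k in range(self.K):
            rows[f"label_{k + 1}"] = list(self.log_ratios[k])
        for k in range(self.K):
            rows[f"ratio_{k + 1}"] = list(self.ratios[k])
        rows["genotype"] = list(self.genotype)
        rows["age"] = list(self.age)
        pd.DataFrame(rows, index=list(self.subject_ids)).T.to_csv(
            path, index_label="row"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelRatioFeatureTable":
        df = pd.read_csv(path, index_col="row")
        label_rows = [r for r in df.index if r.startswith("label_")]
        K = len(label_rows)
        log_ratios = df.loc[[f"label_{k + 1}" for k in range(K)]].to_numpy(dtype=float)
        ratios = df.loc[[f"ratio_{k + 1}" for k in range(K)]].to_numpy(dtype=float)
        return cls(
            ratios=ratios,
            log_ratios=log_ratios,
            subject_ids=tuple(df.columns),
            genotype=df.loc["genotype"].to_numpy(),
            age=df.loc["age"].to_numpy(dtype=float),
        )


def assign_labels(
    study: MultiparametricStudy,
    params: NormalizationParams,
    som: SOMModel,
    partition: ProtoclusterPartition,
    channel_subset: Sequence[str] | None = None,
) -> TumorLabelMap:
    """Paint every tumor voxel with its nearest protocluster's class label.

    ``channel_subset`` must match the subset the SOM was trained on (None
    for all six channels).
    """
    if not study.tumor_mask.any():
        raise ValueError(f"subject {study.subject_id}: tumor mask is empty")
    if partition.labels.shape[0] != som.n_nodes:
        raise ValueError("partition does not match the SOM grid")
    normalized = normalize_study(study, params)
    coords = np.argwhere(study.tumor_mask)
    vectors = normalized[:, coords[:, 0], coords[:, 1], coords[:, 2]].T
    vectors = vectors[:, channel_indices(channel_subset)]
    bmu = bmu_indices(som, vectors)
    labels = np.zeros(study.tumor_mask.shape, dtype=np.int32)
    labels[coords[:, 0], coords[:, 1], coords[:, 2]] = partition.labels[bmu]
    return TumorLabelMap(subject_id=study.subject_id, labels=labels, K=partition.K)


def label_ratios(label_map: TumorLabelMap) -> np.ndarray:
    """Percentage of tumor voxels per class: p_k = 100 * n_k / n_tumor."""
    counts = np.bincount(
        label_map.labels[label_map.labels > 0], minlength=label_map.K + 1
    )[1:]
    return 100.0 * counts / label_map.tumor_voxel_count


def log_ratio(p: float | np.ndarray) -> float | np.ndarray:
    """log10(p + 1e-2) for a percentage p in [0, 100]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("percentages must lie in [0, 100]")
    out = np.log10(arr + LOG_OFFSET)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def build_feature_table(
    studies: Sequence[MultiparametricStudy],
    params_by_subject: Mapping[str, NormalizationParams],
    som: SOMModel,
    partition: ProtoclusterPartition,
) -> LabelRatioFeatureTable:
    """Label-fraction feature table for one partition (one K).

    Columns follow the order of ``studies`` (manifest order); genotype and
    age vectors are aligned with the columns.
    """
    ratios = np.empty((partition.K, len(studies)))
    for j, study in enumerate(studies):
        if study.subject_id not in params_by_subject:
            raise KeyError(
                f"no normalization params for subject {study.subject_id}"
            )
        lmap = assign_labels(study, params_by_subject[study.subject_id], som, partition)
        ratios[:, j] = label_ratios(lmap)
    return LabelRatioFeatureTable(
        ratios=ratios,
        log_ratios=log_ratio(ratios),
        subject_ids=tuple(s.subject_id for s in studies),
        genotype=np.array([s.genotype for s in studies]),
        age=np.array([s.age for s in studies], dtype=float),
    )


def build_feature_tables(
    studies: Sequence[MultiparametricStudy],
    params_by_subject: Mapping[str, NormalizationParams],
    som: SOMModel,
    partitions: Mapping[int, ProtoclusterPartition],
    channel_subset: Sequence[str] | None = None,
) -> dict[int, LabelRatioFeatureTable]:
    """One feature table per K, sharing BMU lookups across partitions."""
    # BMU of each tumor voxel is partition-independent; compute once
    chan_idx = channel_indices(channel_subset)
    tables = {K: np.empty((part.K, len(studies))) for K, part in partitions.items()}
    for j, study in enumerate(studies):
        if study.subject_id not in params_by_subject:
            raise KeyError(f"no normalization params for subject {study.subject_id}")
        params = params_by_subject[study.subject_id]
        normalized = normalize_study(study, params)
        coords = np.argwhere(study.tumor_mask)
        vectors = normalized[:, coords[:, 0], coords[:, 1], coords[:, 2]].T[:, chan_idx]
        bmu = bmu_indices(som, vectors)
        n_tumor = coords.shape[0]
        for K, part in partitions.items():
            counts = np.bincount(part.labels[bmu], minlength=K + 1)[1:]
            tables[K][:, j] = 100.0 * counts / n_tumor
    genotype = np.array([s.genotype for s in studies])
    age = np.array([s.age for s in studies], dtype=float)
    ids = tuple(s.subject_id for s in studies)
    return {
        K: LabelRatioFeatureTable(
            ratios=tab, log_ratios=log_ratio(tab), subject_ids=ids,
            genotype=genotype, age=age,
        )
        for K, tab in tables.items()
    }
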