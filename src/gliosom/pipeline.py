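"""End-to-end pipeline: simulate -> preprocess -> cluster -> features ->
classify -> compare, with config-hash-based stage caching.

One top-level seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawn keys, so each stage is independently
reproducible.  Every stage writes its outputs plus a small state JSON
recording the hash of the configuration slice it depends on; a rerun skips
stages whose state hash matches and recomputes everything downstream of a
changed setting.  Metric JSON files are written with sorted keys and no
timestamps, so identical config + seed reproduce them byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import cohort as cohort_mod
from .classify import SVMConfig, loocv_classify
from .features import build_feature_tables, LabelRatioFeatureTable
from .preprocess import (
    DEFAULT_STRIDE,
    compute_normalization,
    extract_training_voxels,
    stack_cohort_features,
    VoxelFeatureMatrix,
)
from .som import (
    DEFAULT_EPOCHS,
    DEFAULT_GRID,
    DEFAULT_K_SET,
    DEFAULT_RESTARTS,
    cluster_protoclusters,
    load_model,
    save_model,
    train_som,
)
from .stats import anova_tukey, bootstrap_performance, mannwhitney_bh, BOOT_METRICS

log = logging.getLogger("gliosom")

STAGES = ("simulate", "preprocess", "cluster", "features", "classify", "compare")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults reproduce the reference settings
    (stride 4, 20 x 20 grid, K in {4, 6, 8, 10, 12, 16, 20}, 100 bootstrap
    replicates, alpha 0.05)."""

    workdir: str = "gliosom_run"
    manifest: str | None = None  # existing cohort; None -> simulate stage
    n_subjects: int = 62
    class_balance: float = 33 / 62
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    focus_fraction_wildtype: tuple[float, float] = (0.25, 0.15)
    focus_fraction_mutant: tuple[float, float] = (0.05, 0.05)
    stride: int = DEFAULT_STRIDE
    grid_shape: tuple[int, int] = DEFAULT_GRID
    epochs: int = DEFAULT_EPOCHS
    k_values: tuple[int, ...] = DEFAULT_K_SET
    restarts: int = DEFAULT_RESTARTS
    include_age: bool = False
    positive_class: str = "wildtype"
    channel_subset: tuple[str, ...] | None = None
    n_boot: int = 100
    alpha: float = 0.05
    compare_k: int | None = None  # K for the per-label tests; None -> best AUC
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def stage_seed(self, stage: str) -> int:
        key = STAGES.index(stage)
        return int(np.random.SeedSequence(self.seed, spawn_key=(key,)).generate_state(1)[0] % (2**31))

    def stage_hash(self, stage: str) -> str:
        """Hash of the config slice a stage (and its upstream) depends on."""
        slices = {
            "simulate": ["n_subjects", "class_balance", "volume_shape",
                         "focus_fraction_wildtype", "focus_fraction_mutant", "seed"],
            "preprocess": ["manifest", "stride", "channel_subset"],
            "cluster": ["grid_shape", "epochs", "k_values", "restarts"],
            "features": [],
            "classify": ["include_age", "positive_class"],
            "compare": ["n_boot", "alpha", "compare_k"],
        }
        payload: dict[str, Any] = {}
        for s in STAGES[: STAGES.index(stage) + 1]:
            for name in slices[s]:
                payload[name] = getattr(self, name)
        payload["__stage__"] = stage
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class _StageRunner:
    """Skips a stage when its recorded config hash matches the current one."""

    def __init__(self, workdir: Path, config: PipelineConfig):
        self.workdir = workdir
        self.config = config

    def state_path(self, stage: str) -> Path:
        return self.workdir / stage / ".stage.json"

    def is_fresh(self, stage: str) -> bool:
        p = self.state_path(stage)
        if not p.exists():
            return False
        return json.loads(p.read_text()).get("hash") == self.config.stage_hash(stage)

    def mark(self, stage: str) -> None:
        self.state_path(stage).parent.mkdir(parents=True, exist_ok=True)
        _write_json(self.state_path(stage), {"hash": self.config.stage_hash(stage)})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order, reusing cached stage outputs when the
    relevant configuration has not changed.  Returns the run summary."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(workdir, config)
    summary: dict[str, Any] = {"stages_run": [], "stages_skipped": []}

    def stage(name):
        fresh = runner.is_fresh(name)
        summary["stages_skipped" if fresh else "stages_run"].append(name)
        if not fresh:
            log.info("stage %s: running", name)
        else:
            log.info("stage %s: cached, skipping", name)
        return not fresh

    # --- simulate -----------------------------------------------------
    manifest_path = Path(config.manifest) if config.manifest else workdir / "simulate" / "manifest.csv"
    if config.manifest is None:
        if stage("simulate"):
            spec = cohort_mod.CohortSpec(
                n_subjects=config.n_subjects,
                class_balance=config.class_balance,
                volume_shape=tuple(config.volume_shape),
                focus_fraction_by_class={
                    "wildtype": tuple(config.focus_fraction_wildtype),
                    "mutant": tuple(config.focus_fraction_mutant),
                },
                seed=config.stage_seed("simulate"),
            )
            cohort = cohort_mod.generate_cohort(spec)
            write_dir = workdir / "simulate"
            write_dir.mkdir(parents=True, exist_ok=True)
            cohort_mod.write_cohort(cohort, write_dir, overwrite=True)
            runner.mark("simulate")
    else:
        summary["stages_skipped"].append("simulate")

    studies = cohort_mod.read_cohort(manifest_path)

    # --- preprocess ---------------------------------------------------
    pre_dir = workdir / "preprocess"
    features_path = pre_dir / "voxel_features.parquet"
    params_path = pre_dir / "normalization.json"
    if stage("preprocess"):
        pre_dir.mkdir(parents=True, exist_ok=True)
        params_by_subject = {}
        blocks = []
        for study in studies:
            params = compute_normalization(study)
            params_by_subject[study.subject_id] = params
            blocks.append(
                extract_training_voxels(
                    study, params, stride=config.stride,
                    channel_subset=config.channel_subset,
                )
            )
        names = tuple(config.channel_subset) if config.channel_subset else None
        from .preprocess import CHANNEL_NAMES

        matrix = stack_cohort_features(
            blocks, [s.subject_id for s in studies],
            channel_names=names or CHANNEL_NAMES,
        )
        matrix.save(
            features_path,
            stride=config.stride,
            norm_params={sid: list(p.upper) for sid, p in params_by_subject.items()},
        )
        runner.mark("preprocess")
    matrix = VoxelFeatureMatrix.load(features_path)
    norm_upper = json.loads(features_path.with_suffix(".json").read_text())["normalization_upper"]
    from .preprocess import NormalizationParams

    params_by_subject = {sid: NormalizationParams(np.asarray(u)) for sid, u in norm_upper.items()}

    # --- cluster ------------------------------------------------------
    cluster_dir = workdir / "cluster"
    model_path = cluster_dir / "som_model.npz"
    if stage("cluster"):
        cluster_dir.mkdir(parents=True, exist_ok=True)
        som = train_som(
            matrix,
            grid_shape=tuple(config.grid_shape),
            epochs=config.epochs,
            seed=config.stage_seed("cluster"),
        )
        partitions = {
            K: cluster_protoclusters(
                som, K, restarts=config.restarts,
                seed=config.stage_seed("cluster") + K, allowed_k=None,
            )
            for K in config.k_values
        }
        save_model(model_path, som, partitions, config_hash=config.stage_hash("cluster"))
        runner.mark("cluster")
    som, partitions = load_model(model_path)

    # --- features -----------------------------------------------------
    feat_dir = workdir / "features"
    if stage("features"):
        feat_dir.mkdir(parents=True, exist_ok=True)
        tables = build_feature_tables(
            studies, params_by_subject, som, partitions,
            channel_subset=config.channel_subset,
        )
        for K, table in tables.items():
            table.to_csv(feat_dir / f"label_ratios_k{K}.csv")
        runner.mark("features")
    tables = {
        K: LabelRatioFeatureTable.from_csv(feat_dir / f"label_ratios_k{K}.csv")
        for K in config.k_values
    }

    # --- classify -----------------------------------------------------
    clf_dir = workdir / "classify"
    svm_config = SVMConfig(
        include_age=config.include_age,
        positive_class=config.positive_class,
        seed=config.stage_seed("classify"),
    )
    if stage("classify"):
        clf_dir.mkdir(parents=True, exist_ok=True)
        for K in config.k_values:
            report = loocv_classify(tables[K], svm_config)
            (clf_dir / f"loocv_k{K}.json").write_text(report.to_json())
        runner.mark("classify")
    metrics_by_k = {
        K: json.loads((clf_dir / f"loocv_k{K}.json").read_text())["metrics"]
        for K in config.k_values
    }

    # --- compare ------------------------------------------------------
    cmp_dir = workdir / "compare"
    if stage("compare"):
        cmp_dir.mkdir(parents=True, exist_ok=True)
        boot = bootstrap_performance(
            tables, svm_config, n_boot=config.n_boot, seed=config.stage_seed("compare")
        )
        boot_payload = {
            m: {str(K): boot.values[m][K] for K in boot.k_values()} for m in BOOT_METRICS
        }
        _write_json(cmp_dir / "bootstrap.json", boot_payload)
        anova_payload = {}
        for m in BOOT_METRICS:
            res = anova_tukey(boot, m)
            anova_payload[m] = {
                "F": res.f_statistic,
                "p": res.p_value,
                "df": [res.df_between, res.df_within],
                "no_difference": res.no_difference,
            }
            res.tukey.to_csv(cmp_dir / f"tukey_{m}.csv", index=False)
        _write_json(cmp_dir / "anova.json", anova_payload)
        best_k = config.compare_k or max(
            config.k_values, key=lambda K: (metrics_by_k[K]["auc"] or 0.0, -K)
        )
        labels_df = mannwhitney_bh(tables[best_k], alpha=config.alpha,
                                   positive_class=config.positive_class)
        labels_df.to_csv(cmp_dir / f"label_tests_k{best_k}.csv", index=False)
        runner.mark("compare")

    # --- summary ------------------------------------------------------
    best_by_metric = {
        m: max(config.k_values, key=lambda K: (metrics_by_k[K][m] or 0.0, -K))
        for m in ("auc", "accuracy", "f1")
    }
    summary.update({
        "metrics_by_k": metrics_by_k,
        "best_k": best_by_metric,
        "config": config.to_dict(),
    })
    _write_json(workdir / "summary.json", summary)
    return summary
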