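"""Bootstrap model comparison across K and per-label group tests.

Classifier performance is compared across the candidate K values by
resampling subjects with replacement (stratified by genotype, the same
replicate sample reused for every K so the comparison is matched), running
the full LOOCV classifier per replicate, then one-way ANOVA with Tukey HSD
over the replicate metric distributions.  Per-label log-ratio features are
compared between genotypes with two-sided Mann-Whitney U tests (exact
enumeration for small untied samples, normal approximation with tie
correction otherwise) and Benjamini-Hochberg FDR correction across the K
labels at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import SVMConfig, loocv_classify
from .features import LabelRatioFeatureTable

DEFAULT_N_BOOT = 100
DEFAULT_ALPHA = 0.05
BOOT_METRICS = ("auc", "accuracy", "f1")

#: Exact Mann-Whitney enumeration is used up to this per-group size when
#: the pooled sample has no ties.
EXACT_MAX_N = 25


@dataclass
class BootstrapResult:
    """Replicate metric values per K: ``values[metric][K]`` has length n_boot."""

    values: dict[str, dict[int, np.ndarray]]
    n_boot: int
    replicate_seeds: tuple[int, ...] = ()

    def k_values(self) -> list[int]:
        return sorted(next(iter(self.values.values())).keys())


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA across K groups plus Tukey HSD pairwise comparisons."""

    metric: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame
    no_difference: bool = False


def _stratified_resample(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample subject indices with replacement within each genotype."""
    idx = []
    for g in np.unique(genotype):
        members = np.flatnonzero(genotype == g)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.sort(np.concatenate(idx))


def bootstrap_performance(
    tables: Mapping[int, LabelRatioFeatureTable],
    config: SVMConfig,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    max_retries: int = 10,
) -> BootstrapResult:
    """Replicate LOOCV metrics for every K on matched bootstrap samples.

    Duplicated subjects in a replicate are treated as distinct resampled
    units (standard bootstrap-of-CV behavior; this makes replicate scores
    optimistic relative to the original-sample LOOCV).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    k_values = sorted(tables)
    ref = tables[k_values[0]]
    for K in k_values[1:]:
        if tables[K].subject_ids != ref.subject_ids:
            raise ValueError("all K tables must share the same subjects")

    values: dict[str, dict[int, np.ndarray]] = {
        m: {K: np.empty(n_boot) for K in k_values} for m in BOOT_METRICS
    }
    rep_seeds = []
    for b in range(n_boot):
        ss = np.random.SeedSequence(seed, spawn_key=(b,))
        rng = np.random.default_rng(ss)
        rep_seeds.append(int(ss.generate_state(1)[0] % (2**31)))
        for _ in range(max_retries):
            idx = _stratified_resample(ref.genotype, rng)
            if len(np.unique(ref.genotype[idx])) == 2:
                break
        else:
            raise RuntimeError("bootstrap replicate kept losing a class")
        # unique ids for duplicated subjects so each resampled unit is distinct
        ids = tuple(f"{ref.subject_ids[i]}#r{j}" for j, i in enumerate(idx))
        for K in k_values:
            rep_table = tables[K].subset(idx, subject_ids=ids)
            report = loocv_classify(rep_table, config)
            for m in BOOT_METRICS:
                values[m][K][b] = report.metrics[m]
    return BootstrapResult(values=values, n_boot=n_boot, replicate_seeds=tuple(rep_seeds))


def anova_tukey(result: BootstrapResult, metric: str) -> AnovaTukeyResult:
    """One-way ANOVA across the K groups, then Tukey HSD on all pairs."""
    if metric not in result.values:
        raise KeyError(f"metric {metric!r} not in bootstrap result")
    k_values = result.k_values()
    groups = [np.asarray(result.values[metric][K], dtype=float) for K in k_values]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 replicates each")

    n_total = sum(len(g) for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)

    grand = np.concatenate(groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ssw == 0 and ssb == 0:
        # all replicates identical in every group: explicitly no difference
        tukey = _tukey_frame(groups, k_values, no_variation=True)
        return AnovaTukeyResult(metric, float("nan"), 1.0, df_between, df_within,
                                tukey, no_difference=True)

    f_stat, p_val = sps.f_oneway(*groups)
    res = sps.tukey_hsd(*groups)
    tukey = _tukey_frame(groups, k_values, hsd=res)
    return AnovaTukeyResult(metric, float(f_stat), float(p_val),
                            df_between, df_within, tukey)


def _tukey_frame(groups, k_values, hsd=None, no_variation=False) -> pd.DataFrame:
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rows.append({
                "K_a": k_values[a],
                "K_b": k_values[b],
                "mean_diff": float(groups[a].mean() - groups[b].mean()),
                "p_adj": 1.0 if no_variation else float(hsd.pvalue[a, b]),
            })
    df = pd.DataFrame(rows)
    df["significant"] = df["p_adj"] < DEFAULT_ALPHA
    return df


def _mwu_row(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # no information at all: U is its null mean, p = 1 by convention
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_bh(
    table: LabelRatioFeatureTable,
    alpha: float = DEFAULT_ALPHA,
    positive_class: str = "wildtype",
) -> pd.DataFrame:
    """Per-label two-sided Mann-Whitney U (wild-type vs mutant log-ratios)
    with Benjamini-Hochberg correction over the K label tests.

    Returns one row per label with U, raw p, BH-adjusted p, the median
    difference (positive class minus other), and the significance flag at
    the adjusted level.
    """
    geno = np.asarray(table.genotype)
    if len(np.unique(geno)) < 2:
        raise ValueError("both genotypes must be present")
    grp_a = table.log_ratios[:, geno == positive_class]
    grp_b = table.log_ratios[:, geno != positive_class]

    stats_u, pvals = zip(*(_mwu_row(grp_a[k], grp_b[k]) for k in range(table.K)))
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame({
        "label": np.arange(1, table.K + 1),
        "U": stats_u,
        "p_raw": pvals,
        "p_adj": p_adj,
        "median_diff": np.median(grp_a, axis=1) - np.median(grp_b, axis=1),
        "significant": p_adj < alpha,
    })
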