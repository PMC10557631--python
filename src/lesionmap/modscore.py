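"""Gene-set module scoring and the statistical filter chains.

Implements the binned-control signature score (mean log-normalized
expression over a gene set minus the mean over expression-matched control
genes), the score-threshold region masks, the Wilcoxon rank-sum DEG filter
chain (Bonferroni-adjusted p < 0.05, average logFC > 0.25, pct.2 < 0.1),
cross-group z-scores of group means, and the cluster-proportion permutation
test (BH FDR < 0.05 and |log2FC| > 0.25).

Matrices are genes x units (spots, subspots, or nuclei) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig, DEFAULT_CONFIG


def log_normalize(counts: pd.DataFrame, scale_total: float = 1e4) -> pd.DataFrame:
    """Scale each unit to a fixed total count then log1p (genes x units)."""
    totals = counts.sum(axis=0)
    totals = totals.replace(0, 1.0)
    return np.log1p(counts / totals * scale_total)


def module_score(
    data: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control signature score per unit.

    Genes are binned by their average expression across units (``n_bins``
    rank bins); for every gene in the set, up to ``n_ctrl`` control genes
    are drawn without replacement from the same bin.  The score is the mean
    over set genes minus the mean over the pooled control genes, per unit.
    Deterministic for a given seed.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    missing = [g for g in gene_set if g not in data.index]
    if missing:
        raise KeyError(f"gene set members absent from matrix: {missing[:5]}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n_genes = len(data.index)
    if len(gene_set) >= n_genes:
        if len(gene_set) > n_genes:
            raise ValueError("gene set larger than the genome")
    rng = np.random.default_rng(seed)
    avg = data.mean(axis=1)
    # rank-based binning; ties broken by stable order for determinism
    order = np.argsort(avg.to_numpy(), kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)
    bin_series = pd.Series(bin_of, index=data.index)
    genes_by_bin = {b: idx.to_numpy() for b, idx in data.index.groupby(bin_series).items()}

    ctrl: set[str] = set()
    for g in gene_set:
        pool = genes_by_bin[int(bin_series[g])]
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    set_mean = data.loc[gene_set].mean(axis=0)
    ctrl_mean = data.loc[sorted(ctrl)].mean(axis=0)
    score = set_mean - ctrl_mean
    score.name = "module_score"
    return score


def derive_region_masks(
    gm_score: pd.Series,
    lesion_score: pd.Series,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[pd.Series, pd.Series]:
    """GM mask = {gm_score > 0.01}; Lesion mask = {lesion_score > 0.1} (strict)."""
    if not gm_score.index.equals(lesion_score.index):
        raise ValueError("score vectors are misaligned")
    gm = gm_score > config.gm_score_threshold
    lesion = lesion_score > config.lesion_score_threshold
    gm.name, lesion.name = "gm_mask", "lesion_mask"
    return gm, lesion


def _seurat_logfc(data: pd.DataFrame, in1: np.ndarray, in2: np.ndarray) -> np.ndarray:
    # average log fold change on log-normalized data: log of (mean expm1 + 1) ratio
    m1 = np.expm1(data.loc[:, in1]).mean(axis=1)
    m2 = np.expm1(data.loc[:, in2]).mean(axis=1)
    return np.log((m1 + 1.0) / (m2 + 1.0)).to_numpy()


def rank_sum_deg(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    group1: str | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum DEG table with the filter chain applied.

    ``group_labels`` must contain exactly two labels over the columns of
    ``counts``; ``group1`` names the enriched-in group (default: first label
    in sorted order).  p-values use midranks with the normal approximation
    and continuity correction; adjustment is Bonferroni.  A gene is kept iff
    adj p < 0.05, logFC > 0.25, and pct.2 < 0.1.
    """
    group_labels = group_labels.reindex(counts.columns)
    levels = sorted(group_labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    g1 = group1 if group1 is not None else levels[0]
    g2 = [lv for lv in levels if lv != g1][0]
    in1 = (group_labels == g1).to_numpy()
    in2 = (group_labels == g2).to_numpy()
    if in1.sum() < 3 or in2.sum() < 3:
        raise ValueError("each group must have at least 3 units")

    data = log_normalize(counts)
    x1 = data.loc[:, in1].to_numpy()
    x2 = data.loc[:, in2].to_numpy()
    res = stats.mannwhitneyu(x1, x2, axis=1, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    pvals = np.asarray(res.pvalue)
    n_genes = len(counts.index)
    adj = np.minimum(pvals * n_genes, 1.0)
    logfc = _seurat_logfc(data, in1, in2)
    pct1 = (counts.loc[:, in1] > 0).mean(axis=1).to_numpy()
    pct2 = (counts.loc[:, in2] > 0).mean(axis=1).to_numpy()
    kept = (
        (adj < config.deg_adj_p_cutoff)
        & (logfc > config.deg_logfc_cutoff)
        & (pct2 < config.deg_pct2_cutoff)
    )
    table = pd.DataFrame(
        {
            "avg_logFC": logfc,
            "pct.1": pct1,
            "pct.2": pct2,
            "p_val": pvals,
            "p_val_adj": adj,
            "kept": kept,
        },
        index=counts.index,
    )
    table.attrs["group1"] = g1
    table.attrs["group2"] = g2
    return table


def zscore_group_scores(score_vector: pd.Series, group_labels: pd.Series) -> pd.Series:
    """z-score of each group's mean score across the set of group means.

    z_g = (mean_g - mean of group means) / sample SD (ddof=1) of group means.
    All-equal group means give z = 0 for every group.
    """
    group_labels = group_labels.reindex(score_vector.index)
    means = score_vector.groupby(group_labels).mean()
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    sd = means.std(ddof=1)
    if sd == 0:
        z = means * 0.0
    else:
        z = (means - means.mean()) / sd
    z.name = "zscore"
    return z


def proportion_permutation_test(
    cluster_labels: pd.Series,
    condition_labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Permutation test for per-cluster composition shifts between two conditions.

    Observed statistic per cluster: log2 of the ratio of its proportion in
    condition 1 vs condition 2 (0.5 pseudocount on cluster counts so clusters
    empty in one condition stay finite).  The null is built by shuffling
    condition labels; two-sided p = (1 + #{|perm| >= |obs|}) / (1 + n_perm),
    adjusted by Benjamini-Hochberg.  Significant iff FDR < 0.05 and
    |log2FC| > 0.25.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cluster_labels = cluster_labels.reindex(condition_labels.index)
    conditions = sorted(condition_labels.unique())
    if len(conditions) != 2:
        raise ValueError(f"expected exactly two conditions, got {conditions}")
    clusters = sorted(cluster_labels.unique())
    cl_idx = pd.Categorical(cluster_labels, categories=clusters).codes
    cond1 = (condition_labels == conditions[0]).to_numpy()
    n1, n2 = int(cond1.sum()), int((~cond1).sum())
    k = len(clusters)

    def _log2fc(is1: np.ndarray) -> np.ndarray:
        c1 = np.bincount(cl_idx[is1], minlength=k) + 0.5
        c2 = np.bincount(cl_idx[~is1], minlength=k) + 0.5
        return np.log2((c1 / (n1 + 0.5 * k)) / (c2 / (n2 + 0.5 * k)))

    obs = _log2fc(cond1)
    rng = np.random.default_rng(seed)
    hits = np.zeros(k, dtype=int)
    perm = cond1.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        hits += np.abs(_log2fc(perm)) >= np.abs(obs)
    pvals = (1.0 + hits) / (1.0 + n_perm)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2FC": obs,
            "p_perm": pvals,
            "FDR": fdr,
            "significant": (fdr < config.proportion_fdr_cutoff)
            & (np.abs(obs) > config.proportion_log2fc_cutoff),
        },
        index=pd.Index(clusters, name="cluster"),
    )
    out.attrs["condition1"] = conditions[0]
    out.attrs["condition2"] = conditions[1]
    return out
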