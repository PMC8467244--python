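"""Gene-profile clustering with restarted k-means under correlation distance,
per-cluster per-group mean profiles with significance vs the normal group,
and per-gene differential statistics with unlogged fold changes.

The default distance between a gene profile and a centroid is
``1 - Pearson(gene, centroid)``; Euclidean assignment is available behind the
``metric`` flag.  Each restart starts from a uniformly random partition of the
genes, alternates assignment and centroid update until stable (at most 100
iterations), and the restart with the smallest total within-cluster distance
wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, NormalizedMatrix, SampleSheet, ValidationError
from .stats import bonferroni, pooled_ttest

logger = logging.getLogger(__name__)

MAX_ITER = 100


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so 1 - r = 1 - x.c as dot product."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    return xc / norms


@dataclass
class GeneClustering:
    k: int
    assignment: pd.Series  # gene id -> cluster id in 1..k
    centroids: pd.DataFrame  # k x samples mean profiles (cluster id index)
    objective: float
    seed: int
    n_runs: int
    run_objectives: list[float] = field(default_factory=list)
    excluded_genes: list[str] = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])


def _correlation_kmeans_run(
    xs: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, list[float]]:
    """One restart on row-standardized data.

    Centroid directions are the (re-standardized) means of member rows, which
    exactly minimizes the within-cluster sum of 1 - r for fixed membership, so
    the objective is non-increasing across iterations.
    """
    n = xs.shape[0]
    labels = rng.permutation(np.arange(n) % k)
    objectives: list[float] = []
    for _ in range(MAX_ITER):
        centroids = np.zeros((k, xs.shape[1]))
        np.add.at(centroids, labels, xs)
        counts = np.bincount(labels, minlength=k)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            centroids[empty] = xs[0]  # placeholder; replaced after standardization
        cs = _standardize_rows(centroids)
        sim = xs @ cs.T  # n x k correlations
        if empty.size:
            # re-seed each empty centroid with the gene farthest from its own centroid
            worst = np.argsort(sim[np.arange(n), labels])
            for j, c in enumerate(empty):
                g = worst[j]
                cs[c] = xs[g]
                logger.info("re-seeded empty cluster %d with farthest gene", c + 1)
            sim = xs @ cs.T
        new_labels = np.argmax(sim, axis=1)  # ties -> lowest cluster id
        objectives.append(float(np.sum(1.0 - sim[np.arange(n), new_labels])))
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return labels, objectives[-1], objectives


def _euclidean_kmeans_run(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, list[float]]:
    n = x.shape[0]
    labels = rng.permutation(np.arange(n) % k)
    objectives: list[float] = []
    for _ in range(MAX_ITER):
        centroids = np.zeros((k, x.shape[1]))
        np.add.at(centroids, labels, x)
        counts = np.bincount(labels, minlength=k)
        nonzero = counts > 0
        centroids[nonzero] /= counts[nonzero, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        empty = np.flatnonzero(~nonzero)
        if empty.size:
            worst = np.argsort(-d2[np.arange(n), labels])
            for j, c in enumerate(empty):
                centroids[c] = x[worst[j]]
            d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        objectives.append(float(np.sum(d2[np.arange(n), new_labels])))
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return labels, objectives[-1], objectives


def kmeans_profiles(
    norm: NormalizedMatrix,
    k: int = 10,
    runs: int = 100,
    seed: int = 0,
    metric: str = "correlation",
) -> GeneClustering:
    """Best-of-``runs`` restarted k-means over gene profiles.

    Constant-profile genes (undefined correlation) are excluded with a
    warning and reported in ``excluded_genes``.
    """
    if metric not in ("correlation", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    values = norm.values
    x = values.to_numpy(dtype=float)
    excluded: list[str] = []
    gene_ids = values.index
    if metric == "correlation":
        constant = x.std(axis=1) == 0
        excluded = list(values.index[constant])
        if excluded:
            logger.warning("excluding %d constant-profile genes from clustering", len(excluded))
            x = x[~constant]
            gene_ids = values.index[~constant]
    if k > x.shape[0]:
        raise ValidationError(f"k={k} exceeds number of usable genes ({x.shape[0]})")
    rng = np.random.default_rng(seed)
    run_fn = _correlation_kmeans_run if metric == "correlation" else _euclidean_kmeans_run
    data = _standardize_rows(x) if metric == "correlation" else x
    best: tuple[np.ndarray, float] | None = None
    run_objectives: list[float] = []
    for _ in range(runs):
        labels, obj, trace = run_fn(data, k, rng)
        # Lloyd iterations never increase the objective
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:])), "objective increased"
        run_objectives.append(obj)
        if best is None or obj < best[1]:
            best = (labels, obj)
    labels, objective = best
    assignment = pd.Series(labels + 1, index=gene_ids, name="cluster")
    centroids = pd.DataFrame(
        [x[labels == c].mean(axis=0) for c in range(k)],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=values.columns,
    )
    return GeneClustering(
        k=k,
        assignment=assignment,
        centroids=centroids,
        objective=objective,
        seed=seed,
        n_runs=runs,
        run_objectives=run_objectives,
        excluded_genes=excluded,
    )


def per_sample_cluster_means(clust: GeneClustering, norm: NormalizedMatrix) -> pd.DataFrame:
    """cluster x sample table of mean member-gene expression per sample."""
    values = norm.values.loc[clust.assignment.index]
    return values.groupby(clust.assignment).mean()


def cluster_group_profiles(
    clust: GeneClustering, norm: NormalizedMatrix, sheet: SampleSheet
) -> pd.DataFrame:
    """Mean/sd per (cluster, group) of the per-sample cluster means, with a
    two-sided pooled-variance t-test of each non-N group against N.

    Samples are the independent units: member genes are first averaged within
    each sample, then summarized across the group's samples.  Bonferroni uses
    m = k x 3 (the three non-N contrasts per cluster).  Groups with fewer than
    2 samples get p = NA.
    """
    unlabeled = [s for s in norm.sample_ids if s not in sheet.table.index]
    if unlabeled:
        raise ValidationError(f"samples without group labels: {unlabeled}")
    cl_means = per_sample_cluster_means(clust, norm)
    groups = {g: sheet.samples_in(g) for g in ("N", "E", "C", "T")}
    groups = {g: [s for s in ids if s in cl_means.columns] for g, ids in groups.items()}
    m = clust.k * 3
    rows = []
    for cluster_id in cl_means.index:
        row = cl_means.loc[cluster_id]
        n_vals = row[groups["N"]].to_numpy(dtype=float)
        for g in ("N", "E", "C", "T"):
            vals = row[groups[g]].to_numpy(dtype=float)
            mean = float(vals.mean()) if vals.size else np.nan
            sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
            if g == "N":
                p = p_bonf = np.nan
            elif vals.size < 2 or n_vals.size < 2:
                p = p_bonf = np.nan
            else:
                _, p_arr = pooled_ttest(vals[None, :], n_vals[None, :])
                p = float(p_arr[0])
                p_bonf = min(1.0, p * m)
            rows.append(
                dict(cluster=cluster_id, group=g, mean=mean, sd=sd, n=vals.size,
                     p_vs_N=p, p_bonferroni=p_bonf)
            )
    return pd.DataFrame(rows)


def _resolve_samples(sheet: SampleSheet, group, available) -> list[str]:
    """A group spec is a group label, an iterable of labels, or sample ids."""
    if isinstance(group, str):
        group = (group,)
    group = list(group)
    if all(g in ("N", "E", "C", "T") for g in group):
        ids = sheet.samples_in(*group)
    else:
        ids = group
    return [s for s in ids if s in set(available)]


def gene_stats(
    norm: NormalizedMatrix,
    unlogged: ExpressionMatrix,
    sheet: SampleSheet,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Per-gene differential table for group A vs group B.

    t and p come from a two-sided pooled-variance t-test on the logged values;
    FC is the ratio of unlogged group means (A over B); Bonferroni is over the
    number of genes tested.
    """
    a_ids = _resolve_samples(sheet, group_a, norm.sample_ids)
    b_ids = _resolve_samples(sheet, group_b, norm.sample_ids)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValidationError("both groups need at least 2 samples")
    a = norm.values[a_ids].to_numpy(dtype=float)
    b = norm.values[b_ids].to_numpy(dtype=float)
    t, p = pooled_ttest(a, b)
    mean_a = np.nanmean(unlogged.values[a_ids].to_numpy(dtype=float), axis=1)
    mean_b = np.nanmean(unlogged.values[b_ids].to_numpy(dtype=float), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b == 0, np.nan, mean_a / mean_b)
    if np.any(mean_b == 0):
        logger.warning("zero denominator group mean for %d genes; FC set to NA",
                       int(np.sum(mean_b == 0)))
    return pd.DataFrame(
        {"t": t, "p": p, "p_bonferroni": bonferroni(p, len(t)), "fc": fc},
        index=norm.values.index,
    )
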