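"""Correlation-threshold diagnostic predictor.

The model is a mean C/T reference profile over the top discriminant genes of
two clusters; a sample is scored by its Pearson correlation with that profile
and called tumor_like (r > +0.25), healthy_like (r < -0.25) or unpredictable
(weak correlation in between).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import GeneClustering, gene_stats, kmeans_profiles, per_sample_cluster_means
from .datamodel import (
    ExpressionMatrix,
    NormalizedMatrix,
    PredictionClass,
    SampleSheet,
    ValidationError,
)
from .normalization import DEFAULT_SPAN, _fit_ma_curve, median_reference
from .stats import pooled_ttest

logger = logging.getLogger(__name__)

THRESHOLD_HI = 0.25
THRESHOLD_LO = -0.25


@dataclass
class PredictorModel:
    gene_ids: list[str]
    reference: pd.Series  # mean centered log2 expression over C/T samples
    threshold_hi: float = THRESHOLD_HI
    threshold_lo: float = THRESHOLD_LO
    source_clusters: tuple[int, int] | None = None
    n_top_per_cluster: int = 100

    def __post_init__(self) -> None:
        if not self.threshold_lo < self.threshold_hi:
            raise ValidationError("threshold_lo must be below threshold_hi")
        if len(self.gene_ids) > 2 * self.n_top_per_cluster:
            raise ValidationError("more genes than 2 x n_top_per_cluster")


@dataclass
class PredictorEvaluation:
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    fisher_p: float
    n_unpredictable: int


def default_cluster_pair(
    clust: GeneClustering, norm: NormalizedMatrix, sheet: SampleSheet
) -> tuple[int, int]:
    """The two clusters best separating C/T from N/E with opposite directions.

    Per cluster, the per-sample cluster mean is tested C/T vs N/E; the pair is
    the most significant up cluster and the most significant down cluster.
    """
    cl_means = per_sample_cluster_means(clust, norm)
    pos = [s for s in sheet.samples_in("C", "T") if s in cl_means.columns]
    neg = [s for s in sheet.samples_in("N", "E") if s in cl_means.columns]
    t, p = pooled_ttest(cl_means[pos].to_numpy(), cl_means[neg].to_numpy())
    order = np.argsort(p)
    up = [cl_means.index[i] for i in order if t[i] > 0]
    down = [cl_means.index[i] for i in order if t[i] < 0]
    if not up or not down:
        raise ValidationError("no cluster pair with opposite directions found")
    return int(up[0]), int(down[0])


def select_discriminant_genes(
    stats: pd.DataFrame,
    clustering: GeneClustering,
    clusters: tuple[int, int],
    n_top: int = 100,
) -> list[str]:
    """Top ``n_top`` genes by |t| from each named cluster, concatenated.

    Ties at the cutoff break toward the lexicographically lower gene id; a
    cluster smaller than ``n_top`` contributes all its genes (logged).
    """
    selected: list[str] = []
    for cluster_id in clusters:
        if cluster_id not in set(clustering.assignment):
            raise ValidationError(f"unknown cluster id {cluster_id}")
        members = clustering.members(cluster_id)
        sub = stats.loc[[g for g in members if g in stats.index]]
        # deterministic: sort by (-|t|, gene id)
        order = sorted(sub.index, key=lambda g: (-abs(sub.at[g, "t"]), g))
        if len(order) < n_top:
            logger.warning(
                "cluster %d has only %d genes (< n_top=%d); taking all",
                cluster_id, len(order), n_top,
            )
        selected.extend(order[:n_top])
    return selected


def build_model(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    genes: list[str],
    samples: list[str] | None = None,
    source_clusters: tuple[int, int] | None = None,
    n_top_per_cluster: int = 100,
) -> PredictorModel:
    """Mean centered-log2 profile over the C/T samples on the gene set.

    ``samples`` restricts the C/T pool (for leave-one-out training); default
    is every C/T sample in the matrix.
    """
    pool = sheet.samples_in("C", "T")
    if samples is not None:
        pool = [s for s in pool if s in set(samples)]
    pool = [s for s in pool if s in set(norm.sample_ids)]
    if not pool:
        raise ValidationError("no C/T samples available for the reference profile")
    known = set(norm.gene_ids)
    missing = [g for g in genes if g not in known]
    if missing:
        raise ValidationError(f"model genes missing from matrix: {missing[:5]}")
    reference = norm.values.loc[genes, pool].mean(axis=1)
    return PredictorModel(
        gene_ids=list(genes),
        reference=reference,
        source_clusters=source_clusters,
        n_top_per_cluster=n_top_per_cluster,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise-complete Pearson correlation; NaN if either vector is constant."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        return np.nan
    scale_x = max(1.0, float(np.abs(x).max()))
    scale_y = max(1.0, float(np.abs(y).max()))
    if x.std() < 1e-12 * scale_x or y.std() < 1e-12 * scale_y:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def classify(r: float, threshold_lo: float = THRESHOLD_LO, threshold_hi: float = THRESHOLD_HI) -> PredictionClass:
    if np.isnan(r):
        return PredictionClass.UNPREDICTABLE
    if r > threshold_hi:
        return PredictionClass.TUMOR_LIKE
    if r < threshold_lo:
        return PredictionClass.HEALTHY_LIKE
    return PredictionClass.UNPREDICTABLE


def score_and_classify(model: PredictorModel, norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-sample correlation with the reference and the three-way call.

    A zero-variance sample vector on the gene set yields r = NA and an
    unpredictable call (logged).
    """
    known = set(norm.gene_ids)
    missing = [g for g in model.gene_ids if g not in known]
    if missing:
        raise ValidationError(f"model genes missing from matrix: {missing[:5]}")
    ref = model.reference.loc[model.gene_ids].to_numpy(dtype=float)
    rows = []
    for sample in norm.sample_ids:
        vec = norm.values.loc[model.gene_ids, sample].to_numpy(dtype=float)
        r = _pearson(vec, ref)
        if np.isnan(r):
            logger.warning("zero-variance profile for sample %s; unpredictable", sample)
        rows.append(
            dict(sample_id=sample, r=r,
                 call=classify(r, model.threshold_lo, model.threshold_hi).value)
        )
    return pd.DataFrame(rows).set_index("sample_id")


def evaluate(
    results: pd.DataFrame,
    sheet: SampleSheet,
    policy: str = "count_as_error",
) -> PredictorEvaluation:
    """Sensitivity, specificity and Fisher exact p of the calls against truth.

    Truth-positive samples are groups C and T.  Abstention policy
    ``count_as_error`` (default) counts unpredictable positives as FN and
    unpredictable negatives as FP; ``exclude`` drops unpredictable samples.
    """
    if policy not in ("count_as_error", "exclude"):
        raise ValueError(f"unknown abstention policy {policy!r}")
    tp = fn = fp = tn = n_unpred = 0
    for sample, row in results.iterrows():
        group = sheet.group_of(sample)
        positive = group in ("C", "T")
        call = row["call"]
        if call == PredictionClass.UNPREDICTABLE.value:
            n_unpred += 1
            if policy == "exclude":
                continue
            if positive:
                fn += 1
            else:
                fp += 1
            continue
        called_tumor = call == PredictionClass.TUMOR_LIKE.value
        if positive and called_tumor:
            tp += 1
        elif positive:
            fn += 1
        elif called_tumor:
            fp += 1
        else:
            tn += 1
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    _, fisher_p = sps.fisher_exact([[tp, fn], [fp, tn]], alternative="two-sided")
    return PredictorEvaluation(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=sensitivity, specificity=specificity,
        fisher_p=float(fisher_p), n_unpredictable=n_unpred,
    )


def _transform_heldout(
    raw_col: pd.Series,
    reference: pd.Series,
    gene_medians: pd.Series,
    span: float,
    space: str = "reference",
) -> pd.Series:
    """Normalize one held-out sample with training-set reference and medians."""
    log_ref = np.log2(reference.to_numpy(dtype=float))
    log_s = np.log2(raw_col.to_numpy(dtype=float))
    m = log_s - log_ref
    a = log_ref if space == "reference" else 0.5 * (log_s + log_ref)
    fitted = _fit_ma_curve(m, a, span)
    corrected = log_ref + m - fitted
    return pd.Series(corrected, index=raw_col.index) - gene_medians


def leave_one_out(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    k: int = 10,
    runs: int = 20,
    seed: int = 0,
    n_top: int = 100,
    span: float = DEFAULT_SPAN,
    policy: str = "count_as_error",
) -> tuple[pd.DataFrame, PredictorEvaluation]:
    """Full leave-one-out evaluation rebuilding everything per fold.

    Each fold re-normalizes the training samples, re-clusters the genes,
    re-selects the discriminant gene set and re-fits the reference profile
    before scoring the held-out sample (normalized against the training
    reference and centered with training gene medians).
    """
    from .normalization import log_median_center, lowess_normalize

    rows = []
    for held_out in expr.sample_ids:
        train_ids = [s for s in expr.sample_ids if s != held_out]
        train = expr.subset_samples(train_ids)
        reference = median_reference(train)
        corrected = lowess_normalize(train, reference=reference, span=span)
        logged = np.log2(corrected.values.to_numpy(dtype=float))
        gene_medians = pd.Series(np.median(logged, axis=1), index=corrected.values.index)
        norm = log_median_center(corrected)
        clust = kmeans_profiles(norm, k=k, runs=runs, seed=seed)
        stats = gene_stats(norm, corrected, sheet, ("C", "T"), ("N", "E"))
        pair = default_cluster_pair(clust, norm, sheet)
        genes = select_discriminant_genes(stats, clust, pair, n_top=n_top)
        model = build_model(norm, sheet, genes, source_clusters=pair, n_top_per_cluster=n_top)
        heldout_norm = _transform_heldout(
            expr.values[held_out], reference, gene_medians, span
        )
        vec = heldout_norm.loc[model.gene_ids].to_numpy(dtype=float)
        ref = model.reference.loc[model.gene_ids].to_numpy(dtype=float)
        r = _pearson(vec, ref)
        rows.append(dict(sample_id=held_out, r=r, call=classify(r).value))
    results = pd.DataFrame(rows).set_index("sample_id")
    return results, evaluate(results, sheet, policy=policy)
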