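"""Beta-value EWAS: sample QC, per-probe t-tests with Bonferroni, smoothed
P-values over genomic probe order, methylation-state calling, locus-level
secondary analysis and plot-ready exports.

State calling uses the fixed bands: mean beta < 0.2 unmethylated, in the
closed interval [0.2, 0.6] hemimethylated, > 0.6 methylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, MethylationState, ProbeManifest, ValidationError
from .stats import bonferroni, pooled_ttest

logger = logging.getLogger(__name__)

HEMI_LO = 0.2
HEMI_HI = 0.6
QC_THRESHOLD = 0.35
_INTERMEDIATE = (0.25, 0.75)
_P_FLOOR = 1e-300  # avoids infinite -log10 scores on underflowed p


def qc_samples(beta: BetaMatrix, threshold: float = QC_THRESHOLD) -> pd.DataFrame:
    """Per-sample share of probes with beta in (0.25, 0.75); pass iff below
    ``threshold``.

    A bimodal (beta-distribution-shaped) methylome has little mass in the
    intermediate band; flattened profiles fail and are routed to the
    secondary locus-specific analysis rather than the EWAS.
    """
    arr = beta.beta.to_numpy(dtype=float)
    if arr.shape[0] < 100:
        raise ValidationError("QC requires at least 100 probes per sample")
    lo, hi = _INTERMEDIATE
    inside = (arr > lo) & (arr < hi)
    valid = ~np.isnan(arr)
    frac = inside.sum(axis=0) / valid.sum(axis=0)
    return pd.DataFrame(
        {
            "fraction_intermediate": frac,
            "pass": frac < threshold,
            "threshold": threshold,
        },
        index=beta.beta.columns,
    )


def call_state(mean_beta: float) -> MethylationState:
    """Band classification of a group-mean beta; boundaries belong to the
    hemimethylated band (closed interval)."""
    if np.isnan(mean_beta) or not 0.0 <= mean_beta <= 1.0:
        raise ValidationError(f"mean beta {mean_beta!r} outside [0,1]")
    if mean_beta < HEMI_LO:
        return MethylationState.UNMETHYLATED
    if mean_beta <= HEMI_HI:
        return MethylationState.HEMIMETHYLATED
    return MethylationState.METHYLATED


def _call_states(mean_beta: np.ndarray) -> np.ndarray:
    return np.asarray([call_state(v).value for v in mean_beta], dtype=object)


def combine_beta(*matrices: BetaMatrix) -> BetaMatrix:
    """Column-concatenate beta matrices sharing the same probe index."""
    first = matrices[0].beta.index
    for m in matrices[1:]:
        if not m.beta.index.equals(first):
            raise ValidationError("beta matrices have different probe indices")
    return BetaMatrix(pd.concat([m.beta for m in matrices], axis=1))


def ewas(beta: BetaMatrix, tumor_ids: list[str], control_ids: list[str]) -> pd.DataFrame:
    """Per-probe two-sided pooled-variance t-test of tumor vs control betas.

    Returns one row per probe (input order) with group means, delta beta,
    t, p, Bonferroni-corrected p (m = probes tested) and the state calls of
    both arms.
    """
    for ids, name in ((tumor_ids, "tumor"), (control_ids, "control")):
        missing = [s for s in ids if s not in set(beta.sample_ids)]
        if missing:
            raise ValidationError(f"{name} samples missing from matrix: {missing}")
        if len(ids) < 2:
            raise ValidationError(f"need >= 2 {name} samples after QC")
    tum = beta.beta[list(tumor_ids)].to_numpy(dtype=float)
    ctl = beta.beta[list(control_ids)].to_numpy(dtype=float)
    t, p = pooled_ttest(tum, ctl)
    mean_t = np.nanmean(tum, axis=1)
    mean_c = np.nanmean(ctl, axis=1)
    return pd.DataFrame(
        {
            "mean_beta_tumor": mean_t,
            "mean_beta_control": mean_c,
            "delta_beta": mean_t - mean_c,
            "t_stat": t,
            "p": p,
            "p_bonferroni": bonferroni(p, len(p)),
            "state_tumor": _call_states(mean_t),
            "state_control": _call_states(mean_c),
        },
        index=beta.beta.index,
    )


def _windowed_mean(scores: np.ndarray, radius: int) -> np.ndarray:
    """Mean over the index window [i - radius, i + radius] truncated at the ends."""
    n = scores.size
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    lo = np.maximum(np.arange(n) - radius, 0)
    hi = np.minimum(np.arange(n) + radius, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def smooth_pvalues(
    results: pd.DataFrame, manifest: ProbeManifest, radius: int = 3
) -> pd.DataFrame:
    """Attach ``p_smoothed``: 10**(-mean of -log10 p over a probe-index window).

    Probes are ordered by (chromosome, position); chromosomes are smoothed
    independently.  Probes without manifest coordinates get p_smoothed = NA.
    Row order of ``results`` is preserved.
    """
    out = results.copy()
    out["p_smoothed"] = np.nan
    known = set(manifest.probe_ids)
    in_manifest = set(p for p in out.index if p in known)
    skipped = len(out) - len(in_manifest)
    if skipped:
        logger.warning("%d probes lack manifest coordinates; p_smoothed = NA", skipped)
    ordered = [p for p in manifest.genomic_order() if p in in_manifest]
    chroms = manifest.table.loc[ordered, "chromosome"].to_numpy()
    pvals = out.loc[ordered, "p"].to_numpy(dtype=float)
    scores = -np.log10(np.maximum(pvals, _P_FLOOR))
    smoothed = np.empty_like(scores)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        smoothed[mask] = _windowed_mean(scores[mask], radius)
    out.loc[ordered, "p_smoothed"] = 10.0 ** (-smoothed)
    return out


@dataclass
class LocusSummary:
    island_id: str
    probes: pd.DataFrame  # EWAS rows restricted to the island, genomic order
    n_hemimethylated_tumor: int
    verdict: str  # concordant_hemimethylation | mixed | null
    extra_states: pd.DataFrame | None = None  # QC-failed samples, if supplied


def locus_analysis(
    results: pd.DataFrame,
    manifest: ProbeManifest,
    island_id: str,
    extra_beta: BetaMatrix | None = None,
) -> LocusSummary:
    """Secondary locus-specific analysis of one CpG island.

    Verdict is ``concordant_hemimethylation`` iff every probe of the island is
    hemimethylated in tumor and unmethylated in control, ``null`` if no probe
    shows that pattern, ``mixed`` otherwise.  QC-failed samples supplied in
    ``extra_beta`` are summarized separately (per-probe mean beta and state).
    """
    probe_ids = manifest.island_probes(island_id)
    have = set(results.index)
    present = [p for p in probe_ids if p in have]
    if not present:
        raise ValidationError(f"island {island_id!r} has no probes in the results")
    sub = results.loc[present]
    hemi = (sub["state_tumor"] == MethylationState.HEMIMETHYLATED.value) & (
        sub["state_control"] == MethylationState.UNMETHYLATED.value
    )
    if hemi.all():
        verdict = "concordant_hemimethylation"
    elif hemi.any():
        verdict = "mixed"
    else:
        verdict = "null"
    extra_states = None
    if extra_beta is not None and extra_beta.beta.shape[1] > 0:
        on_island = [p for p in present if p in set(extra_beta.probe_ids)]
        means = extra_beta.beta.loc[on_island].mean(axis=1)
        extra_states = pd.DataFrame(
            {"mean_beta": means, "state": _call_states(means.to_numpy())}
        )
    return LocusSummary(
        island_id=island_id,
        probes=sub,
        n_hemimethylated_tumor=int(
            (sub["state_tumor"] == MethylationState.HEMIMETHYLATED.value).sum()
        ),
        verdict=verdict,
        extra_states=extra_states,
    )


def locus_min_smoothed_p(results: pd.DataFrame, manifest: ProbeManifest) -> pd.Series:
    """Minimum smoothed p per island, ascending (locus ranking for top-hit scans)."""
    known = set(manifest.probe_ids)
    islands = manifest.table.loc[
        [p for p in results.index if p in known], "island_id"
    ]
    per_locus = results.loc[islands.index, "p_smoothed"].groupby(islands).min()
    return per_locus.sort_values(kind="stable")


def export_manhattan_volcano(
    results: pd.DataFrame, manifest: ProbeManifest
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables.

    Manhattan: (chromosome, position, neg_log10_p_smoothed) in genomic order,
    rows with NA smoothed p omitted.  Volcano: (delta_beta, neg_log10_p) for
    every probe, input order retained.
    """
    have = set(results.index)
    ordered = [p for p in manifest.genomic_order() if p in have]
    man = pd.DataFrame(
        {
            "chromosome": manifest.table.loc[ordered, "chromosome"],
            "position": manifest.table.loc[ordered, "position"],
            "neg_log10_p_smoothed": -np.log10(
                np.maximum(results.loc[ordered, "p_smoothed"].to_numpy(dtype=float), _P_FLOOR)
            ),
        },
        index=pd.Index(ordered, name="id"),
    )
    man = man[~results.loc[ordered, "p_smoothed"].isna().to_numpy()]
    vol = pd.DataFrame(
        {
            "delta_beta": results["delta_beta"],
            "neg_log10_p": -np.log10(np.maximum(results["p"].to_numpy(dtype=float), _P_FLOOR)),
        },
        index=results.index,
    )
    return man, vol
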