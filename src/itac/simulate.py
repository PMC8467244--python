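"""Synthetic expression and methylation generators with full planted truth.

The expression scenario emulates a 4-group cohort (N/E/C/T) whose genes fall
into 10 profile archetypes — two differential in both C and T, two
differential in T only, six null — plus named planted genes whose tumor/normal
fold change is specified on the unlogged group-mean scale.  The methylation
scenario produces bimodal (beta-shaped) methylomes with two planted
tumor-hemimethylated CpG islands and a set of flattened QC-failing tumor
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    ExpressionMatrix,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

GROUP_ORDER = ("N", "E", "C", "T")

# per-group log2 offsets (N, E, C, T) for the 10 default archetypes
DEFAULT_ARCHETYPES: tuple[tuple[float, float, float, float], ...] = (
    (0.0, 0.0, 1.0, 1.0),  # up in C and T
    (0.0, 0.0, -1.0, -1.0),  # down in C and T
    (0.0, 0.0, 0.0, 1.0),  # up in T only
    (0.0, 0.0, 0.0, -1.0),  # down in T only
    (0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0, 0.0),
)
DIFFERENTIAL_ARCHETYPES = (1, 2, 3, 4)  # 1-based ids of the non-null archetypes


def _default_planted() -> dict[str, dict[str, float]]:
    # planted genes: per-group log2 offsets; T offset encodes the unlogged
    # group-mean T/N fold change (log2 of it), C partially elevated for CDX2
    return {
        "CDX2": {"N": 0.0, "E": 0.0, "C": math.log2(1.6), "T": math.log2(2.46)},
        "CACNA1C": {"N": 0.0, "E": 0.0, "C": 0.0, "T": math.log2(1.52)},
    }


@dataclass
class ExpressionScenario:
    n_genes: int = 2000
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"N": 13, "E": 16, "C": 13, "T": 13}
    )
    archetypes: tuple = DEFAULT_ARCHETYPES
    # genes per non-null archetype; keeping the differential fraction modest
    # limits the signal-induced M-vs-A tilt the LOWESS step would absorb
    diff_archetype_size: int = 50
    noise_sd: float = 0.3
    planted_genes: dict[str, dict[str, float]] = field(default_factory=_default_planted)
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.0
    bias_amplitude: float = 0.0  # per-sample intensity-dependent bias, for LOWESS tests

    @classmethod
    def from_dict(cls, d: dict) -> "ExpressionScenario":
        kw = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**kw)


def generate_expression(
    scenario: ExpressionScenario, seed: int
) -> tuple[ExpressionMatrix, SampleSheet, dict]:
    """Simulate a raw intensity matrix, its sample sheet and the planted truth.

    Truth tables: ``archetype`` (gene -> archetype id, 0 for planted genes),
    ``planted`` (per-gene per-group log2 offsets and the implied T/N fold
    change on the unlogged group-mean scale).
    """
    for g in GROUP_ORDER:
        if scenario.n_per_group.get(g, 0) < 1:
            raise ValidationError(f"group {g} must have at least 1 sample")
    rng = np.random.default_rng(seed)
    planted = dict(scenario.planted_genes)
    n_regular = scenario.n_genes - len(planted)
    if n_regular < len(scenario.archetypes):
        raise ValidationError("n_genes too small for the archetype design")
    width = len(str(n_regular))
    regular_ids = [f"G{i + 1:0{width}d}" for i in range(n_regular)]
    gene_ids = regular_ids + list(planted)
    arch_mat_check = np.asarray(scenario.archetypes, dtype=float)
    is_null = ~np.any(arch_mat_check != 0, axis=1)
    archetype = np.empty(n_regular, dtype=int)
    pos = 0
    for a in np.flatnonzero(~is_null):  # fixed-size differential archetypes first
        archetype[pos : pos + scenario.diff_archetype_size] = a
        pos += scenario.diff_archetype_size
    if pos > n_regular:
        raise ValidationError("diff_archetype_size too large for n_genes")
    null_ids = np.flatnonzero(is_null)
    if null_ids.size:
        archetype[pos:] = null_ids[np.arange(n_regular - pos) % null_ids.size]
    elif pos < n_regular:
        raise ValidationError("no null archetype to absorb remaining genes")

    sample_ids, groups = [], []
    for g in GROUP_ORDER:
        for i in range(scenario.n_per_group[g]):
            sample_ids.append(f"{g}{i + 1:02d}")
            groups.append(g)
    group_idx = {g: i for i, g in enumerate(GROUP_ORDER)}
    col_group = np.array([group_idx[g] for g in groups])

    arch_mat = np.asarray(scenario.archetypes, dtype=float)  # 10 x 4
    offsets = np.vstack(
        [
            arch_mat[archetype],  # regular genes
            np.array([[planted[g][grp] for grp in GROUP_ORDER] for g in planted]),
        ]
    )  # genes x 4
    baseline = rng.normal(scenario.baseline_mean_log2, scenario.baseline_sd_log2, len(gene_ids))
    logv = (
        baseline[:, None]
        + offsets[:, col_group]
        + rng.normal(0.0, scenario.noise_sd, (len(gene_ids), len(sample_ids)))
    )
    if scenario.bias_amplitude > 0:
        amp = rng.uniform(-scenario.bias_amplitude, scenario.bias_amplitude, len(sample_ids))
        logv = logv + amp[None, :] * np.sin(logv)
    values = pd.DataFrame(np.exp2(logv), index=gene_ids, columns=sample_ids)

    sheet = SampleSheet(pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="id")))
    truth = {
        "archetype": pd.Series(
            np.concatenate([archetype + 1, np.zeros(len(planted), dtype=int)]),
            index=gene_ids,
            name="archetype",
        ),
        "planted": pd.DataFrame(
            {
                "gene": list(planted),
                **{f"offset_{g}": [planted[x][g] for x in planted] for g in GROUP_ORDER},
                "fc_t_n": [2.0 ** (planted[x]["T"] - planted[x]["N"]) for x in planted],
            }
        ).set_index("gene"),
    }
    return ExpressionMatrix(values), sheet, truth


@dataclass
class PlantedIsland:
    island_id: str
    n_probes: int
    gene: str
    tumor_mean: float = 0.4
    tumor_sd: float = 0.05
    control_mean: float = 0.05
    control_sd: float = 0.02


@dataclass
class MethylationScenario:
    n_probes: int = 20000
    n_chromosomes: int = 22
    island_size: int = 5  # null islands: runs of consecutive probes
    n_tumor_good: int = 4
    n_tumor_bad_qc: int = 7
    n_control: int = 72
    planted_islands: tuple = (
        PlantedIsland("CpG:84", 6, "CACNA1C-AS1"),
        PlantedIsland("CpG:41", 9, "SLC26A10"),
    )
    unmeth_shape: tuple[float, float] = (1.0, 10.0)
    meth_shape: tuple[float, float] = (10.0, 1.0)
    flat_shape: tuple[float, float] = (1.5, 1.5)  # QC-failing samples

    @classmethod
    def from_dict(cls, d: dict) -> "MethylationScenario":
        kw = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**kw)


def _beta_shape(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) parameters with the requested mean and sd."""
    nu = mean * (1 - mean) / sd**2 - 1
    if nu <= 0:
        raise ValidationError(f"sd {sd} too large for mean {mean}")
    return mean * nu, (1 - mean) * nu


def generate_methylation(
    scenario: MethylationScenario, seed: int
) -> tuple[BetaMatrix, BetaMatrix, ProbeManifest, dict]:
    """Simulate tumor and control beta matrices, a probe manifest and truth.

    Tumor columns are the QC-good samples followed by the flattened QC-bad
    ones; the planted islands stay hemimethylated in every tumor sample so the
    secondary locus analysis can confirm them on the QC-failed set.
    """
    if scenario.n_tumor_good < 2 or scenario.n_control < 2:
        raise ValidationError("need at least 2 QC-good tumor and 2 control samples")
    per_chrom = -(-scenario.n_probes // scenario.n_chromosomes)  # ceil
    for isl in scenario.planted_islands:
        if isl.n_probes > per_chrom:
            raise ValidationError(
                f"island {isl.island_id} ({isl.n_probes} probes) exceeds the "
                f"per-chromosome probe budget ({per_chrom})"
            )
    rng = np.random.default_rng(seed)

    probe_ids = [f"cg{i + 1:08d}" for i in range(scenario.n_probes)]
    chrom_idx = np.arange(scenario.n_probes) // per_chrom
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    pos_in_chrom = np.arange(scenario.n_probes) % per_chrom
    positions = 1 + pos_in_chrom * 1000

    # null islands: runs of island_size consecutive probes, restarting per
    # chromosome; counter skips ids reserved for the planted islands
    reserved = {int(isl.island_id.split(":")[1]) for isl in scenario.planted_islands}
    island_ids = np.empty(scenario.n_probes, dtype=object)
    counter = 0
    for i in range(scenario.n_probes):
        if pos_in_chrom[i] % scenario.island_size == 0 or pos_in_chrom[i] == 0:
            counter += 1
            while counter in reserved:
                counter += 1
        island_ids[i] = f"CpG:{counter}"
    genes = np.array([f"GENE{i // scenario.island_size + 1}" for i in range(scenario.n_probes)], dtype=object)

    # plant the two islands on the last chromosome, well inside its block
    planted_rows: dict[str, list[str]] = {}
    last_start = (scenario.n_chromosomes - 1) * per_chrom
    offset = 10
    for isl in scenario.planted_islands:
        start = last_start + offset
        stop = start + isl.n_probes
        if stop > scenario.n_probes:
            raise ValidationError("planted islands exceed the probe budget")
        island_ids[start:stop] = isl.island_id
        genes[start:stop] = isl.gene
        planted_rows[isl.island_id] = probe_ids[start:stop]
        offset += isl.n_probes + 20  # leave a null gap between planted islands

    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "chromosome": chroms,
                "position": positions,
                "gene": genes,
                "island_id": island_ids,
            },
            index=pd.Index(probe_ids, name="id"),
        )
    )

    n_tumor = scenario.n_tumor_good + scenario.n_tumor_bad_qc
    tumor_ids = [f"T{i + 1:02d}" for i in range(n_tumor)]
    good_ids = tumor_ids[: scenario.n_tumor_good]
    bad_ids = tumor_ids[scenario.n_tumor_good :]
    control_ids = [f"CTL{i + 1:02d}" for i in range(scenario.n_control)]

    methylated_probe = rng.random(scenario.n_probes) < 0.5  # background bimodality
    au, bu = scenario.unmeth_shape
    am, bm = scenario.meth_shape

    def background(n_cols: int) -> np.ndarray:
        out = np.empty((scenario.n_probes, n_cols))
        out[~methylated_probe] = rng.beta(au, bu, ((~methylated_probe).sum(), n_cols))
        out[methylated_probe] = rng.beta(am, bm, (methylated_probe.sum(), n_cols))
        return out

    tumor = np.empty((scenario.n_probes, n_tumor))
    tumor[:, : scenario.n_tumor_good] = background(scenario.n_tumor_good)
    af, bf = scenario.flat_shape
    tumor[:, scenario.n_tumor_good :] = rng.beta(
        af, bf, (scenario.n_probes, scenario.n_tumor_bad_qc)
    )
    control = background(scenario.n_control)

    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    for isl in scenario.planted_islands:
        rows = [probe_pos[p] for p in planted_rows[isl.island_id]]
        at, bt = _beta_shape(isl.tumor_mean, isl.tumor_sd)
        ac, bc = _beta_shape(isl.control_mean, isl.control_sd)
        tumor[rows, :] = rng.beta(at, bt, (len(rows), n_tumor))
        control[rows, :] = rng.beta(ac, bc, (len(rows), scenario.n_control))

    truth = {
        "planted_islands": {
            isl.island_id: {
                "probes": planted_rows[isl.island_id],
                "gene": isl.gene,
                "tumor_mean": isl.tumor_mean,
                "control_mean": isl.control_mean,
            }
            for isl in scenario.planted_islands
        },
        "qc_good_samples": good_ids,
        "qc_bad_samples": bad_ids,
        "methylated_probe": pd.Series(methylated_probe, index=probe_ids),
    }
    tumor_bm = BetaMatrix(pd.DataFrame(tumor, index=probe_ids, columns=tumor_ids))
    control_bm = BetaMatrix(pd.DataFrame(control, index=probe_ids, columns=control_ids))
    return tumor_bm, control_bm, manifest, truth
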