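"""Core data types shared by every pipeline stage.

All tabular containers wrap :class:`pandas.DataFrame` objects and validate
their invariants at construction time.  Row/column order is always preserved
exactly as supplied (readers never reorder).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

GROUPS = ("N", "E", "C", "T")


class ValidationError(ValueError):
    """Raised when a matrix or sheet violates a structural invariant."""


class PredictionClass(str, Enum):
    TUMOR_LIKE = "tumor_like"
    HEALTHY_LIKE = "healthy_like"
    UNPREDICTABLE = "unpredictable"


class MethylationState(str, Enum):
    UNMETHYLATED = "unmethylated"
    HEMIMETHYLATED = "hemimethylated"
    METHYLATED = "methylated"


@dataclass
class SampleSheet:
    """Maps sample ids to one of the four groups N/E/C/T.

    ``table`` is indexed by sample id with a ``group`` column and an optional
    ``quality_note`` column.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValidationError("sample sheet requires a 'group' column")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups}")
        bad = sorted(set(self.table["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels {bad}; expected one of {GROUPS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def samples_in(self, *groups: str) -> list[str]:
        """Sample ids whose group is one of ``groups``, in sheet order."""
        wanted = set(groups)
        return [s for s, g in self.table["group"].items() if g in wanted]


@dataclass
class ExpressionMatrix:
    """Gene x sample raw intensities; strictly positive."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        arr = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.argwhere(~(arr > 0) & ~np.isnan(arr))  # NA cells are allowed
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-positive intensity {arr[r, c]!r} at gene {v.index[r]!r}, "
                f"sample {v.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)])


@dataclass
class NormalizedMatrix:
    """Gene x sample log2 values, gene-median-centered."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("normalized matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class BetaMatrix:
    """CpG-probe x sample methylation fractions in [0, 1].

    Out-of-range values are rejected, never clipped; NA cells are allowed and
    handled listwise per probe downstream.
    """

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        b = self.beta
        if b.index.has_duplicates:
            dups = b.index[b.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        arr = b.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.argwhere((arr < 0) | (arr > 1))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"beta value {arr[r, c]!r} outside [0,1] at probe {b.index[r]!r}, "
                f"sample {b.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


MANIFEST_COLUMNS = ("chromosome", "position", "gene", "island_id")


@dataclass
class ProbeManifest:
    """Probe annotation: chromosome, 1-based position, gene symbol, island id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids in manifest: {dups}")
        pos = self.table["position"].to_numpy()
        if not np.issubdtype(np.asarray(pos).dtype, np.number) or np.any(pos < 1):
            raise ValidationError("manifest positions must be numeric and 1-based (>= 1)")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def genomic_order(self) -> pd.Index:
        """Probe ids sorted by (chromosome, position); stable within ties."""
        ordered = self.table.sort_values(["chromosome", "position"], kind="stable")
        return ordered.index

    def island_probes(self, island_id: str) -> list[str]:
        sub = self.table[self.table["island_id"] == island_id]
        if sub.empty:
            raise ValidationError(f"island {island_id!r} has no probes in manifest")
        return list(sub.sort_values("position", kind="stable").index)
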