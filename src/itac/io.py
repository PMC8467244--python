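"""Readers/writers for the tab-separated exchange formats.

Dialect: UTF-8, tab separators, ``.`` decimal, no quoting, missing values
encoded ``NA``, first header cell fixed to ``id``.  Writing then reading is
the identity on the canonical form (floats are serialized with shortest
round-trip repr and parsed back exactly).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .datamodel import (
    BetaMatrix,
    ExpressionMatrix,
    NormalizedMatrix,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

_READ_KW = dict(sep="\t", index_col=0, float_precision="round_trip", na_values=["NA"], keep_default_na=False)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(_read_table(path))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    _write_table(sheet.table, path)


def read_expression(path, sheet_path) -> tuple[ExpressionMatrix, SampleSheet]:
    """Read a gene x sample intensity table plus its sample sheet.

    Every sample in the matrix must be declared in the sheet; non-positive
    intensities are rejected with the offending cell named.
    """
    sheet = read_sample_sheet(sheet_path)
    df = _read_table(path)
    missing = [s for s in df.columns if s not in sheet.table.index]
    if missing:
        raise ValidationError(f"samples absent from sheet: {missing}")
    return ExpressionMatrix(df), sheet


def write_expression(expr: ExpressionMatrix, path) -> None:
    _write_table(expr.values, path)


def read_normalized(path) -> NormalizedMatrix:
    return NormalizedMatrix(_read_table(path))


def write_normalized(norm: NormalizedMatrix, path) -> None:
    _write_table(norm.values, path)


def read_manifest(path) -> ProbeManifest:
    return ProbeManifest(_read_table(path))


def write_manifest(manifest: ProbeManifest, path) -> None:
    _write_table(manifest.table, path)


def read_beta(path, manifest_path) -> tuple[BetaMatrix, ProbeManifest, list[str]]:
    """Read a probe x sample beta table and its probe manifest.

    Probes present in the beta matrix but absent from the manifest are not an
    error: a warning per probe is recorded (and emitted) and those probes are
    simply excluded from position-dependent operations downstream.
    """
    manifest = read_manifest(manifest_path)
    beta = BetaMatrix(_read_table(path))
    known = set(manifest.probe_ids)
    warn_list = [
        f"probe {p!r} absent from manifest; excluded from position-dependent analyses"
        for p in beta.probe_ids
        if p not in known
    ]
    for msg in warn_list:
        warnings.warn(msg, stacklevel=2)
    return beta, manifest, warn_list


def write_beta(beta: BetaMatrix, path) -> None:
    _write_table(beta.beta, path)


def validate_expression(path, sheet_path) -> list[str]:
    """Validate an expression table + sheet; returns a list of error strings."""
    try:
        read_expression(path, sheet_path)
    except (ValidationError, KeyError) as exc:
        return [str(exc)]
    return []


def validate_beta(path, manifest_path) -> list[str]:
    try:
        _, _, warn_list = read_beta(path, manifest_path)
    except ValidationError as exc:
        return [str(exc)]
    return []
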