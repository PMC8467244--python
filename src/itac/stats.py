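"""Shared statistical primitives (vectorized pooled-variance t-test)."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided pooled-variance Student t-test along rows.

    ``a`` and ``b`` are 2-D arrays (features x samples); NaN cells are dropped
    listwise within each row.  Returns ``(t, p)`` per row.  Rows where either
    arm has fewer than 2 non-missing values get NaN.  A row with zero pooled
    variance yields t = 0, p = 1 when the means are equal and |t| = inf,
    p = 0 otherwise.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na = np.sum(~np.isnan(a), axis=1).astype(float)
    nb = np.sum(~np.isnan(b), axis=1).astype(float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    df = na + nb - 2.0
    sp2 = np.where(df > 0, ((na - 1) * va + (nb - 1) * vb) / np.where(df > 0, df, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / se
    diff = ma - mb
    zero_var = (sp2 == 0) | (se == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (diff == 0), 0.0, t)
        t = np.where(zero_var & (diff != 0), np.sign(diff) * np.inf, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), np.where(df > 0, df, 1.0))
    invalid = (na < 2) | (nb < 2)
    t = np.where(invalid, np.nan, t)
    p = np.where(invalid, np.nan, p)
    return t, p


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m); NaN propagates."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = int(np.sum(~np.isnan(p)))
    return np.minimum(1.0, p * m)
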