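"""Cross-dataset replication by sign concordance of differential genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceReport:
    n_common: int
    n_concordant: int
    n_significant_both: int
    n_concordant_significant: int
    per_gene: pd.DataFrame  # gene, sign_a, sign_b, p_a, p_b, concordant


def stats_to_signs(stats: pd.DataFrame) -> pd.DataFrame:
    """Condense a per-gene stats table to (sign, p, abs_t).

    Direction is the sign of the mean logged difference, i.e. the sign of t.
    Duplicate gene symbols collapse to the row with the largest |t| (logged).
    """
    out = pd.DataFrame(
        {"sign": np.sign(stats["t"]).astype(int), "p": stats["p"], "abs_t": stats["t"].abs()}
    )
    if out.index.has_duplicates:
        n_dups = int(out.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene symbols to max |t|", n_dups)
        out = out.sort_values("abs_t", ascending=False, kind="stable")
        out = out[~out.index.duplicated(keep="first")]
        out = out.loc[[g for g in stats.index.unique() if g in out.index]]
    return out


def concordance(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame, alpha: float = 0.05
) -> ConcordanceReport:
    """Count genes whose direction of change agrees between two datasets.

    Both tables must carry ``sign`` and ``p`` columns indexed by gene symbol
    (see :func:`stats_to_signs`).  Genes are matched by exact symbol; a zero
    sign on either side counts as discordant.  The significant subset is
    p < alpha in both datasets.
    """
    for name, df in (("A", stats_a), ("B", stats_b)):
        missing = [c for c in ("sign", "p") if c not in df.columns]
        if missing:
            raise ValidationError(f"stats table {name} missing columns {missing}")
    common = [g for g in stats_a.index if g in set(stats_b.index)]
    if not common:
        raise ValidationError("no common genes between datasets")
    sign_a = stats_a.loc[common, "sign"].astype(int)
    sign_b = stats_b.loc[common, "sign"].astype(int)
    p_a = stats_a.loc[common, "p"].astype(float)
    p_b = stats_b.loc[common, "p"].astype(float)
    concordant = (sign_a == sign_b) & (sign_a != 0)
    significant = (p_a < alpha) & (p_b < alpha)
    per_gene = pd.DataFrame(
        {
            "sign_a": sign_a,
            "sign_b": sign_b,
            "p_a": p_a,
            "p_b": p_b,
            "concordant": concordant,
            "significant_both": significant,
        },
        index=pd.Index(common, name="gene"),
    )
    return ConcordanceReport(
        n_common=len(common),
        n_concordant=int(concordant.sum()),
        n_significant_both=int(significant.sum()),
        n_concordant_significant=int((concordant & significant).sum()),
        per_gene=per_gene,
    )
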