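"""Jaccard similarity between gene signatures and Ro/e enrichment of
ligand-receptor pairs across ecosystems.

Ro/e is the ratio of the observed count of a ligand-receptor pair within a
group to its expectation under independence of pairs and groups — the
chi-square expected count ``row_total * col_total / grand_total``. A pair is
enriched in a group iff Ro/e > 1 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RoeResult",
    "jaccard_similarity",
    "expected_counts",
    "roe",
    "top_k_pairs",
    "filter_interaction_frequency",
]


@dataclass
class RoeResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    roe: pd.DataFrame
    enriched: pd.DataFrame  # boolean; False where expected == 0 (undefined)
    undefined: pd.DataFrame  # boolean mask of cells with expected == 0


def jaccard_similarity(a, b) -> float:
    """|A ∩ B| / |A ∪ B| for two gene sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(sa & sb) / len(sa | sb)


def _as_counts(table: pd.DataFrame) -> pd.DataFrame:
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("interaction counts must be nonnegative")
    return table.astype(float)


def expected_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Chi-square expected counts from the table margins.

    ``expected[i, j] = row_total[i] * col_total[j] / grand_total``; margins are
    preserved exactly.
    """
    table = _as_counts(table)
    total = float(table.to_numpy().sum())
    if total <= 0:
        raise ValueError("degenerate table: zero grand total")
    rows = table.sum(axis=1).to_numpy()
    cols = table.sum(axis=0).to_numpy()
    exp = np.outer(rows, cols) / total
    return pd.DataFrame(exp, index=table.index, columns=table.columns)


def roe(table: pd.DataFrame) -> RoeResult:
    """Observed/expected ratio per (pair, group); enrichment is strict Ro/e > 1.

    Cells with zero expected count are flagged undefined (Ro/e reported as NaN)
    and never enriched.
    """
    table = _as_counts(table)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("Ro/e needs at least 2 pairs and 2 groups")
    exp = expected_counts(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = table.to_numpy() / exp.to_numpy()
    undefined = exp.to_numpy() == 0
    ratio = np.where(undefined, np.nan, ratio)
    ratio_df = pd.DataFrame(ratio, index=table.index, columns=table.columns)
    enriched = pd.DataFrame((ratio > 1) & ~undefined,
                            index=table.index, columns=table.columns)
    if undefined.any():
        logger.warning("%d cells have zero expected count; flagged undefined",
                       int(undefined.sum()))
    return RoeResult(observed=table, expected=exp, roe=ratio_df, enriched=enriched,
                     undefined=pd.DataFrame(undefined, index=table.index,
                                            columns=table.columns))


def top_k_pairs(result: RoeResult, group: str, k: int = 10) -> list[str]:
    """The ``k`` pairs with the highest Ro/e within ``group``.

    Ties break by observed count (descending) then pair id; undefined cells are
    excluded. Fewer than ``k`` available pairs are all returned with a warning.
    """
    col = result.roe[group]
    obs = result.observed[group]
    valid = col.dropna()
    ranked = sorted(valid.index,
                    key=lambda p: (-valid[p], -obs[p], str(p)))
    if k > len(ranked):
        logger.warning("requested top %d pairs but only %d available in %s",
                       k, len(ranked), group)
    return ranked[:k]


def filter_interaction_frequency(frequencies: dict[str, float] | pd.Series,
                                 lo: float = 0.001, hi: float = 0.02) -> list[str]:
    """Retain pairs whose significant-interaction frequency lies inside [lo, hi].

    The frequency is the fraction of cluster-cluster combinations in which the
    pair is significant. The retain-inside direction is a documented choice
    (see the methods note) and both bounds are configurable.
    """
    freq = pd.Series(frequencies)
    return [str(p) for p, f in freq.items() if lo <= f <= hi]
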