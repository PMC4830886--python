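"""Transfer-corrected potency and concordance with an in vivo ranking.

The in vitro benchmark concentration (BMC_d50, uM) is divided by the
relative placental-transfer rate (relative Papp, dimensionless) to give
a corrected potency score: compounds that cross the barrier slowly need
a proportionally higher maternal exposure to reach the same fetal
concentration, so their effective potency is down-weighted.  Lower
corrected BMC = more potent.  Orderings from different methods are
compared with Spearman's rho and Kendall's tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompoundSummary",
    "corrected_bmc",
    "potency_ranking",
    "rank_concordance",
    "build_summary_table",
]


@dataclass
class CompoundSummary:
    """Potency summary for one compound (rank 1 = most potent/toxic)."""

    compound_id: str
    bmc_d50: float
    relative_papp: float
    corrected_bmc_d50: float
    in_vitro_rank: int | None = None
    corrected_rank: int | None = None
    in_vivo_rank: int | None = None


def corrected_bmc(bmc_d50_um: float, relative_papp: float) -> float:
    """Transfer-corrected potency: BMC_d50 / relative Papp (uM)."""
    if relative_papp <= 0:
        raise ValueError("relative Papp must be strictly positive")
    return bmc_d50_um / relative_papp


def potency_ranking(values: Mapping[str, float]) -> list[str]:
    """Order compounds most potent (lowest value) first.

    Ties are flagged with a warning and broken by compound id so the
    output is deterministic.
    """
    if len(values) == 0:
        raise ValueError("no compounds supplied")
    items = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    vals = [v for _, v in items]
    if len(set(vals)) != len(vals):
        warnings.warn("tied potency values; ties broken by compound id", stacklevel=2)
    return [k for k, _ in items]


def _ranks(order: Sequence[str]) -> dict[str, int]:
    return {c: i + 1 for i, c in enumerate(order)}


def rank_concordance(
    order_a: Sequence[str], order_b: Sequence[str]
) -> tuple[float, float, int]:
    """Spearman's rho, Kendall's tau and the discordant-pair count
    between two orderings of the same compound set."""
    set_a, set_b = set(order_a), set(order_b)
    if set_a != set_b:
        raise ValueError(
            f"orderings differ in compounds: only in a: {sorted(set_a - set_b)}, "
            f"only in b: {sorted(set_b - set_a)}"
        )
    if len(order_a) != len(set_a):
        raise ValueError("orderings contain duplicates")
    ra, rb = _ranks(order_a), _ranks(order_b)
    compounds = sorted(set_a)
    x = np.array([ra[c] for c in compounds], dtype=float)
    y = np.array([rb[c] for c in compounds], dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    tau = float(stats.kendalltau(x, y).statistic)
    n_disc = 0
    for i in range(len(compounds)):
        for j in range(i + 1, len(compounds)):
            if (x[i] - x[j]) * (y[i] - y[j]) < 0:
                n_disc += 1
    return rho, tau, n_disc


def build_summary_table(
    bmc_d50: Mapping[str, float],
    relative_papp: Mapping[str, float],
    in_vivo_order_most_potent_first: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-compound summary with corrected BMC and the three rankings.

    Ranks are 1 = most potent.  The in vivo ranking is an external input
    (an expert-derived ordered list), not computed here.
    """
    compounds = sorted(bmc_d50)
    missing = [c for c in compounds if c not in relative_papp]
    if missing:
        raise ValueError(f"relative Papp missing for: {missing}")
    corrected = {c: corrected_bmc(bmc_d50[c], relative_papp[c]) for c in compounds}
    vitro_order = potency_ranking(dict(bmc_d50))
    corr_order = potency_ranking(corrected)
    rv, rc = _ranks(vitro_order), _ranks(corr_order)
    ri = (
        _ranks(in_vivo_order_most_potent_first)
        if in_vivo_order_most_potent_first is not None
        else None
    )
    rows = []
    for c in compounds:
        rows.append(
            {
                "compound": c,
                "bmc_d50_um": bmc_d50[c],
                "relative_papp": relative_papp[c],
                "corrected_bmc_d50_um": corrected[c],
                "in_vitro_rank": rv[c],
                "corrected_rank": rc[c],
                "in_vivo_rank": ri[c] if ri is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows).set_index("compound")
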