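"""Area under the discounting curve (AUC), standard and ordinal.

The AUC summarizes an indifference curve without committing to a
discounting equation: IPs are normalized by the larger amount A, the cost
axis is mapped onto [0, 1], and the areas of the trapezoids between
adjacent points are summed, x2 - x1 * [(y1 + y2) / 2] per segment.  The
*ordinal* AUC replaces numeric costs with their ranks 1..5 before
normalizing, which removes the influence of the (often skewed) spacing of
the cost levels; lower values mean steeper discounting (more impatience,
risk aversion, or effort aversion).

A zero-cost anchor (x = 0, y = 1) is prepended by default so five IPs form
five trapezoids and the measure spans the full [0, 1] range.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .schedules import normalize_costs, ordinal_ranks
from .titration import IndifferenceCurve

__all__ = ["auc_trapezoid", "auc_table", "AUC_COLUMNS"]

AUC_COLUMNS = ["participant_id", "timepoint", "task", "auc", "auc_ord"]


def auc_trapezoid(
    costs,
    ips,
    amount: float,
    cost_encoding: str = "ordinal",
    anchor: bool = True,
    anchor_y: float = 1.0,
) -> float:
    """Normalized area under one indifference curve.

    Parameters
    ----------
    costs, ips
        Equal-length increasing cost levels and their indifference points
        (in currency units, each within [0, amount]).
    amount
        The larger amount A used to normalize the IPs.
    cost_encoding
        ``"ordinal"`` uses ranks 1..k divided by k as the x axis;
        ``"raw_normalized"`` divides raw costs by the maximum cost.
    anchor
        Prepend the zero-cost point (x=0, y=``anchor_y``).  With the anchor
        the measure spans [0, 1]; without it the x axis starts at the first
        cost level.
    """
    costs = np.asarray(list(costs), dtype=float)
    y = np.asarray(list(ips), dtype=float)
    if costs.shape != y.shape or costs.size == 0:
        raise ValueError("costs and ips must be equal-length and nonempty")
    if np.any(np.diff(costs) <= 0):
        raise ValueError("costs must be strictly increasing")
    if amount <= 0:
        raise ValueError("amount must be positive")
    if np.any(y < 0) or np.any(y > amount):
        raise ValueError("every IP must lie in [0, amount]")
    if cost_encoding == "ordinal":
        x = np.asarray(ordinal_ranks(costs), dtype=float) / costs.size
    elif cost_encoding == "raw_normalized":
        x = normalize_costs(costs)
    else:
        raise ValueError(f"unknown cost_encoding {cost_encoding!r}")
    y = y / amount
    if anchor:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[anchor_y], y])
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def auc_table(
    curves: Iterable[IndifferenceCurve],
    amount: float | None = None,
    anchor: bool = True,
    anchor_y: float = 1.0,
) -> pd.DataFrame:
    """Both AUC variants for every curve, one row per participant × time × task."""
    rows = []
    for c in curves:
        a = amount if amount is not None else c.amount_large
        rows.append(
            {
                "participant_id": c.participant_id,
                "timepoint": c.timepoint,
                "task": c.task.value,
                "auc": auc_trapezoid(
                    c.costs, c.ips, a, "raw_normalized", anchor, anchor_y
                ),
                "auc_ord": auc_trapezoid(c.costs, c.ips, a, "ordinal", anchor, anchor_y),
            }
        )
    out = pd.DataFrame(rows, columns=AUC_COLUMNS)
    return out.sort_values(["task", "participant_id", "timepoint"]).reset_index(
        drop=True
    )
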