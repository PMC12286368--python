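"""Stage decomposition of the bread element burden.

Each element's concentration in the finished bread is split into three
sources by a mass-balance reading of the production chain: the flour
baseline, the dough-stage additions (water, salt, yeast), and the baking /
oven-contact increment:

    flour share = f / b,   dough share = (d - f) / b,   oven share = (b - d) / b

with f, d, b the stage mean concentrations (mg/kg dry weight). Measurement
noise can produce negative increments; these are clipped at zero and the
three shares renormalised to 100%, which keeps shares non-negative,
scale-invariant and summing to 100 per element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import CensorPolicy, apply_censor_policy

__all__ = ["stage_contributions", "apportionment_table", "ApportionmentResult"]

logger = logging.getLogger(__name__)


def stage_contributions(f: float, d: float, b: float) -> tuple[float, float, float]:
    """(flour %, dough %, oven %) for one element's stage means.

    Raises on a non-positive bread mean (decomposition undefined).
    """
    if not b > 0:
        raise ValueError("bread mean must be positive for apportionment")
    if f < 0 or d < 0:
        raise ValueError("stage means must be non-negative")
    increments = np.array([f, d - f, b - d], dtype=float)
    increments = np.clip(increments, 0.0, None)
    total = increments.sum()
    if total == 0:  # f = d = 0 and b - d clipped cannot both vanish unless b<=d
        return (0.0, 0.0, 100.0)
    shares = increments / total * 100.0
    return (float(shares[0]), float(shares[1]), float(shares[2]))


@dataclass(frozen=True)
class ApportionmentResult:
    """Per-element stage shares and their grand mean across elements."""

    table: pd.DataFrame
    grand_mean: tuple[float, float, float]


def apportionment_table(records: pd.DataFrame,
                        policy: CensorPolicy = CensorPolicy.EXCLUDE,
                        ) -> ApportionmentResult:
    """Stage shares per element from region-pooled stage means.

    Elements lacking any usable value for one of the three stages (e.g. fully
    censored elements under the exclude policy) are dropped with a logged
    message and excluded from the grand mean.
    """
    usable = apply_censor_policy(records, policy)
    means = usable.pivot_table(index="element", columns="stage",
                               values="value", aggfunc="mean")
    rows = []
    for element, row in means.iterrows():
        if row.reindex(["flour", "dough", "bread"]).isna().any():
            logger.warning("element %s missing a stage mean; "
                           "excluded from apportionment", element)
            continue
        if not row["bread"] > 0:
            logger.warning("element %s has non-positive bread mean; row skipped",
                           element)
            continue
        fp, dp, op = stage_contributions(row["flour"], row["dough"], row["bread"])
        rows.append({"element": element, "flour_pct": fp,
                     "dough_pct": dp, "oven_pct": op})
    table = pd.DataFrame(rows, columns=["element", "flour_pct",
                                        "dough_pct", "oven_pct"])
    if table.empty:
        raise ValueError("no element with all three stage means")
    gm = (float(table["flour_pct"].mean()),
          float(table["dough_pct"].mean()),
          float(table["oven_pct"].mean()))
    return ApportionmentResult(table=table.reset_index(drop=True), grand_mean=gm)
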