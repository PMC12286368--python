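"""Screening of mean concentrations against permissible limits.

Regional stage means are compared with regulatory limit tables (element,
authority, limit in mg/kg). Exceedance uses a strict ``mean > limit``
convention; an element present in the data but absent from the limit table is
reported with an absent (NA) exceedance flag rather than silently dropped.
"""

from __future__ import annotations

import pandas as pd

from .exposure import CensorPolicy, apply_censor_policy

__all__ = ["exceedance_report"]


def exceedance_report(records: pd.DataFrame, limits: pd.DataFrame,
                      stage: str = "bread",
                      policy: CensorPolicy = CensorPolicy.EXCLUDE,
                      ) -> pd.DataFrame:
    """Per (region, element, authority) exceedance table.

    Columns: region, element, authority, mean_mg_kg, limit_mg_kg, ratio,
    exceeds. ``exceeds`` is boolean where a limit exists (strict inequality),
    NA otherwise; ``ratio`` is mean/limit. Flags are invariant to record
    ordering and to joint rescaling of values and limits.
    """
    if limits.empty:
        raise ValueError("limits table is empty")
    usable = apply_censor_policy(records, policy)
    usable = usable.loc[usable["stage"] == stage]
    if usable.empty:
        raise ValueError(f"no usable records for stage {stage!r}")

    means = (usable.groupby(["region", "element"], sort=True)["value"]
             .mean().rename("mean_mg_kg").reset_index())
    merged = means.merge(limits, on="element", how="left")
    merged["authority"] = merged["authority"].astype(object)
    merged["ratio"] = merged["mean_mg_kg"] / merged["limit_mg_kg"]
    merged["exceeds"] = pd.array(
        merged["mean_mg_kg"] > merged["limit_mg_kg"], dtype="boolean")
    merged.loc[merged["limit_mg_kg"].isna(), "exceeds"] = pd.NA
    cols = ["region", "element", "authority", "mean_mg_kg",
            "limit_mg_kg", "ratio", "exceeds"]
    return merged[cols].sort_values(["region", "element"]).reset_index(drop=True)
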