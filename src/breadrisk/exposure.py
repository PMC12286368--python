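"""Chronic daily intake (CDI) from bread consumption.

The ingestion dose model is the EPA chronic-intake equation

    CDI = C * IR * EF * ED / (BW * AT)      [mg/kg body weight/day]

with C the element concentration in the consumed product (mg/kg dry weight)
and cohort-specific ingestion rate IR, exposure frequency EF, duration ED,
body weight BW and averaging time AT. CDI is linear and homogeneous in C and
invariant under joint rescaling of ED and AT.

Left-censored measurements (below the limit of detection) are resolved by an
explicit :class:`CensorPolicy` before any averaging: the default policy drops
censored cells and therefore drops entirely-censored elements from dietary
risk, matching the usual practice of not reporting risk for non-detects.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import ExposureParams

__all__ = [
    "CensorPolicy",
    "chronic_daily_intake",
    "apply_censor_policy",
    "mean_cdi_by_element",
]

logger = logging.getLogger(__name__)


class CensorPolicy(str, Enum):
    """Substitution rule for below-detection-limit cells.

    exclude: drop censored cells; elements censored everywhere disappear
    from downstream risk (the default).
    zero / half_lod / full_lod: substitute 0, LOD/2 or LOD respectively.
    """

    EXCLUDE = "exclude"
    ZERO = "zero"
    HALF_LOD = "half_lod"
    FULL_LOD = "full_lod"


def chronic_daily_intake(c, params: ExposureParams):
    """CDI (mg/kg/day) for concentration ``c`` (mg/kg) under ``params``.

    Accepts scalars or arrays; raises on negative concentrations.
    """
    c_arr = np.asarray(c, dtype=float)
    if (c_arr < 0).any():
        raise ValueError("concentration must be non-negative")
    out = c_arr * params.IR * params.EF * params.ED / (params.BW * params.AT)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def apply_censor_policy(records: pd.DataFrame,
                        policy: CensorPolicy = CensorPolicy.EXCLUDE,
                        ) -> pd.DataFrame:
    """Resolve censored cells, returning rows with a usable ``value``.

    Under ``exclude`` the censored rows are dropped (an element censored in
    every record thus vanishes). The substitution modes fill censored values
    with 0, LOD/2 or LOD and keep all rows.
    """
    policy = CensorPolicy(policy)
    df = records.copy()
    if policy is CensorPolicy.EXCLUDE:
        return df.loc[~df["censored"]].copy()
    if policy is CensorPolicy.ZERO:
        fill = 0.0
        df.loc[df["censored"], "value"] = fill
    elif policy is CensorPolicy.HALF_LOD:
        df.loc[df["censored"], "value"] = df.loc[df["censored"], "lod"] / 2.0
    else:  # FULL_LOD
        df.loc[df["censored"], "value"] = df.loc[df["censored"], "lod"]
    return df


def mean_cdi_by_element(records: pd.DataFrame,
                        cohorts: Mapping[str, ExposureParams],
                        policy: CensorPolicy = CensorPolicy.EXCLUDE,
                        stage: str = "bread") -> pd.DataFrame:
    """Mean CDI per (region, cohort, element).

    Only records of the consumed ``stage`` (bread by default) enter dietary
    exposure; flour and dough serve source apportionment and group testing.
    The regional concentration is the arithmetic mean of bakery-level values
    after censoring resolution; CDI of the mean equals the mean CDI by
    linearity. Regions without usable records for an element are omitted with
    a logged warning.

    Returns a tidy frame: region, cohort, element, mean_concentration_mg_kg,
    cdi_mg_kg_day.
    """
    usable = apply_censor_policy(records, policy)
    usable = usable.loc[usable["stage"] == stage]
    if usable.empty:
        logger.warning("no usable %s-stage records after censoring policy", stage)
        return pd.DataFrame(columns=["region", "cohort", "element",
                                     "mean_concentration_mg_kg",
                                     "cdi_mg_kg_day"])

    all_regions = records.loc[records["stage"] == stage, "region"].unique()
    means = (usable.groupby(["region", "element"], sort=True)["value"]
             .mean().rename("mean_concentration_mg_kg").reset_index())
    missing = set(all_regions) - set(means["region"])
    for region in sorted(missing):  # pragma: no cover - defensive logging
        logger.warning("region %r has no usable %s records", region, stage)

    rows = []
    for cohort, params in cohorts.items():
        block = means.copy()
        block.insert(1, "cohort", cohort)
        block["cdi_mg_kg_day"] = chronic_daily_intake(
            block["mean_concentration_mg_kg"].to_numpy(), params)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
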