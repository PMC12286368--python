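"""Deterministic non-carcinogenic and carcinogenic risk.

Point-estimate risk follows the EPA screening convention:

    HQ  = CDI / RfD          (target hazard quotient, per element)
    HI  = sum of HQs         (hazard index, per region and cohort)
    CR  = CDI * OSF          (incremental lifetime cancer risk)
    TCR = sum of CRs         (over carcinogens with a slope factor)

A hazard quotient or index above 1 flags non-carcinogenic concern; cancer
risk is classified against a de-minimis level (1e-6) and an unacceptable
level (1e-4), the conventionally acceptable range lying between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ExposureParams,
    RiskTable,
    ThresholdPolicy,
    ToxProfile,
)
from .exposure import CensorPolicy, mean_cdi_by_element

__all__ = [
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "total_cancer_risk",
    "compute_risk_table",
    "classify",
    "RiskSummary",
    "summarize",
]

logger = logging.getLogger(__name__)


def hazard_quotient(cdi: float, rfd: float) -> float:
    """HQ = CDI / RfD (both mg/kg/day)."""
    if not rfd > 0:
        raise ValueError("rfd must be positive")
    if cdi < 0:
        raise ValueError("cdi must be non-negative")
    return cdi / rfd


def hazard_index(hqs: Iterable[float]) -> float:
    """HI, the exact sum of hazard quotients; undefined for no components."""
    values = [float(h) for h in hqs]
    if not values:
        raise ValueError("hazard index of an empty collection is undefined")
    if any(v < 0 for v in values):
        raise ValueError("hazard quotients must be non-negative")
    return float(sum(values))


def cancer_risk(cdi: float, osf: float) -> float:
    """CR = CDI * OSF (linear slope-factor model)."""
    if not osf > 0:
        raise ValueError("osf must be positive")
    if cdi < 0:
        raise ValueError("cdi must be non-negative")
    return cdi * osf


def total_cancer_risk(crs: Iterable[float]) -> float:
    """TCR, the exact sum of per-carcinogen risks."""
    values = [float(c) for c in crs]
    if not values:
        raise ValueError("total cancer risk of an empty collection is undefined")
    if any(v < 0 for v in values):
        raise ValueError("cancer risks must be non-negative")
    return float(sum(values))


def compute_risk_table(records: pd.DataFrame,
                       cohorts: Mapping[str, ExposureParams],
                       tox: Mapping[str, ToxProfile],
                       policy: CensorPolicy = CensorPolicy.EXCLUDE,
                       carcinogens: Sequence[str] | None = None,
                       stage: str = "bread") -> RiskTable:
    """Full deterministic risk table from a concentration table.

    Elements without an RfD are skipped from HQ/HI with a warning (never
    treated as zero-risk silently); carcinogens default to the elements that
    both carry a slope factor and survive the censoring policy.
    """
    cdi_tidy = mean_cdi_by_element(records, cohorts, policy, stage=stage)
    if cdi_tidy.empty:
        raise ValueError("no usable records: cannot build a risk table")
    cdi = cdi_tidy.pivot_table(index=["region", "cohort"], columns="element",
                               values="cdi_mg_kg_day", sort=True)
    cdi.columns.name = None

    present = [el for el in cdi.columns]
    no_rfd = [el for el in present if tox.get(el) is None or tox[el].rfd is None]
    for el in no_rfd:
        logger.warning("element %s has no oral reference dose; "
                       "skipped from HQ/HI", el)
    hq_elements = [el for el in present if el not in no_rfd]
    if not hq_elements:
        raise ValueError("no element with an RfD: hazard index undefined")
    hq = cdi[hq_elements] / pd.Series({el: tox[el].rfd for el in hq_elements})

    if carcinogens is None:
        carcinogens = [el for el in present
                       if tox.get(el) is not None and tox[el].osf is not None]
    missing = [el for el in carcinogens if el not in present]
    if missing:
        raise ValueError(f"carcinogens absent from usable data: {missing}")
    cr = cdi[list(carcinogens)] * pd.Series(
        {el: tox[el].osf for el in carcinogens})

    return RiskTable.from_components(cdi=cdi, hq=hq, cr=cr)


def classify(table: RiskTable,
             policy: ThresholdPolicy = ThresholdPolicy()) -> pd.DataFrame:
    """Threshold flags per (region, cohort) row.

    hq_flag_<el>: HQ strictly above the hazard limit; hi_flag likewise for
    the index. cr_class labels TCR as de_minimis (< de-minimis level),
    acceptable_range, or unacceptable (> unacceptable level); classification
    is monotone in every component.
    """
    flags = table.hq.gt(policy.hq_limit).add_prefix("hq_flag_")
    flags["hi_flag"] = table.hi > policy.hq_limit
    tcr = table.tcr
    cr_class = pd.Series(
        np.where(tcr > policy.cr_unacceptable, "unacceptable",
                 np.where(tcr < policy.cr_de_minimis, "de_minimis",
                          "acceptable_range")),
        index=tcr.index, name="cr_class")
    flags["cr_class"] = cr_class
    return flags


@dataclass(frozen=True)
class RiskSummary:
    """Cross-region aggregates per cohort.

    mean/min/max of HI and TCR are arithmetic statistics over regions;
    ``hi_ratio`` holds the per-region child:adult HI ratio when both cohorts
    are present.
    """

    hi_mean: Mapping[str, float]
    hi_min: Mapping[str, float]
    hi_max: Mapping[str, float]
    tcr_mean: Mapping[str, float]
    tcr_min: Mapping[str, float]
    tcr_max: Mapping[str, float]
    hi_ratio: Mapping[str, float]

    @property
    def hi_ratio_max(self) -> float:
        if not self.hi_ratio:
            raise ValueError("no region has both cohorts")
        return max(self.hi_ratio.values())


def summarize(table: RiskTable) -> RiskSummary:
    """Cross-region means, ranges and child:adult hazard ratios."""
    hi = table.hi
    tcr = table.tcr
    cohorts = hi.index.get_level_values("cohort").unique()

    def _stats(series):
        g = series.groupby(level="cohort")
        return (g.mean().to_dict(), g.min().to_dict(), g.max().to_dict())

    hi_mean, hi_min, hi_max = _stats(hi)
    tcr_mean, tcr_min, tcr_max = _stats(tcr)

    ratios: dict[str, float] = {}
    if {"adult", "child"}.issubset(set(cohorts)):
        wide = hi.unstack("cohort")
        both = wide.dropna(subset=["adult", "child"])
        ratios = (both["child"] / both["adult"]).to_dict()
    return RiskSummary(hi_mean=hi_mean, hi_min=hi_min, hi_max=hi_max,
                       tcr_mean=tcr_mean, tcr_min=tcr_min, tcr_max=tcr_max,
                       hi_ratio=ratios)
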