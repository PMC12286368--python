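"""Model/Results objects tying the pipeline stages together.

:class:`BreadRiskModel` is constructed from a long-format concentration
table plus exposure, toxicity and censoring configuration. ``fit()`` runs the
deterministic risk equations and returns a :class:`RiskResults` carrying the
per-region risk table, threshold classification, cross-region summary and the
auxiliary screens (compliance, stage apportionment, group comparisons).
``simulate()`` runs the seeded Monte Carlo propagation and returns a
:class:`MonteCarloResults` with percentile risk measures, cumulative curves
and contribution-to-variance sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apportionment import ApportionmentResult, apportionment_table
from .compliance import exceedance_report
from .datamodel import (
    ExposureParams,
    RiskTable,
    StudyDefaults,
    ThresholdPolicy,
    ToxProfile,
    builtin_defaults,
    read_concentrations,
    validate_concentrations,
    write_risk_report,
)
from .exposure import CensorPolicy
from .group_stats import regional_difference_table
from .montecarlo import (
    DistSpec,
    McDraws,
    cumulative_curve,
    default_concentration_dists,
    percentile,
    simulate_risk,
)
from .risk import RiskSummary, classify, compute_risk_table, summarize
from .sensitivity import sensitivity_report

__all__ = ["BreadRiskModel", "RiskResults", "MonteCarloResults"]


class BreadRiskModel:
    """Dietary heavy-metal risk model for a bakery concentration survey.

    Parameters
    ----------
    data:
        Long-format concentration table (region, bakery_id, stage,
        bread_type, element, value, censored, lod). Validated on entry.
    cohorts:
        Mapping cohort name -> :class:`ExposureParams`. Defaults to the
        built-in adult/child parameters.
    tox:
        Mapping element -> :class:`ToxProfile`. Defaults to the built-in
        oral reference doses and slope factors.
    censor_policy:
        How below-detection values enter the analysis (default: exclude).
    thresholds:
        Risk classification thresholds (HQ limit 1, CR 1e-6 / 1e-4).
    stage:
        The consumed stage entering dietary exposure (default "bread").
    """

    def __init__(self, data: pd.DataFrame,
                 cohorts: Mapping[str, ExposureParams] | None = None,
                 tox: Mapping[str, ToxProfile] | None = None,
                 censor_policy: CensorPolicy = CensorPolicy.EXCLUDE,
                 thresholds: ThresholdPolicy | None = None,
                 stage: str = "bread"):
        defaults = builtin_defaults()
        self.data = validate_concentrations(data)
        self.cohorts = dict(cohorts) if cohorts is not None else defaults.cohorts
        self.tox = dict(tox) if tox is not None else dict(defaults.tox)
        self.censor_policy = CensorPolicy(censor_policy)
        self.thresholds = thresholds if thresholds is not None else defaults.thresholds
        self.stage = stage

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "BreadRiskModel":
        return cls(read_concentrations(path), **kwargs)

    def fit(self, carcinogens: Sequence[str] | None = None) -> "RiskResults":
        """Deterministic risk tables from regional mean concentrations."""
        table = compute_risk_table(self.data, self.cohorts, self.tox,
                                   policy=self.censor_policy,
                                   carcinogens=carcinogens, stage=self.stage)
        return RiskResults(model=self, risk_table=table)

    def simulate(self, n: int = 10_000, seed: int = 0,
                 conc_dists: Mapping[str, DistSpec] | None = None,
                 param_dists: Mapping[str, DistSpec] | None = None,
                 ) -> "MonteCarloResults":
        """Seeded Monte Carlo propagation of input uncertainty.

        Concentration distributions default to per-element lognormal fits of
        the usable consumed-stage values; exposure parameters default to
        point masses.
        """
        if conc_dists is None:
            conc_dists = default_concentration_dists(
                self.data, self.censor_policy, stage=self.stage)
        draws = simulate_risk(conc_dists, self.tox, self.cohorts,
                              n=n, seed=seed, param_dists=param_dists)
        return MonteCarloResults(model=self, draws=draws,
                                 conc_dists=dict(conc_dists))


@dataclass
class RiskResults:
    """Deterministic risk estimates and the screens derived from them."""

    model: BreadRiskModel
    risk_table: RiskTable

    def classify(self, thresholds: ThresholdPolicy | None = None) -> pd.DataFrame:
        return classify(self.risk_table,
                        thresholds or self.model.thresholds)

    def risk_summary(self) -> RiskSummary:
        return summarize(self.risk_table)

    def compliance(self, limits: pd.DataFrame) -> pd.DataFrame:
        return exceedance_report(self.model.data, limits,
                                 stage=self.model.stage,
                                 policy=self.model.censor_policy)

    def apportionment(self) -> ApportionmentResult:
        return apportionment_table(self.model.data,
                                   policy=self.model.censor_policy)

    def group_tests(self, grouping: str = "region",
                    alpha: float = 0.05, holm: bool = False) -> pd.DataFrame:
        return regional_difference_table(self.model.data, grouping=grouping,
                                         stage=self.model.stage, alpha=alpha,
                                         policy=self.model.censor_policy,
                                         holm=holm)

    def to_csv(self, path: str | Path,
               metadata: Mapping[str, object] | None = None) -> None:
        write_risk_report(self.risk_table, path, metadata=metadata)

    def summary(self) -> str:
        """Human-readable report of the fitted risk table."""
        table = self.risk_table
        s = self.risk_summary()
        flags = self.classify()
        lines = ["Dietary heavy-metal risk (deterministic)",
                 "=" * 48]
        lines.append(f"rows: {len(table.hq)} (region x cohort); "
                     f"elements in HI: {', '.join(table.hq.columns)}")
        lines.append(f"carcinogens in TCR: {', '.join(table.cr.columns)}")
        lines.append("")
        lines.append("Hazard index by region and cohort:")
        hi = table.hi.unstack("cohort")
        lines.append(hi.round(4).to_string())
        lines.append("")
        lines.append("Total cancer risk by region and cohort:")
        tcr = table.tcr.unstack("cohort").map(lambda v: f"{v:.3e}")
        lines.append(tcr.to_string())
        lines.append("")
        for cohort in sorted(s.hi_mean):
            lines.append(
                f"{cohort}: mean HI {s.hi_mean[cohort]:.4g} "
                f"(range {s.hi_min[cohort]:.4g}-{s.hi_max[cohort]:.4g}); "
                f"mean TCR {s.tcr_mean[cohort]:.3e} "
                f"(range {s.tcr_min[cohort]:.3e}-{s.tcr_max[cohort]:.3e})")
        if s.hi_ratio:
            lines.append(f"max regional child:adult HI ratio "
                         f"{s.hi_ratio_max:.4g}")
        n_hi_flag = int(flags["hi_flag"].sum())
        lines.append(f"rows with HI above {self.model.thresholds.hq_limit}: "
                     f"{n_hi_flag}/{len(flags)}; "
                     f"CR classes: {flags['cr_class'].value_counts().to_dict()}")
        return "\n".join(lines)


@dataclass
class MonteCarloResults:
    """Monte Carlo risk draws plus the derived uncertainty measures."""

    model: BreadRiskModel
    draws: McDraws
    conc_dists: dict[str, DistSpec] = field(default_factory=dict)

    def percentile(self, q: float, endpoint: str = "HI",
                   cohort: str = "adult") -> float:
        return percentile(self.draws.outputs[f"{cohort}:{endpoint}"], q)

    def cdf(self, endpoint: str = "HI", cohort: str = "adult"):
        return cumulative_curve(self.draws.outputs[f"{cohort}:{endpoint}"])

    def sensitivity(self) -> pd.DataFrame:
        return sensitivity_report(self.draws)

    def summary_frame(self, percentiles: Sequence[float] = (0.05, 0.5, 0.95),
                      ) -> pd.DataFrame:
        """Mean and selected percentiles per cohort and endpoint."""
        rows = []
        for key in sorted(self.draws.outputs):
            cohort, _, endpoint = key.partition(":")
            x = self.draws.outputs[key]
            row = {"cohort": cohort, "endpoint": endpoint,
                   "mean": float(np.mean(x))}
            for q in percentiles:
                row[f"p{int(round(q * 100)):02d}"] = percentile(x, q)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [f"Monte Carlo risk ({self.draws.n} iterations, "
                 f"seed {self.draws.seed})", "=" * 48,
                 frame.to_string(index=False,
                                 float_format=lambda v: f"{v:.4g}")]
        top = (self.sensitivity().groupby(["cohort", "endpoint"])
               .head(1)[["cohort", "endpoint", "variable",
                         "contribution_pct"]])
        lines.append("")
        lines.append("top variance contributor per endpoint:")
        lines.append(top.to_string(index=False,
                                   float_format=lambda v: f"{v:.1f}"))
        return "\n".join(lines)
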