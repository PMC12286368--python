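"""Probabilistic risk: input distributions and seeded Monte Carlo propagation.

Instead of a single point estimate, each uncertain input (element
concentrations; optionally the exposure parameters) is described by a
:class:`DistSpec`, sampled independently, and pushed through the intake and
risk equations for every iteration. The hazard index and total cancer risk
draws support percentile risk measures (the 95th percentile by convention)
and cumulative risk curves.

Defaults are deliberately minimal: concentrations are lognormal (positive,
right-skewed, the shape bakery surveys show), exposure parameters are point
masses; every variable's family is overridable. All sampling flows from one
integer seed, and identical (distributions, n, seed) reproduce bit-identical
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExposureParams, ToxProfile
from .exposure import CensorPolicy, apply_censor_policy

__all__ = [
    "DistSpec",
    "McDraws",
    "fit_distribution",
    "default_concentration_dists",
    "simulate_risk",
    "percentile",
    "cumulative_curve",
]

_FAMILIES = ("point", "normal", "lognormal", "triangular", "uniform")

_EXPOSURE_FIELDS = ("IR", "EF", "ED", "BW", "AT")


@dataclass(frozen=True)
class DistSpec:
    """One input variable's probability distribution.

    families and parameters:
      point:      (value,)
      normal:     (mean, sd), sd >= 0
      lognormal:  (mu, sigma) of the underlying normal on the log scale
      triangular: (lower, mode, upper), lower <= mode <= upper
      uniform:    (lower, upper), lower <= upper
    """

    variable: str
    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"allowed: {', '.join(_FAMILIES)}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        n_expected = {"point": 1, "normal": 2, "lognormal": 2,
                      "triangular": 3, "uniform": 2}[self.family]
        if len(p) != n_expected:
            raise ValueError(f"{self.variable}: {self.family} needs "
                             f"{n_expected} parameters, got {len(p)}")
        if self.family in ("normal", "lognormal") and p[1] < 0:
            raise ValueError(f"{self.variable}: sd/sigma must be >= 0")
        if self.family == "triangular" and not (p[0] <= p[1] <= p[2]):
            raise ValueError(f"{self.variable}: need lower <= mode <= upper")
        if self.family == "uniform" and not (p[0] <= p[1]):
            raise ValueError(f"{self.variable}: need lower <= upper")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(n, p[0])
        if self.family == "normal":
            return rng.normal(p[0], p[1], size=n)
        if self.family == "lognormal":
            return rng.lognormal(p[0], p[1], size=n)
        if self.family == "triangular":
            if p[0] == p[2]:
                return np.full(n, p[0])
            return rng.triangular(p[0], p[1], p[2], size=n)
        return rng.uniform(p[0], p[1], size=n)

    @property
    def is_stochastic(self) -> bool:
        if self.family == "point":
            return False
        if self.family in ("normal", "lognormal"):
            return self.params[1] > 0
        if self.family == "triangular":
            return self.params[0] < self.params[2]
        return self.params[0] < self.params[1]


def fit_distribution(samples, family: str, variable: str = "x",
                     censored=None, lods=None,
                     policy: CensorPolicy = CensorPolicy.EXCLUDE) -> DistSpec:
    """Maximum-likelihood fit of one family to a sample.

    Censored observations (``censored`` mask + ``lods``) are resolved by the
    given policy before fitting. Requires at least 5 usable observations.
    Lognormal fitting demands strictly positive values.
    """
    x = np.asarray(samples, dtype=float)
    if censored is not None:
        censored = np.asarray(censored, dtype=bool)
        lods = np.asarray(lods, dtype=float)
        policy = CensorPolicy(policy)
        if policy is CensorPolicy.EXCLUDE:
            x = x[~censored]
        else:
            sub = {CensorPolicy.ZERO: np.zeros_like(lods),
                   CensorPolicy.HALF_LOD: lods / 2.0,
                   CensorPolicy.FULL_LOD: lods}[policy]
            x = np.where(censored, sub, x)
    if x.size < 5:
        raise ValueError("need at least 5 usable samples to fit")

    if family == "point":
        return DistSpec(variable, "point", (float(x.mean()),))
    if family == "normal":
        return DistSpec(variable, "normal", (float(x.mean()),
                                             float(x.std(ddof=0))))
    if family == "lognormal":
        if (x <= 0).any():
            raise ValueError("lognormal fit requires strictly positive samples")
        logs = np.log(x)
        return DistSpec(variable, "lognormal", (float(logs.mean()),
                                                float(logs.std(ddof=0))))
    if family == "uniform":
        return DistSpec(variable, "uniform", (float(x.min()), float(x.max())))
    if family == "triangular":
        from scipy import stats
        c, loc, scale = stats.triang.fit(x)
        return DistSpec(variable, "triangular",
                        (float(loc), float(loc + c * scale),
                         float(loc + scale)))
    raise ValueError(f"unknown family {family!r}")


def default_concentration_dists(records: pd.DataFrame,
                                policy: CensorPolicy = CensorPolicy.EXCLUDE,
                                stage: str = "bread",
                                ) -> dict[str, DistSpec]:
    """Lognormal concentration distributions fitted per element.

    Uses pooled usable stage values; elements with fewer than 5 usable values
    (e.g. fully censored ones under the exclude policy) are omitted.
    """
    usable = apply_censor_policy(records, policy)
    usable = usable.loc[usable["stage"] == stage]
    dists: dict[str, DistSpec] = {}
    for element, block in usable.groupby("element", sort=True):
        x = block["value"].to_numpy()
        if x.size < 5 or (x <= 0).any():
            continue
        dists[element] = fit_distribution(x, "lognormal", variable=f"C_{element}")
    return dists


@dataclass
class McDraws:
    """Seeded Monte Carlo input and output draws.

    ``inputs`` maps variable names (``C_<element>``, ``<cohort>.IR`` ...) to
    length-n vectors; ``outputs`` maps ``"<cohort>:HI"`` / ``"<cohort>:TCR"``
    to length-n risk draws.
    """

    n: int
    seed: int
    inputs: dict[str, np.ndarray]
    outputs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, v in {**self.inputs, **self.outputs}.items():
            if v.shape != (self.n,):
                raise ValueError(f"{name}: expected length {self.n} vector")

    def hi(self, cohort: str) -> np.ndarray:
        return self.outputs[f"{cohort}:HI"]

    def tcr(self, cohort: str) -> np.ndarray:
        return self.outputs[f"{cohort}:TCR"]

    @property
    def cohorts(self) -> list[str]:
        return sorted({k.split(":")[0] for k in self.outputs})


def simulate_risk(conc_dists: Mapping[str, DistSpec],
                  tox: Mapping[str, ToxProfile],
                  cohorts: Mapping[str, ExposureParams],
                  n: int = 10_000,
                  seed: int = 0,
                  param_dists: Mapping[str, DistSpec] | None = None,
                  ) -> McDraws:
    """Propagate input distributions through the intake/risk equations.

    ``conc_dists`` maps element symbols to concentration distributions
    (mg/kg); ``param_dists`` optionally overrides exposure parameters with
    keys ``"<cohort>.<field>"`` (e.g. ``"child.BW"``). All inputs are drawn
    independently; concentration draws are shared across cohorts. Output is
    deterministic given (distributions, n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not conc_dists:
        raise ValueError("no concentration distribution supplied")
    param_dists = dict(param_dists or {})
    for key in param_dists:
        cohort, _, fieldname = key.partition(".")
        if cohort not in cohorts or fieldname not in _EXPOSURE_FIELDS:
            raise ValueError(f"unknown parameter-distribution key {key!r}")

    hi_elements = [el for el in sorted(conc_dists)
                   if tox.get(el) is not None and tox[el].rfd is not None]
    cr_elements = [el for el in sorted(conc_dists)
                   if tox.get(el) is not None and tox[el].osf is not None]
    if not hi_elements and not cr_elements:
        raise ValueError("no element with toxicity values among distributions")

    rng = np.random.default_rng(seed)
    inputs: dict[str, np.ndarray] = {}
    # fixed draw order for bit-reproducibility: concentrations, then params
    for el in sorted(conc_dists):
        inputs[f"C_{el}"] = conc_dists[el].sample(rng, n)
    for cohort in sorted(cohorts):
        params = cohorts[cohort]
        for fieldname in _EXPOSURE_FIELDS:
            key = f"{cohort}.{fieldname}"
            spec = param_dists.get(
                key, DistSpec(key, "point", (getattr(params, fieldname),)))
            inputs[key] = spec.sample(rng, n)

    outputs: dict[str, np.ndarray] = {}
    for cohort in sorted(cohorts):
        ir, ef, ed, bw, at = (inputs[f"{cohort}.{f}"] for f in _EXPOSURE_FIELDS)

        def _cdi(c):
            # same operation order as exposure.chronic_daily_intake, so the
            # all-point-mass simulation reproduces the deterministic risk
            # bit-exactly
            return c * ir * ef * ed / (bw * at)

        if hi_elements:
            hi = np.zeros(n)
            for el in hi_elements:
                hi += _cdi(inputs[f"C_{el}"]) / tox[el].rfd
            outputs[f"{cohort}:HI"] = hi
        if cr_elements:
            tcr = np.zeros(n)
            for el in cr_elements:
                tcr += _cdi(inputs[f"C_{el}"]) * tox[el].osf
            outputs[f"{cohort}:TCR"] = tcr
    return McDraws(n=n, seed=seed, inputs=inputs, outputs=outputs)


def percentile(draws, q: float) -> float:
    """Empirical quantile with the linear interpolation convention."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("empty draws")
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    return float(np.quantile(x, q, method="linear"))


def cumulative_curve(draws) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative risk curve as (values, probabilities).

    The curve starts at (min, 0) and steps to (max, 1); probabilities are
    monotone non-decreasing.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    if x.size == 0:
        raise ValueError("empty draws")
    n = x.size
    values = np.concatenate(([x[0]], x))
    probs = np.concatenate(([0.0], np.arange(1, n + 1) / n))
    return values, probs
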