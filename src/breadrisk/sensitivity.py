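"""Contribution-to-variance sensitivity analysis of Monte Carlo risk.

Each stochastic input's influence on an output (hazard index or total cancer
risk) is scored by its Spearman rank correlation with the output draws; the
contribution is the squared rank correlation normalised across inputs to sum
to 100%. This is the tornado-style "contribution to variance" convention of
spreadsheet risk simulators: rank-based (hence invariant under monotone
rescaling of any input), with negative correlations contributing by their
square and the direction reported in a separate sign column. Zero-variance
inputs contribute exactly 0.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .montecarlo import McDraws

__all__ = ["contribution_to_variance", "sensitivity_report"]


def contribution_to_variance(inputs: Mapping[str, np.ndarray],
                             output: np.ndarray) -> pd.DataFrame:
    """Normalised squared Spearman correlations, as percentages.

    Returns a frame (variable, rho, contribution_pct, sign) sorted by
    descending contribution. Raises if every input is constant or vectors
    disagree in length (n >= 10 required).
    """
    y = np.asarray(output, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    rhos: dict[str, float] = {}
    any_varying = False
    for name, x in inputs.items():
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"{name}: length mismatch with output")
        if np.ptp(x) == 0:
            rhos[name] = 0.0
            continue
        any_varying = True
        rho = stats.spearmanr(x, y).statistic
        rhos[name] = 0.0 if np.isnan(rho) else float(rho)
    if not any_varying:
        raise ValueError("all inputs are constant; sensitivity undefined")

    sq = {k: v * v for k, v in rhos.items()}
    total = sum(sq.values())
    rows = []
    for name in inputs:
        contribution = 100.0 * sq[name] / total if total > 0 else 0.0
        rows.append({"variable": name, "rho": rhos[name],
                     "contribution_pct": contribution,
                     "sign": int(np.sign(rhos[name]))})
    frame = pd.DataFrame(rows).sort_values("contribution_pct",
                                           ascending=False, kind="stable")
    return frame.reset_index(drop=True)


def sensitivity_report(mc: McDraws) -> pd.DataFrame:
    """Ranked contribution table per cohort and endpoint (HI, TCR).

    Columns: cohort, endpoint, variable, rho, contribution_pct, sign, sorted
    by descending contribution within each (cohort, endpoint) block. Only the
    inputs relevant to a cohort (shared concentrations plus that cohort's
    exposure parameters) are scored against its outputs.
    """
    if not mc.inputs:
        raise ValueError("Monte Carlo draws carry no stored inputs")
    blocks = []
    for key in sorted(mc.outputs):
        cohort, _, endpoint = key.partition(":")
        relevant = {name: v for name, v in mc.inputs.items()
                    if name.startswith("C_") or name.startswith(f"{cohort}.")}
        table = contribution_to_variance(relevant, mc.outputs[key])
        table.insert(0, "endpoint", endpoint)
        table.insert(0, "cohort", cohort)
        blocks.append(table)
    return pd.concat(blocks, ignore_index=True)
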