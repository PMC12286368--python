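"""Published regional risk tables from the Mashhad bakery survey.

The survey that motivates this package reports, for five urban regions and
two cohorts (adult, child), per-element hazard quotients for bread
consumption together with the regional hazard index, and per-carcinogen
cancer risks (As, Cd) with the regional total. The raw concentration data
behind them are not public; these printed aggregates are shipped so that the
additive risk identities (HI as the sum of HQs, TCR as the sum of CRs) and
cross-region summaries can be recomputed and checked against the published
numbers.

Known printed inconsistency: the West-adult total cancer risk is reported as
4.23e-3 although its As + Cd components sum to 4.77e-3. The loaders return
the components and the printed totals separately so callers can choose which
identity to rely on.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_regional_hazard_quotients",
    "load_published_hazard_index",
    "load_regional_cancer_risks",
]

_HQ_ELEMENTS = ("Al", "As", "Cd", "Co", "Cr", "Cu", "Fe", "Ni", "Zn", "V")

# per-element hazard quotients, keyed (region, cohort)
_HQ = {
    ("South", "adult"): (0.029, 5.21, 0.170, 1.297, 0.0006, 0.283, 0.428,
                         0.029, 0.192, 0.006),
    ("South", "child"): (0.036, 6.5135, 0.213, 0.833, 0.0008, 0.354, 0.535,
                         0.036, 0.239, 0.007),
    ("East", "adult"): (0.037, 5.066, 0.150, 0.671, 0.001, 0.300, 0.360,
                        0.043, 0.201, 0.025),
    ("East", "child"): (0.045, 6.33, 0.188, 0.839, 0.001, 0.375, 0.450,
                        0.053, 0.252, 0.032),
    ("North", "adult"): (0.029, 3.955, 0.121, 0.217, 0.001, 0.331, 0.367,
                         0.032, 0.171, 0.004),
    ("North", "child"): (0.036, 4.943, 0.152, 0.271, 0.001, 0.414, 0.458,
                         0.040, 0.213, 0.005),
    ("West", "adult"): (0.034, 4.633, 0.157, 0.276, 0.001, 0.370, 0.383,
                        0.019, 0.184, 0.087),
    ("West", "child"): (0.041, 5.792, 0.197, 0.345, 0.002, 0.463, 0.479,
                        0.024, 0.230, 0.108),
    ("Center", "adult"): (0.033, 5.361, 0.183, 0.205, 0.002, 0.380, 0.505,
                          0.059, 0.192, 0.047),
    ("Center", "child"): (0.041, 6.702, 0.229, 0.256, 0.002, 0.476, 0.613,
                          0.074, 0.240, 0.058),
}

# published regional hazard index (the printed column totals)
_HI = {
    ("South", "adult"): 7.6446, ("South", "child"): 8.7673,
    ("East", "adult"): 6.854, ("East", "child"): 8.565,
    ("North", "adult"): 5.228, ("North", "child"): 6.533,
    ("West", "adult"): 6.144, ("West", "child"): 7.681,
    ("Center", "adult"): 6.967, ("Center", "child"): 8.691,
}

# per-carcinogen cancer risks and the printed regional totals
_CR = {
    ("South", "adult"): (4.69e-3, 6.47e-5, 4.76e-3),
    ("South", "child"): (5.86e-3, 7.46e-5, 5.94e-3),
    ("East", "adult"): (4.56e-3, 6.47e-5, 4.62e-3),
    ("East", "child"): (5.70e-3, 6.85e-5, 5.77e-3),
    ("North", "adult"): (3.56e-3, 4.61e-5, 3.61e-3),
    ("North", "child"): (4.45e-3, 5.31e-5, 4.50e-3),
    ("West", "adult"): (4.71e-3, 5.98e-5, 4.23e-3),
    ("West", "child"): (5.21e-3, 6.88e-5, 5.28e-3),
    ("Center", "adult"): (4.83e-3, 6.95e-5, 4.90e-3),
    ("Center", "child"): (6.03e-3, 8.01e-5, 6.11e-3),
}


def _index(keys) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(keys, names=["region", "cohort"])


def load_regional_hazard_quotients() -> pd.DataFrame:
    """Published per-element HQs, indexed by (region, cohort)."""
    return pd.DataFrame.from_dict(
        {k: dict(zip(_HQ_ELEMENTS, v)) for k, v in _HQ.items()},
        orient="index").set_axis(_index(_HQ.keys()), axis=0)


def load_published_hazard_index() -> pd.Series:
    """Published regional HI values, indexed by (region, cohort)."""
    return pd.Series(_HI.values(), index=_index(_HI.keys()), name="hi")


def load_regional_cancer_risks() -> pd.DataFrame:
    """Published cancer risks: columns As, Cd and the printed total tcr."""
    frame = pd.DataFrame.from_dict(
        {k: dict(zip(("As", "Cd", "tcr_printed"), v)) for k, v in _CR.items()},
        orient="index").set_axis(_index(_CR.keys()), axis=0)
    return frame
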