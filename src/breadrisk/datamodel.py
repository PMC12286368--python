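"""Domain types, tabular I/O and built-in defaults.

The package works on long-format concentration tables: one row per
region x bakery x processing stage x element, in mg/kg dry weight, with an
explicit left-censoring flag (value below the instrument's limit of
detection). Exposure parameters and toxicological reference values follow
the EPA ingestion-pathway convention: ingestion rate IR (kg/day), exposure
frequency EF (days/year), exposure duration ED (years), body weight BW (kg)
and averaging time AT (days) per cohort; an oral reference dose RfD
(mg/kg/day) and, for carcinogens, an oral slope factor OSF ((mg/kg/day)^-1)
per element.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENTS",
    "STAGES",
    "BREAD_TYPES",
    "REGIONS",
    "ExposureParams",
    "ToxProfile",
    "ThresholdPolicy",
    "LimitEntry",
    "RiskTable",
    "StudyDefaults",
    "builtin_defaults",
    "read_concentrations",
    "validate_concentrations",
    "read_limits",
    "load_example_limits",
    "write_risk_report",
    "read_risk_report",
]

#: Closed vocabulary of analysed elements (ICP-OES panel).
ELEMENTS: tuple[str, ...] = (
    "Fe", "Zn", "Cu", "Co", "Cr", "V", "Al", "Ni", "As", "Hg", "Pb", "Cd",
)

STAGES: tuple[str, ...] = ("flour", "dough", "bread")

BREAD_TYPES: tuple[str, ...] = ("sangak", "barbari", "taftoon", "lavash", "unknown")

#: The five survey regions. Free labels are accepted in input tables; these
#: are the defaults used by the synthetic generator.
REGIONS: tuple[str, ...] = ("North", "South", "East", "West", "Center")

#: Instrument limits of detection, mg/kg dry weight, per element.
DEFAULT_LODS: dict[str, float] = {
    "Fe": 0.06, "Zn": 0.1, "Cu": 0.1, "Co": 0.02, "Cr": 0.06, "V": 0.06,
    "Al": 0.18, "Ni": 0.012, "As": 0.02, "Hg": 0.01, "Pb": 0.01, "Cd": 0.01,
}

CONCENTRATION_COLUMNS = (
    "region", "bakery_id", "stage", "bread_type", "element",
    "value", "censored", "lod",
)


class ParseError(ValueError):
    """Raised when an input table violates the schema."""


@dataclass(frozen=True)
class ExposureParams:
    """Cohort-specific ingestion-exposure parameters.

    Units: IR kg/day, EF days/year, ED years, BW kg, AT days.
    """

    cohort: str
    IR: float
    EF: float
    ED: float
    BW: float
    AT: float

    def __post_init__(self) -> None:
        for name in ("IR", "EF", "ED", "BW", "AT"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.EF > 366:
            raise ValueError(f"EF cannot exceed 366 days/year, got {self.EF}")


@dataclass(frozen=True)
class ToxProfile:
    """Oral toxicity reference values for one element.

    rfd: oral reference dose, mg/kg/day (non-carcinogenic endpoint).
    osf: oral slope factor, (mg/kg/day)^-1 (carcinogenic endpoint).
    At least one must be present for the element to enter risk computation.
    """

    element: str
    rfd: float | None = None
    osf: float | None = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(
                f"unknown element {self.element!r}; allowed: {', '.join(ELEMENTS)}"
            )
        if self.rfd is None and self.osf is None:
            raise ValueError(f"{self.element}: at least one of rfd/osf required")
        for name in ("rfd", "osf"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.element}: {name} must be positive, got {v}")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Risk classification thresholds.

    hq_limit: hazard quotient / hazard index threshold (concern above 1).
    cr_de_minimis: cancer risk below which risk is negligible (1e-6).
    cr_unacceptable: cancer risk above which risk is unacceptable (1e-4);
    between the two lies the conventionally acceptable range.
    """

    hq_limit: float = 1.0
    cr_de_minimis: float = 1e-6
    cr_unacceptable: float = 1e-4

    def __post_init__(self) -> None:
        if not self.hq_limit > 0:
            raise ValueError("hq_limit must be positive")
        if not self.cr_de_minimis < self.cr_unacceptable:
            raise ValueError("cr_de_minimis must be below cr_unacceptable")


@dataclass(frozen=True)
class LimitEntry:
    """One regulatory permissible limit (mg/kg) for an element."""

    element: str
    limit: float
    authority: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if not self.limit > 0:
            raise ValueError("limit must be positive")


# ---------------------------------------------------------------------------
# Built-in defaults
# ---------------------------------------------------------------------------

_DEFAULT_RFD: dict[str, float] = {
    "As": 0.003, "Cd": 0.001, "Al": 0.7, "Co": 0.0004, "Cu": 0.04,
    "Fe": 0.7, "Hg": 0.0004, "V": 0.009, "Zn": 0.3, "Cr": 0.003,
    "Ni": 0.2, "Pb": 0.0035,
}

_DEFAULT_OSF: dict[str, float] = {"As": 1.5, "Pb": 0.0085, "Cd": 0.38}


@dataclass(frozen=True)
class StudyDefaults:
    """Bundle of the built-in exposure, toxicity and threshold defaults."""

    adult: ExposureParams
    child: ExposureParams
    tox: Mapping[str, ToxProfile]
    thresholds: ThresholdPolicy

    @property
    def cohorts(self) -> dict[str, ExposureParams]:
        return {"adult": self.adult, "child": self.child}


def builtin_defaults() -> StudyDefaults:
    """Built-in exposure parameters and toxicity values.

    Adult: IR 0.420 kg/day (Iranian per-capita bread consumption of 420 g),
    ED 70 y, BW 70 kg, AT 10550 d. Child: IR 0.210, ED 6 y, BW 20 kg,
    AT 2100 d. EF 365 d/y for both. RfD/OSF are EPA screening-level oral
    values for the 12-element panel.
    """
    adult = ExposureParams("adult", IR=0.420, EF=365, ED=70, BW=70, AT=10550)
    child = ExposureParams("child", IR=0.210, EF=365, ED=6, BW=20, AT=2100)
    tox = {
        el: ToxProfile(el, rfd=_DEFAULT_RFD.get(el), osf=_DEFAULT_OSF.get(el))
        for el in ELEMENTS
    }
    return StudyDefaults(adult=adult, child=child, tox=tox,
                         thresholds=ThresholdPolicy())


# ---------------------------------------------------------------------------
# Concentration table I/O
# ---------------------------------------------------------------------------

_LT_RE = re.compile(r"^\s*<\s*([0-9.eE+-]+)\s*$")


def _parse_value_cell(raw, row_no: int):
    """Return (value, censored_from_value, lod_from_value) for one cell."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return (np.nan, None, None)
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return (np.nan, None, None)
        m = _LT_RE.match(raw)
        if m:
            lod = float(m.group(1))
            if not lod > 0:
                raise ParseError(f"row {row_no}: non-positive LOD in {raw!r}")
            return (np.nan, True, lod)
        try:
            raw = float(raw)
        except ValueError as exc:
            raise ParseError(f"row {row_no}: unparseable value {raw!r}") from exc
    v = float(raw)
    if v < 0:
        raise ParseError(f"row {row_no}: negative concentration {v}")
    return (v, None, None)


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


def _parse_bool(raw, row_no: int) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return False
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ParseError(f"row {row_no}: unparseable censored flag {raw!r}")


def validate_concentrations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a raw concentration table.

    Accepts censored cells either as ``censored=true`` with ``lod`` set, or as
    a ``"<LOD"`` string in the value column (e.g. ``<0.01``). Returns a typed
    copy with columns region, bakery_id, stage, bread_type, element, value
    (float, NaN when censored), censored (bool), lod (float, NaN when not
    recorded). Errors name the offending row (1-based data row).
    """
    missing = [c for c in ("region", "bakery_id", "stage", "element", "value")
               if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {', '.join(missing)}")

    df = df.copy()
    if "bread_type" not in df.columns:
        df["bread_type"] = "unknown"
    if "censored" not in df.columns:
        df["censored"] = False
    if "lod" not in df.columns:
        df["lod"] = np.nan

    out = {c: [] for c in CONCENTRATION_COLUMNS}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        stage = row.stage
        if not isinstance(stage, str) or stage not in STAGES:
            raise ParseError(
                f"row {i}: missing or invalid stage {stage!r}; "
                f"allowed: {', '.join(STAGES)}"
            )
        element = row.element
        if element not in ELEMENTS:
            raise ParseError(
                f"row {i}: unknown element {element!r}; "
                f"allowed: {', '.join(ELEMENTS)}"
            )
        bread_type = row.bread_type
        if not isinstance(bread_type, str) or bread_type == "" or (
                isinstance(bread_type, float) and math.isnan(bread_type)):
            bread_type = "unknown"
        if bread_type not in BREAD_TYPES:
            raise ParseError(
                f"row {i}: unknown bread_type {bread_type!r}; "
                f"allowed: {', '.join(BREAD_TYPES)}"
            )

        value, cens_from_value, lod_from_value = _parse_value_cell(row.value, i)
        censored = _parse_bool(row.censored, i)
        if cens_from_value:
            censored = True
        lod = row.lod
        lod = float(lod) if lod is not None and not pd.isna(lod) else np.nan
        if lod_from_value is not None:
            lod = lod_from_value

        if censored:
            if not (lod > 0):
                raise ParseError(f"row {i}: censored record without a positive LOD")
            value = np.nan
        else:
            if math.isnan(value):
                raise ParseError(f"row {i}: uncensored record without a value")
            if value < 0:
                raise ParseError(f"row {i}: negative concentration {value}")

        out["region"].append(str(row.region))
        out["bakery_id"].append(str(row.bakery_id))
        out["stage"].append(stage)
        out["bread_type"].append(bread_type)
        out["element"].append(element)
        out["value"].append(value)
        out["censored"].append(censored)
        out["lod"].append(lod)

    res = pd.DataFrame(out)
    res["value"] = res["value"].astype(float)
    res["censored"] = res["censored"].astype(bool)
    res["lod"] = res["lod"].astype(float)
    return res


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format concentration CSV.

    Columns: region, bakery_id, stage, bread_type, element, value, censored,
    lod. Lines starting with ``#`` are treated as metadata comments.
    """
    raw = pd.read_csv(path, comment="#", dtype={"value": str})
    return validate_concentrations(raw)


def read_limits(path: str | Path) -> pd.DataFrame:
    """Read a permissible-limit CSV: element, authority, limit_mg_kg."""
    df = pd.read_csv(path, comment="#")
    required = {"element", "authority", "limit_mg_kg"}
    if not required.issubset(df.columns):
        raise ParseError(f"limits CSV must have columns {sorted(required)}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        LimitEntry(row.element, float(row.limit_mg_kg), str(row.authority))
    return df[["element", "authority", "limit_mg_kg"]].copy()


def load_example_limits() -> pd.DataFrame:
    """Illustrative permissible limits bundled for demos and tests.

    These are synthetic placeholder numbers sized against the synthetic
    generator's default concentration scales — not actual WHO/FAO or national
    limit values, which users must supply in their own limits CSV.
    """
    path = Path(__file__).parent / "data" / "limits_synthetic.csv"
    return read_limits(path)


# ---------------------------------------------------------------------------
# Risk tables
# ---------------------------------------------------------------------------


@dataclass
class RiskTable:
    """Per (region, cohort) deterministic risk estimates.

    All frames are indexed by a (region, cohort) MultiIndex; ``cdi``, ``hq``
    and ``cr`` have one column per element, ``hi`` and ``tcr`` are Series.
    ``hi`` is the row sum of ``hq`` and ``tcr`` the row sum of ``cr`` by
    construction; the constructor enforces both identities and non-negativity.
    """

    cdi: pd.DataFrame
    hq: pd.DataFrame
    hi: pd.Series
    cr: pd.DataFrame
    tcr: pd.Series

    def __post_init__(self) -> None:
        if len(self.hq) == 0:
            raise ValueError("empty risk table")
        for name, frame in (("cdi", self.cdi), ("hq", self.hq), ("cr", self.cr)):
            if (frame.to_numpy() < 0).any():
                raise ValueError(f"{name} contains negative entries")
        if not np.allclose(self.hq.sum(axis=1).to_numpy(), self.hi.to_numpy(),
                           rtol=1e-12, atol=1e-15):
            raise ValueError("hi must equal the row sum of hq")
        if not np.allclose(self.cr.sum(axis=1).to_numpy(), self.tcr.to_numpy(),
                           rtol=1e-12, atol=1e-300):
            raise ValueError("tcr must equal the row sum of cr")

    @classmethod
    def from_components(cls, cdi: pd.DataFrame, hq: pd.DataFrame,
                        cr: pd.DataFrame) -> "RiskTable":
        return cls(cdi=cdi, hq=hq, hi=hq.sum(axis=1),
                   cr=cr, tcr=cr.sum(axis=1))

    @property
    def rows(self) -> pd.MultiIndex:
        return self.hq.index

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one wide row per (region, cohort)."""
        parts = [
            self.cdi.add_prefix("cdi_"),
            self.hq.add_prefix("hq_"),
            self.hi.rename("hi"),
            self.cr.add_prefix("cr_"),
            self.tcr.rename("tcr"),
        ]
        return pd.concat(parts, axis=1)


def write_risk_report(table: RiskTable, path: str | Path,
                      metadata: Mapping[str, object] | None = None) -> None:
    """Write a RiskTable to CSV, one row per (region, cohort).

    Numeric values round-trip losslessly (written at full precision).
    Optional metadata is emitted as leading ``# key=value`` comment lines.
    """
    if len(table.hq) == 0:  # pragma: no cover - constructor forbids this
        raise ValueError("refusing to write an empty risk table")
    frame = table.to_frame().reset_index()
    buf = io.StringIO()
    if metadata:
        for k, v in metadata.items():
            buf.write(f"# {k}={v}\n")
    frame.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_risk_report(path: str | Path) -> RiskTable:
    """Inverse of :func:`write_risk_report`."""
    frame = pd.read_csv(path, comment="#")
    frame = frame.set_index(["region", "cohort"])
    cdi = frame[[c for c in frame.columns if c.startswith("cdi_")]]
    cdi = cdi.rename(columns=lambda c: c[len("cdi_"):])
    hq = frame[[c for c in frame.columns if c.startswith("hq_")]]
    hq = hq.rename(columns=lambda c: c[len("hq_"):])
    cr = frame[[c for c in frame.columns if c.startswith("cr_")]]
    cr = cr.rename(columns=lambda c: c[len("cr_"):])
    return RiskTable(cdi=cdi, hq=hq, hi=frame["hi"], cr=cr, tcr=frame["tcr"])
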