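"""Data model, packaged constants, and delimited-text I/O.

Units are fixed by convention and never auto-detected: soil concentrations in
mg/kg, extract concentrations in µg/L, soil ingestion rates in kg/day.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Method",
    "SiteGroup",
    "RbaRule",
    "Measurement",
    "SampleRecord",
    "ElementInfo",
    "ReceptorProfile",
    "CHILD",
    "ADULT",
    "ANALYSIS_ELEMENTS",
    "HI_ELEMENTS",
    "ParseError",
    "ValidationError",
    "builtin_registry",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "write_results",
    "read_results",
    "read_config",
]


class ParseError(ValueError):
    """A malformed input row or cell."""


class ValidationError(ValueError):
    """A structurally valid value that violates a domain constraint."""


class Method(str, enum.Enum):
    XRF = "XRF"
    ICPMS = "ICPMS"


class SiteGroup(str, enum.Enum):
    COMMUNITY = "community"
    BURNING = "burning"
    DISMANTLING = "dismantling"
    BACKGROUND = "background"


class RbaRule(str, enum.Enum):
    """How relative bioavailability is resolved for an element.

    ``regression_as``/``regression_pb`` use the in vivo/in vitro linear
    regressions; ``direct_ivba`` uses the bioaccessible percentage itself;
    ``fixed_one`` assumes complete bioavailability (used where extract
    concentrations sit below detection and no IVBA can be measured).
    """

    REGRESSION_AS = "regression_as"
    REGRESSION_PB = "regression_pb"
    DIRECT_IVBA = "direct_ivba"
    FIXED_ONE = "fixed_one"


@dataclass(frozen=True)
class Measurement:
    """One possibly left-censored concentration in mg/kg.

    For a censored result ``value`` is ``None`` and ``detection_limit`` is the
    reporting bound ("<LOD"). For an uncensored result ``value`` is the
    measured concentration and ``detection_limit``, when known, is the
    instrument LOD.
    """

    value: float | None
    censored: bool = False
    detection_limit: float | None = None
    method: Method = Method.XRF

    def __post_init__(self) -> None:
        if self.censored:
            if self.value is not None:
                raise ValidationError("censored measurement must not carry a value")
            if self.detection_limit is None or self.detection_limit <= 0:
                raise ValidationError("censored measurement needs a positive detection limit")
        else:
            if self.value is None or self.value <= 0:
                raise ValidationError("uncensored measurement needs a positive value")
            if self.detection_limit is not None and self.detection_limit <= 0:
                raise ValidationError("detection limit must be positive")

    def resolved(self, convention: str = "half_lod") -> float:
        """Numeric stand-in for risk arithmetic: the value, or for censored
        cells the LOD substitution given by *convention* (``half_lod``,
        ``lod`` or ``zero``)."""
        if not self.censored:
            assert self.value is not None
            return self.value
        assert self.detection_limit is not None
        if convention == "half_lod":
            return self.detection_limit / 2.0
        if convention == "lod":
            return self.detection_limit
        if convention == "zero":
            return 0.0
        raise ValueError(f"unknown censoring convention {convention!r}")


@dataclass
class SampleRecord:
    """One soil sample: id, site group, optional local coordinates (meters),
    and a map element symbol -> :class:`Measurement`."""

    sample_id: str
    site_group: SiteGroup
    x: float | None = None
    y: float | None = None
    measurements: dict[str, Measurement] = field(default_factory=dict)


@dataclass(frozen=True)
class ElementInfo:
    """Per-element packaged constants.

    ``tdi`` is the tolerable daily intake (mg·kg⁻¹·d⁻¹); ``csf`` the oral
    cancer slope factor ((mg·kg⁻¹·d⁻¹)⁻¹), present only for elements treated
    as carcinogens; guideline values are soil screening levels in mg/kg.
    ``background_mean`` (M_b) is site-specific and therefore user-supplied via
    config, not packaged.
    """

    symbol: str
    lod_xrf: float | None
    tdi: float | None = None
    csf: float | None = None
    ccme_residential: float | None = None
    dutch_intervention: float | None = None
    background_mean: float | None = None
    rba_rule: RbaRule = RbaRule.FIXED_ONE

    def __post_init__(self) -> None:
        for name in ("lod_xrf", "tdi", "csf", "ccme_residential", "dutch_intervention", "background_mean"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{self.symbol}.{name} must be positive, got {v}")


@dataclass(frozen=True)
class ReceptorProfile:
    """Exposure receptor for incidental soil ingestion.

    The exposure term is the dimensionless fraction
    ``(days_per_week/7) × (weeks_per_year/52)``; with the default continuous
    residential scenario it equals 1. ``exposure_duration / life_expectancy``
    enters the dose only for carcinogens.
    """

    name: str
    ing_rate: float  # kg soil / day
    body_weight: float  # kg
    days_per_week: float = 7.0
    weeks_per_year: float = 52.0
    exposure_duration: float = 64.0  # years
    life_expectancy: float = 64.0  # years
    carcinogen_assessment: bool = False

    def __post_init__(self) -> None:
        if self.ing_rate <= 0 or self.body_weight <= 0:
            raise ValidationError("ing_rate and body_weight must be positive")
        if self.days_per_week > 7 or self.weeks_per_year > 52:
            raise ValidationError("days_per_week ≤ 7 and weeks_per_year ≤ 52 required")
        if self.exposure_duration > self.life_expectancy:
            raise ValidationError("exposure_duration cannot exceed life_expectancy")

    @property
    def exposure_fraction(self) -> float:
        return (self.days_per_week / 7.0) * (self.weeks_per_year / 52.0)

    @property
    def carcinogen_years_fraction(self) -> float:
        return self.exposure_duration / self.life_expectancy


#: Default receptors: child 0.0004 kg/day, 30 kg; adult 0.0001 kg/day, 70 kg;
#: life expectancy 64 y; continuous exposure. Cancer risk is assessed for the
#: adult receptor by default.
CHILD = ReceptorProfile("child", ing_rate=0.0004, body_weight=30.0)
ADULT = ReceptorProfile("adult", ing_rate=0.0001, body_weight=70.0, carcinogen_assessment=True)

#: The 12 toxicologically significant metals retained for analysis.
ANALYSIS_ELEMENTS = ("Ag", "As", "Au", "Cd", "Cr", "Cu", "Mo", "Ni", "Pb", "Sb", "Sn", "Zn")

#: Elements whose hazard quotients are summed into the hazard index (Au is
#: retained for distribution analysis but has no oral TDI).
HI_ELEMENTS = ("Ag", "As", "Cd", "Cr", "Cu", "Mo", "Ni", "Pb", "Sb", "Sn", "Zn")

_REGISTRY_ROWS: list[dict] = [
    # symbol, XRF LOD, TDI, CSF, CCME residential, Dutch intervention, rba_rule
    dict(symbol="Ag", lod_xrf=4.0, tdi=0.005, rba_rule=RbaRule.DIRECT_IVBA),
    dict(symbol="As", lod_xrf=4.0, tdi=0.0003, csf=1.8, ccme_residential=12.0,
         dutch_intervention=55.0, rba_rule=RbaRule.REGRESSION_AS),
    dict(symbol="Au", lod_xrf=4.0, rba_rule=RbaRule.FIXED_ONE),
    dict(symbol="Cd", lod_xrf=6.0, tdi=0.0005, ccme_residential=10.0,
         dutch_intervention=12.0, rba_rule=RbaRule.FIXED_ONE),
    dict(symbol="Cr", lod_xrf=9.0, tdi=0.003, ccme_residential=64.0,
         dutch_intervention=380.0, rba_rule=RbaRule.DIRECT_IVBA),
    dict(symbol="Cu", lod_xrf=15.0, tdi=0.01, ccme_residential=63.0,
         dutch_intervention=190.0, rba_rule=RbaRule.DIRECT_IVBA),
    dict(symbol="Mo", lod_xrf=3.0, tdi=0.005, rba_rule=RbaRule.FIXED_ONE),
    dict(symbol="Ni", lod_xrf=17.0, tdi=0.02, ccme_residential=45.0,
         dutch_intervention=210.0, rba_rule=RbaRule.DIRECT_IVBA),
    dict(symbol="Pb", lod_xrf=4.0, tdi=0.0036, ccme_residential=140.0,
         dutch_intervention=210.0, rba_rule=RbaRule.REGRESSION_PB),
    dict(symbol="Sb", lod_xrf=7.0, tdi=0.0005, ccme_residential=20.0,
         dutch_intervention=15.0, rba_rule=RbaRule.FIXED_ONE),
    dict(symbol="Sn", lod_xrf=5.0, tdi=0.6, ccme_residential=50.0, rba_rule=RbaRule.FIXED_ONE),
    dict(symbol="Zn", lod_xrf=12.0, tdi=0.3, ccme_residential=250.0,
         dutch_intervention=720.0, rba_rule=RbaRule.DIRECT_IVBA),
    # Fe is carried as the enrichment-factor normalizer only; it is not part
    # of the 12-element analysis set and has no toxicity or guideline values.
    dict(symbol="Fe", lod_xrf=None, rba_rule=RbaRule.FIXED_ONE),
]


def builtin_registry(backgrounds: Mapping[str, float] | None = None) -> dict[str, ElementInfo]:
    """Packaged element registry: XRF detection limits, oral TDIs, the As
    cancer slope factor, CCME residential and Dutch intervention screening
    values, and the per-element RBA resolution rule.

    *backgrounds* optionally attaches user-supplied background means M_b
    (mg/kg), e.g. from a control-site config.
    """
    registry = {row["symbol"]: ElementInfo(**row) for row in _REGISTRY_ROWS}
    if backgrounds:
        for sym, mb in backgrounds.items():
            if sym not in registry:
                raise KeyError(f"background supplied for unknown element {sym!r}")
            registry[sym] = replace(registry[sym], background_mean=float(mb))
    return registry


# ---------------------------------------------------------------------------
# sample table I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ("sample_id", "site_group", "x", "y")


def _parse_cell(cell, lod: float | None, method: Method, row_label: str, element: str) -> Measurement | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return None
    if text.startswith("<"):
        try:
            bound = float(text[1:])
        except ValueError as exc:
            raise ParseError(f"row {row_label}: bad censoring mark {text!r} for {element}") from exc
        return Measurement(None, censored=True, detection_limit=bound, method=method)
    try:
        value = float(text)
    except ValueError as exc:
        raise ParseError(f"row {row_label}: non-numeric cell {text!r} for {element}") from exc
    if value <= 0:
        raise ValidationError(f"row {row_label}: non-positive concentration {value} for {element}")
    return Measurement(value, detection_limit=lod, method=method)


def read_samples(path: str | Path, registry: Mapping[str, ElementInfo], *,
                 method: Method = Method.XRF) -> list[SampleRecord]:
    """Read a sample CSV into :class:`SampleRecord` objects.

    Expected header: ``sample_id, site_group[, x, y], <element columns…>``.
    Concentration cells are either plain positive numbers (mg/kg) or
    left-censoring marks ``<X`` where X is the reporting limit. A paired
    two-column dialect is also accepted: a numeric column ``E`` plus a boolean
    ``E_censored`` column, in which case the numeric cell of a censored row
    holds the detection limit. Columns naming elements absent from *registry*
    are ignored with a warning.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    if "sample_id" not in df.columns or "site_group" not in df.columns:
        raise ParseError("sample file must have sample_id and site_group columns")
    flag_cols = {c: c[: -len("_censored")] for c in df.columns if c.endswith("_censored")}
    element_cols = [c for c in df.columns if c not in _META_COLUMNS and c not in flag_cols]
    known, unknown = [], []
    for c in element_cols:
        (known if c in registry else unknown).append(c)
    if unknown:
        warnings.warn(f"ignoring unknown element columns: {', '.join(unknown)}")

    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        label = f"{i + 2}"  # header is line 1
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ParseError(f"row {label}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            group = SiteGroup(str(row["site_group"]).strip())
        except ValueError as exc:
            raise ParseError(f"row {label}: unknown site_group {row['site_group']!r}") from exc
        coords = {}
        for axis in ("x", "y"):
            if axis in df.columns and not pd.isna(row[axis]):
                coords[axis] = float(row[axis])
        meas: dict[str, Measurement] = {}
        for col in known:
            lod = registry[col].lod_xrf
            flagged = flag_cols and f"{col}_censored" in df.columns and \
                str(row.get(f"{col}_censored", "")).strip().lower() in ("1", "true", "yes")
            if flagged:
                cell = row[col]
                bound = float(cell) if cell is not None and str(cell).strip() else lod
                meas[col] = Measurement(None, censored=True, detection_limit=bound, method=method)
                continue
            m = _parse_cell(row[col], lod, method, label, col)
            if m is not None:
                meas[col] = m
        records.append(SampleRecord(sid, group, coords.get("x"), coords.get("y"), meas))
    return records


def samples_to_frame(samples: Sequence[SampleRecord], *, convention: str | None = None) -> pd.DataFrame:
    """Tabular view of samples. With ``convention=None`` censored cells render
    as ``<LOD`` strings (the on-disk dialect); otherwise they are substituted
    numerically via :meth:`Measurement.resolved`."""
    elements = sorted({e for s in samples for e in s.measurements})
    rows = []
    for s in samples:
        row: dict = {"sample_id": s.sample_id, "site_group": s.site_group.value, "x": s.x, "y": s.y}
        for e in elements:
            m = s.measurements.get(e)
            if m is None:
                row[e] = None
            elif m.censored and convention is None:
                row[e] = f"<{m.detection_limit:g}"
            else:
                row[e] = m.value if convention is None else m.resolved(convention)
        rows.append(row)
    return pd.DataFrame(rows)


def write_samples(samples: Sequence[SampleRecord], path: str | Path, *,
                  header_lines: Iterable[str] = ()) -> None:
    """Write samples in the CSV dialect :func:`read_samples` reads, censored
    cells emitted as ``<LOD`` marks. Concentrations keep 12 significant
    digits so a write/read cycle reproduces the records."""
    write_results(samples_to_frame(samples), path, precision=12,
                  header_lines=header_lines)


def write_results(table: pd.DataFrame, path: str | Path, *, precision: int = 6,
                  allow_empty: bool = False, header_lines: Iterable[str] = ()) -> None:
    """Write any pipeline output table as delimited text with a stable column
    order and optional ``#``-prefixed provenance header lines."""
    if table.empty and not allow_empty and len(table.columns) == 0:
        raise ValueError("refusing to write an empty, column-less table (pass allow_empty=True)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, float_format=f"%.{precision}g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results` (skips ``#`` headers)."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Load a nested key-value run config (YAML): receptors, background means,
    censoring convention, thresholds, seed. Missing sections get defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError("config root must be a mapping")
    cfg: dict = {
        "receptors": [CHILD, ADULT],
        "backgrounds": {},
        "censored_convention": "half_lod",
        "thresholds": {"hi_limit": 1.0, "cr_limit": 1e-5, "alpha": 0.05},
        "seed": 0,
    }
    if "receptors" in raw:
        cfg["receptors"] = [ReceptorProfile(**r) for r in raw["receptors"]]
    for key in ("backgrounds", "censored_convention", "seed"):
        if key in raw:
            cfg[key] = raw[key]
    if "thresholds" in raw:
        cfg["thresholds"].update(raw["thresholds"])
    for name, v in cfg["thresholds"].items():
        if v <= 0:
            raise ValidationError(f"threshold {name} must be positive")
    return cfg
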