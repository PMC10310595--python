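"""Enrichment factor, geoaccumulation index, descriptive pollution classes,
and soil-guideline exceedance screening.

The enrichment factor normalizes to Fe, EF = (Ms·Feb)/(Mb·Fes), so that a
sample at background composition scores exactly 1 regardless of units. The
geoaccumulation index Igeo = log2(Ms / (1.5·Mb)) compares a sample to 1.5×
background, the factor absorbing natural lithogenic variability.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .censored_stats import CensoredSummary
from .core_data import ElementInfo, SampleRecord

__all__ = [
    "IndexResult",
    "ExceedanceRow",
    "EF_CLASSES",
    "IGEO_CLASSES",
    "enrichment_factor",
    "geoaccumulation",
    "classify_index",
    "guideline_screen",
    "sample_indices",
]

# (upper bound, label); intervals are closed on the right, so a value exactly
# on a boundary falls in the lower bin.
EF_CLASSES: list[tuple[float, str]] = [
    (2.0, "deficiency to minimal enrichment"),
    (5.0, "moderate enrichment"),
    (20.0, "significant enrichment"),
    (40.0, "very high enrichment"),
    (math.inf, "extremely high enrichment"),
]

IGEO_CLASSES: list[tuple[float, str]] = [
    (0.0, "unpolluted"),
    (1.0, "unpolluted to moderately polluted"),
    (2.0, "moderately polluted"),
    (3.0, "moderately to highly polluted"),
    (4.0, "highly polluted"),
    (5.0, "highly to extremely high polluted"),
    (6.0, "extremely high polluted"),
]


@dataclass
class IndexResult:
    element: str
    ef: float | None
    ef_class: str | None
    igeo: float | None
    igeo_class: str | None
    flags: set[str] = field(default_factory=set)


@dataclass
class ExceedanceRow:
    element: str
    site_group: str
    mean: float
    guideline_name: str
    guideline_value: float
    exceeds: bool
    ratio: float


def enrichment_factor(ms: float, fes: float, mb: float, feb: float) -> float:
    """Fe-normalized enrichment factor (Ms × Feb) / (Mb × Fes)."""
    for name, v in (("ms", ms), ("fes", fes), ("mb", mb), ("feb", feb)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (ms * feb) / (mb * fes)


def geoaccumulation(ms: float, mb: float) -> float:
    """Geoaccumulation index log2(Ms / (1.5 × Mb))."""
    if ms <= 0 or mb <= 0:
        raise ValueError("concentrations must be positive")
    return math.log2(ms / (1.5 * mb))


def classify_index(value: float, scheme: str) -> str:
    """Descriptive class for an EF or Igeo value.

    Bins are closed on the right (a boundary value takes the lower class).
    An Igeo above 6 is off the descriptive scale and keeps the top label.
    """
    if scheme == "ef":
        if value <= 0:
            raise ValueError("EF must be positive")
        table = EF_CLASSES
    elif scheme == "igeo":
        table = IGEO_CLASSES
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    for upper, label in table:
        if value <= upper:
            return label
    return table[-1][1]  # Igeo > 6: out of scale, top class retained


def sample_indices(sample: SampleRecord, registry: Mapping[str, ElementInfo],
                   elements: Iterable[str], *, fe_background: float | None = None,
                   convention: str = "half_lod") -> list[IndexResult]:
    """Per-sample EF and Igeo against registry background means.

    EF needs an Fe measurement in the sample and an Fe background (either
    *fe_background* or ``registry["Fe"].background_mean``); when absent only
    Igeo is produced, flagged accordingly. Censored concentrations enter via
    the LOD-substitution *convention* and are flagged.
    """
    feb = fe_background
    if feb is None and "Fe" in registry:
        feb = registry["Fe"].background_mean
    fe_meas = sample.measurements.get("Fe")
    fes = fe_meas.resolved(convention) if fe_meas is not None else None
    out: list[IndexResult] = []
    for element in elements:
        info = registry.get(element)
        m = sample.measurements.get(element)
        if info is None or m is None or info.background_mean is None:
            out.append(IndexResult(element, None, None, None, None, {"missing_background" if info and info.background_mean is None else "missing_data"}))
            continue
        flags: set[str] = set()
        if m.censored:
            flags.add("censored_substituted")
        ms = m.resolved(convention)
        igeo = geoaccumulation(ms, info.background_mean)
        igeo_class = classify_index(igeo, "igeo")
        if igeo > 6:
            flags.add("igeo_out_of_scale")
        if fes is not None and feb is not None:
            ef = enrichment_factor(ms, fes, info.background_mean, feb)
            ef_class = classify_index(ef, "ef")
        else:
            ef, ef_class = None, None
            flags.add("no_fe_normalizer")
        out.append(IndexResult(element, ef, ef_class, igeo, igeo_class, flags))
    return out


def guideline_screen(summaries: Mapping[tuple[str, str], CensoredSummary],
                     registry: Mapping[str, ElementInfo]) -> list[ExceedanceRow]:
    """Compare KM mean concentrations per (element, site group) against every
    available guideline. Exceedance is strict: a mean exactly at the guideline
    does not exceed. Elements with no guideline value are skipped."""
    rows: list[ExceedanceRow] = []
    for (element, group), summary in summaries.items():
        info = registry.get(element)
        if info is None:
            continue
        for name, value in (("CCME residential", info.ccme_residential),
                            ("Dutch intervention", info.dutch_intervention)):
            if value is None:
                continue
            ratio = summary.mean / value
            rows.append(ExceedanceRow(element, group, summary.mean, name, value,
                                      exceeds=ratio > 1.0, ratio=ratio))
    return rows


def exceedance_table(rows: Sequence[ExceedanceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
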