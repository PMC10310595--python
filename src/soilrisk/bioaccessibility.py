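"""In vitro bioaccessibility (gastric-phase glycine extraction) and its
conversion to relative bioavailability.

IVBA% is the fraction of the total soil concentration that dissolves in the
extraction vessel (default 1 g soil in 100 mL fluid). RBA is resolved per
element: validated in vivo/in vitro regressions for As and Pb, the IVBA value
used directly where no regression exists, and RBA = 1 where extract
concentrations sit below detection and IVBA cannot be measured.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import ElementInfo, RbaRule

__all__ = [
    "BioaccessRecord",
    "DEFAULT_SOIL_MASS_G",
    "DEFAULT_FLUID_VOLUME_L",
    "ivba_percent",
    "rba_arsenic",
    "rba_lead",
    "resolve_rba",
    "process_bioaccess",
    "mean_ivba_by_element",
]

DEFAULT_SOIL_MASS_G = 1.0
DEFAULT_FLUID_VOLUME_L = 0.1


@dataclass
class BioaccessRecord:
    """One extraction measurement with derived IVBA% and resolved RBA."""

    sample_id: str
    element: str
    extract_conc: float  # µg/L
    fluid_volume: float  # L
    soil_mass: float  # g
    total_conc: float  # mg/kg
    ivba_pct: float | None = None
    rba_fraction: float | None = None
    rba_source: RbaRule | None = None
    flags: set[str] = field(default_factory=set)


def ivba_percent(extract_conc: float, fluid_volume: float = DEFAULT_FLUID_VOLUME_L,
                 soil_mass: float = DEFAULT_SOIL_MASS_G, total_conc: float = 1.0) -> float:
    """Percent bioaccessibility from one extraction.

    Bioaccessible concentration (µg/g ≡ mg/kg) is extract_conc × volume /
    mass; IVBA% is that over the total concentration × 100. With the default
    1 g / 100 mL vessel, IVBA% = 10 × extract(µg/L) / total(mg/kg). The
    result may exceed 100% (measurement error on heterogeneous soils); it is
    reported as computed and flagged downstream.
    """
    for name, v in (("extract_conc", extract_conc), ("fluid_volume", fluid_volume),
                    ("soil_mass", soil_mass), ("total_conc", total_conc)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    bioaccessible = extract_conc * fluid_volume / soil_mass
    return 100.0 * bioaccessible / total_conc


def rba_arsenic(ivba: float) -> float:
    """Arsenic RBA(%) = 0.79 × IVBA(%) + 3, clamped to [0, 100]."""
    if ivba < 0:
        raise ValueError("IVBA must be non-negative")
    return min(max(0.79 * ivba + 3.0, 0.0), 100.0)


def rba_lead(ivba: float) -> float:
    """Lead RBA(%) = 0.878 × IVBA(%) − 2.8, clamped to [0, 100]."""
    if ivba < 0:
        raise ValueError("IVBA must be non-negative")
    return min(max(0.878 * ivba - 2.8, 0.0), 100.0)


def resolve_rba(element: str, ivba: float | None,
                registry: Mapping[str, ElementInfo]) -> tuple[float, RbaRule, set[str]]:
    """Relative bioavailability fraction in [0, 1] for *element*.

    Applies the element's registry rule: the As/Pb regressions, direct IVBA
    (capped at 100% with an ``ivba_gt_100`` flag), or a fixed RBA of 1.
    A direct-IVBA element with no measured IVBA falls back to 1 and is
    flagged ``rba_defaulted``.
    """
    info = registry.get(element)
    if info is None:
        raise KeyError(f"unknown element {element!r}")
    rule = info.rba_rule
    flags: set[str] = set()
    if rule is RbaRule.FIXED_ONE:
        return 1.0, rule, flags
    if ivba is None:
        flags.add("rba_defaulted")
        return 1.0, rule, flags
    if ivba > 100.0:
        flags.add("ivba_gt_100")
    if rule is RbaRule.REGRESSION_AS:
        return rba_arsenic(ivba) / 100.0, rule, flags
    if rule is RbaRule.REGRESSION_PB:
        return rba_lead(ivba) / 100.0, rule, flags
    # direct IVBA, capped so the fraction stays physical
    return min(ivba, 100.0) / 100.0, rule, flags


def process_bioaccess(table: pd.DataFrame, registry: Mapping[str, ElementInfo], *,
                      extract_lods: Mapping[str, float] | None = None) -> list[BioaccessRecord]:
    """Turn a raw extraction table into resolved :class:`BioaccessRecord`s.

    Expected columns: sample_id, element, extract_conc_ugL, soil_mass_g,
    fluid_volume_mL, total_mgkg. A record whose extract concentration falls
    below its element's extract LOD gets no IVBA (flag ``below_extract_lod``)
    and its RBA falls back per :func:`resolve_rba`.
    """
    required = {"sample_id", "element", "extract_conc_ugL", "soil_mass_g",
                "fluid_volume_mL", "total_mgkg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"bioaccessibility table missing columns: {sorted(missing)}")
    extract_lods = extract_lods or {}
    records: list[BioaccessRecord] = []
    for _, row in table.iterrows():
        element = str(row["element"])
        rec = BioaccessRecord(
            sample_id=str(row["sample_id"]),
            element=element,
            extract_conc=float(row["extract_conc_ugL"]),
            fluid_volume=float(row["fluid_volume_mL"]) / 1000.0,
            soil_mass=float(row["soil_mass_g"]),
            total_conc=float(row["total_mgkg"]),
        )
        lod = extract_lods.get(element)
        if lod is not None and rec.extract_conc < lod:
            rec.flags.add("below_extract_lod")
        else:
            rec.ivba_pct = ivba_percent(rec.extract_conc, rec.fluid_volume,
                                        rec.soil_mass, rec.total_conc)
            if rec.ivba_pct > 100.0:
                rec.flags.add("ivba_gt_100")
        if element in registry:
            frac, source, flags = resolve_rba(element, rec.ivba_pct, registry)
            rec.rba_fraction, rec.rba_source = frac, source
            rec.flags |= flags
        else:
            rec.flags.add("element_not_in_registry")
        records.append(rec)
    return records


def mean_ivba_by_element(records: Sequence[BioaccessRecord]) -> dict[str, float]:
    """Arithmetic mean IVBA% per element over records where IVBA exists
    (group-level fallback when a sample has no own extraction)."""
    acc: dict[str, list[float]] = {}
    for r in records:
        if r.ivba_pct is not None:
            acc.setdefault(r.element, []).append(r.ivba_pct)
    return {e: float(np.mean(v)) for e, v in acc.items()}


def bioaccess_table(records: Sequence[BioaccessRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "element": r.element,
            "extract_conc_ugL": r.extract_conc, "soil_mass_g": r.soil_mass,
            "fluid_volume_mL": r.fluid_volume * 1000.0, "total_mgkg": r.total_conc,
            "ivba_pct": r.ivba_pct, "rba_fraction": r.rba_fraction,
            "rba_source": r.rba_source.value if r.rba_source else None,
            "flags": ";".join(sorted(r.flags)),
        })
    return pd.DataFrame(rows)
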