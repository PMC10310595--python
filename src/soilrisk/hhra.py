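"""Oral-ingestion exposure and risk.

Chemical daily intake from incidental soil ingestion is
CDI = Msoil × IngR × ET / BW, with the additional factor
exposure_duration / life_expectancy applied for carcinogens only (lifetime
averaging). Hazard quotients HQ = CDI × RBA / TDI are summed into the hazard
index; arsenic cancer risk is CR = CDI × CSF × RBA. HI > 1 flags elevated
non-carcinogenic concern; the default CR acceptability limit is 1 × 10⁻⁵
(one excess cancer per 100,000 exposed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .bioaccessibility import BioaccessRecord, mean_ivba_by_element, resolve_rba
from .core_data import ElementInfo, HI_ELEMENTS, ReceptorProfile, SampleRecord

__all__ = [
    "Thresholds",
    "RbaMap",
    "RiskResult",
    "chemical_daily_intake",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "assess_dataset",
    "risk_table",
]


@dataclass(frozen=True)
class Thresholds:
    hi_limit: float = 1.0
    cr_limit: float = 1e-5

    def __post_init__(self) -> None:
        if self.hi_limit <= 0 or self.cr_limit <= 0:
            raise ValueError("thresholds must be positive")


class RbaMap:
    """Per-element (and optionally per-sample) relative bioavailability.

    ``per_element`` supplies group-level fractions; ``per_sample`` keyed by
    (sample_id, element) takes precedence where present. Elements absent from
    both fall back to :func:`~soilrisk.bioaccessibility.resolve_rba` with no
    IVBA (fixed-one elements get 1; direct-IVBA elements default to 1 with a
    flag).
    """

    def __init__(self, per_element: Mapping[str, float] | None = None,
                 per_sample: Mapping[tuple[str, str], float] | None = None):
        self.per_element = dict(per_element or {})
        self.per_sample = dict(per_sample or {})
        for frac in (*self.per_element.values(), *self.per_sample.values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"RBA fraction {frac} outside [0, 1]")

    @classmethod
    def from_records(cls, records: Sequence[BioaccessRecord],
                     registry: Mapping[str, ElementInfo]) -> "RbaMap":
        """Build from processed extraction records: per-sample resolved RBAs
        plus per-element fallbacks from mean IVBA (Table-5 style)."""
        per_sample = {(r.sample_id, r.element): r.rba_fraction
                      for r in records if r.rba_fraction is not None}
        per_element = {}
        for element, ivba in mean_ivba_by_element(records).items():
            if element in registry:
                frac, _, _ = resolve_rba(element, ivba, registry)
                per_element[element] = frac
        return cls(per_element, per_sample)

    def get(self, sample_id: str, element: str,
            registry: Mapping[str, ElementInfo]) -> tuple[float, set[str]]:
        if (sample_id, element) in self.per_sample:
            return self.per_sample[(sample_id, element)], set()
        if element in self.per_element:
            return self.per_element[element], {"rba_group_mean"}
        frac, _, flags = resolve_rba(element, None, registry)
        return frac, flags


@dataclass
class RiskResult:
    """Per sample × receptor risk bundle."""

    sample_id: str
    receptor: str
    cdi: dict[str, float] = field(default_factory=dict)
    rba: dict[str, float] = field(default_factory=dict)
    hq: dict[str, float] = field(default_factory=dict)
    hi: float = 0.0
    cr_as: float | None = None
    hi_exceeds: bool = False
    cr_exceeds: bool = False
    flags: set[str] = field(default_factory=set)


def chemical_daily_intake(msoil: float, receptor: ReceptorProfile,
                          carcinogenic: bool = False) -> float:
    """Dose rate (mg·kg⁻¹·d⁻¹) from incidental ingestion of soil at
    *msoil* mg/kg. For carcinogens the dose is averaged over the lifetime via
    exposure_duration / life_expectancy."""
    if msoil < 0:
        raise ValueError("msoil must be non-negative")
    if receptor.body_weight <= 0:
        raise ValueError("body weight must be positive")
    cdi = msoil * receptor.ing_rate * receptor.exposure_fraction / receptor.body_weight
    if carcinogenic:
        cdi *= receptor.carcinogen_years_fraction
    return cdi


def hazard_quotient(cdi: float, rba: float, tdi: float) -> float:
    """HQ = CDI × RBA / TDI."""
    if tdi <= 0:
        raise ValueError("TDI must be positive")
    if not 0.0 <= rba <= 1.0:
        raise ValueError("RBA fraction must lie in [0, 1]")
    return cdi * rba / tdi


def hazard_index(hqs: Mapping[str, float]) -> tuple[float, list[str]]:
    """Sum hazard quotients over the HI element set; returns (HI, the
    elements that contributed)."""
    if not hqs:
        raise ValueError("hazard_index needs at least one hazard quotient")
    contributing = [e for e in hqs if e in HI_ELEMENTS]
    return float(sum(hqs[e] for e in contributing)), contributing


def cancer_risk(cdi: float, csf: float, rba: float) -> float:
    """Incremental lifetime cancer risk CR = CDI × CSF × RBA (CSF in
    (mg·kg⁻¹·d⁻¹)⁻¹ so CR is dimensionless)."""
    if csf <= 0:
        raise ValueError("CSF must be positive")
    return cdi * csf * rba


def assess_dataset(samples: Sequence[SampleRecord],
                   registry: Mapping[str, ElementInfo],
                   rba_map: RbaMap | Mapping[str, float],
                   receptors: Sequence[ReceptorProfile],
                   thresholds: Thresholds = Thresholds(),
                   *, censored_convention: str = "half_lod") -> list[RiskResult]:
    """Full risk bundle per sample × receptor.

    Censored concentrations contribute via *censored_convention* (``half_lod``
    default; ``lod`` and ``zero`` bracket the answer). Elements with no TDI
    are skipped with a flag, never silently zeroed. Cancer risk (As only) is
    computed for receptors with ``carcinogen_assessment`` set — the adult by
    default.
    """
    if not receptors:
        raise ValueError("receptor list is empty")
    if not isinstance(rba_map, RbaMap):
        rba_map = RbaMap(per_element=rba_map)
    out: list[RiskResult] = []
    for sample in samples:
        for receptor in receptors:
            res = RiskResult(sample.sample_id, receptor.name)
            if censored_convention != "half_lod":
                res.flags.add(f"censored_as_{censored_convention}")
            for element, meas in sample.measurements.items():
                info = registry.get(element)
                if info is None:
                    continue
                msoil = meas.resolved(censored_convention)
                if meas.censored:
                    res.flags.add("censored_substituted")
                rba, rba_flags = rba_map.get(sample.sample_id, element, registry)
                res.flags |= rba_flags
                res.rba[element] = rba
                res.cdi[element] = chemical_daily_intake(msoil, receptor)
                if element in HI_ELEMENTS:
                    if info.tdi is None:
                        res.flags.add(f"no_tdi_{element}")
                    else:
                        res.hq[element] = hazard_quotient(res.cdi[element], rba, info.tdi)
                if info.csf is not None and receptor.carcinogen_assessment:
                    cdi_carc = chemical_daily_intake(msoil, receptor, carcinogenic=True)
                    cr = cancer_risk(cdi_carc, info.csf, rba)
                    res.cr_as = cr if res.cr_as is None else res.cr_as + cr
            if res.hq:
                res.hi, _ = hazard_index(res.hq)
            res.hi_exceeds = res.hi > thresholds.hi_limit
            res.cr_exceeds = res.cr_as is not None and res.cr_as > thresholds.cr_limit
            out.append(res)
    return out


def risk_table(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Wide risk table: sample_id, receptor, HQ per element, HI, CR, flags."""
    elements = sorted({e for r in results for e in r.hq})
    rows = []
    for r in results:
        row: dict = {"sample_id": r.sample_id, "receptor": r.receptor}
        for e in elements:
            row[f"HQ_{e}"] = r.hq.get(e, math.nan)
        row["HI"] = r.hi
        row["CR_As"] = r.cr_as
        row["hi_exceeds"] = r.hi_exceeds
        row["cr_exceeds"] = r.cr_exceeds
        row["flags"] = ";".join(sorted(r.flags))
        rows.append(row)
    return pd.DataFrame(rows)
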