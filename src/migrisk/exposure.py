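"""Bioaccessibility-adjusted dietary exposure (EDI) and hazard quotients.

The estimated daily intake of a packaging additive through one food is

    EDI = V · C / BW                      (ng/kg bw/day)

with ``V`` the daily consumption of the food (kg/day), ``C`` the additive
concentration in the food (ng/kg) and ``BW`` body weight (kg).  When the
food concentration originates from packaging migration, ``C`` is expressed
through the packaging content ``C_p`` (µg/g), the packaging mass per kg
food ``m_p`` (g/kg) and the final migration ratio ``MR_f`` (%), and the
intake is scaled by the bioaccessible fraction ``BA`` (%):

    EDI = V · C_p · (MR_f/100) · m_p · 10³ / BW · (BA/100)

Risk is screened through the hazard quotient HQ = EDI/RfD; HQ < 1 denotes
acceptable risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

__all__ = [
    "DEFAULT_RFD_NG_KG_BW_DAY",
    "DEFAULT_BODY_WEIGHT_KG",
    "RfDRegistry",
    "ConsumptionScenario",
    "PackagingAssumption",
    "ExposureResult",
    "edi_concentration",
    "edi_from_migration",
    "hazard_quotient",
    "is_acceptable",
    "assess_exposure",
    "risk_summary",
]

#: oral reference doses (ng/kg bw/day) for the five flame retardants assessed
DEFAULT_RFD_NG_KG_BW_DAY: dict[str, float] = {
    "TPhP": 70_000.0,
    "EHDPP": 6_000.0,
    "TBOEP": 15_000.0,
    "TnBP": 10_000.0,
    "TPPO": 20_000.0,
}

DEFAULT_BODY_WEIGHT_KG = 60.0


class RfDRegistry:
    """Per-compound oral reference doses (ng/kg bw/day)."""

    def __init__(self, rfd: Mapping[str, float] | None = None) -> None:
        table = dict(DEFAULT_RFD_NG_KG_BW_DAY if rfd is None else rfd)
        for compound, value in table.items():
            if not value > 0:
                raise ValueError(f"RfD for {compound} must be positive, got {value!r}")
        self._table = table

    def __contains__(self, compound: str) -> bool:
        return compound in self._table

    def __getitem__(self, compound: str) -> float:
        try:
            return self._table[compound]
        except KeyError:
            raise KeyError(
                f"no reference dose registered for compound {compound!r}"
            ) from None

    def compounds(self) -> tuple[str, ...]:
        return tuple(self._table)


@dataclass(frozen=True)
class ConsumptionScenario:
    """Per-food daily intake (kg/day) for one consumption scenario."""

    scenario: Literal["median", "p95"]
    intake_kg_day: Mapping[str, float] = field(default_factory=dict)
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise ValueError("body weight must be positive")
        for food, v in self.intake_kg_day.items():
            if v < 0:
                raise ValueError(f"intake for {food} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class PackagingAssumption:
    """Additive content and packaging mass assumptions behind C in Eq. for EDI."""

    c_p_ug_g: float = 100.0  # additive content in packaging, µg/g (0.1 g/kg)
    m_p_g_kg: float = 4.0    # packaging mass in contact per kg food, g/kg

    def __post_init__(self) -> None:
        if not self.c_p_ug_g > 0 or not self.m_p_g_kg > 0:
            raise ValueError("packaging assumptions must be positive")


def edi_concentration(v_kg_day: float, c_ng_kg: float, bw_kg: float) -> float:
    """EDI = V·C/BW (ng/kg bw/day) from a known food concentration."""
    if not bw_kg > 0:
        raise ValueError(f"body weight must be positive, got {bw_kg!r}")
    if v_kg_day < 0:
        raise ValueError(f"consumption must be non-negative, got {v_kg_day!r}")
    return v_kg_day * c_ng_kg / bw_kg


def edi_from_migration(
    v_kg_day: float,
    pack: PackagingAssumption,
    mr_f_percent: float,
    ba_percent: float,
    bw_kg: float = DEFAULT_BODY_WEIGHT_KG,
) -> float:
    """Migration- and bioaccessibility-based EDI (ng/kg bw/day).

    The food concentration is C = C_p·(MR_f/100)·m_p in µg/kg, i.e.
    ×10³ ng/kg; the bioaccessible fraction BA/100 scales the intake.
    Bilinear in MR_f and BA.
    """
    if mr_f_percent < 0 or ba_percent < 0:
        raise ValueError("MR_f and BA percentages must be non-negative")
    c_ng_kg = pack.c_p_ug_g * (mr_f_percent / 100.0) * pack.m_p_g_kg * 1.0e3
    return edi_concentration(v_kg_day, c_ng_kg, bw_kg) * (ba_percent / 100.0)


def hazard_quotient(edi_ng_kg_bw_day: float, rfd_ng_kg_bw_day: float) -> float:
    """HQ = EDI/RfD (dimensionless)."""
    if not rfd_ng_kg_bw_day > 0:
        raise ValueError(f"RfD must be positive, got {rfd_ng_kg_bw_day!r}")
    if edi_ng_kg_bw_day < 0:
        raise ValueError(f"EDI must be non-negative, got {edi_ng_kg_bw_day!r}")
    return edi_ng_kg_bw_day / rfd_ng_kg_bw_day


def is_acceptable(hq: float) -> bool:
    """Risk classification: acceptable iff HQ < 1 (boundary not acceptable)."""
    return hq < 1.0


@dataclass(frozen=True)
class ExposureResult:
    """EDI and HQ for one compound × food × scenario."""

    compound: str
    food: str
    scenario: str
    mr_f_percent: float
    ba_percent: float
    edi_ng_kg_bw_day: float
    hq: float

    @property
    def acceptable(self) -> bool:
        return is_acceptable(self.hq)


def assess_exposure(
    mr_f: Mapping[tuple[str, str], float],
    ba: Mapping[tuple[str, str], float],
    scenarios: Iterable[ConsumptionScenario],
    rfd: RfDRegistry | None = None,
    pack: PackagingAssumption | None = None,
) -> list[ExposureResult]:
    """Join migration, bioaccessibility, consumption and RfDs into EDI/HQ.

    ``mr_f`` and ``ba`` map (food, compound) to the final migration ratio
    and bioaccessibility in percent.  Every (food, compound) pair present
    in ``mr_f`` is assessed for every scenario food it appears under.
    """
    registry = rfd if rfd is not None else RfDRegistry()
    packaging = pack if pack is not None else PackagingAssumption()
    results = []
    for scenario in scenarios:
        for (food, compound), mr_value in sorted(mr_f.items()):
            if food not in scenario.intake_kg_day:
                continue
            if compound not in registry:
                raise KeyError(
                    f"no reference dose registered for compound {compound!r}"
                )
            ba_value = ba[(food, compound)]
            edi = edi_from_migration(
                scenario.intake_kg_day[food],
                packaging,
                mr_value,
                ba_value,
                scenario.body_weight_kg,
            )
            results.append(
                ExposureResult(
                    compound=compound,
                    food=food,
                    scenario=scenario.scenario,
                    mr_f_percent=mr_value,
                    ba_percent=ba_value,
                    edi_ng_kg_bw_day=edi,
                    hq=hazard_quotient(edi, registry[compound]),
                )
            )
    return results


def risk_summary(results: Iterable[ExposureResult]) -> dict:
    """Ranked risk report over a set of exposure results.

    Returns per-compound HQ maxima (over foods × scenarios), per-food EDI
    rankings and the rows flagged with HQ ≥ 1.
    """
    rows = list(results)
    if not rows:
        raise ValueError("risk_summary requires at least one exposure result")
    df = pd.DataFrame(
        {
            "compound": [r.compound for r in rows],
            "food": [r.food for r in rows],
            "scenario": [r.scenario for r in rows],
            "edi": [r.edi_ng_kg_bw_day for r in rows],
            "hq": [r.hq for r in rows],
        }
    )
    max_hq = df.groupby("compound")["hq"].max().to_dict()
    rankings = {
        (food, scenario): group.sort_values("edi", ascending=False)["compound"].tolist()
        for (food, scenario), group in df.groupby(["food", "scenario"])
    }
    flags = [
        (r.compound, r.food, r.scenario, r.hq) for r in rows if not r.acceptable
    ]
    return {"max_hq_per_compound": max_hq, "edi_ranking": rankings, "flags": flags}


def results_to_frame(results: Iterable[ExposureResult]) -> pd.DataFrame:
    """Tabulate exposure results (food × compound × scenario → EDI, HQ)."""
    rows = list(results)
    return pd.DataFrame(
        {
            "food": [r.food for r in rows],
            "scenario": [r.scenario for r in rows],
            "compound": [r.compound for r in rows],
            "mr_f_percent": [r.mr_f_percent for r in rows],
            "ba_percent": [r.ba_percent for r in rows],
            "edi_ng_kg_bw_day": [r.edi_ng_kg_bw_day for r in rows],
            "hq": [r.hq for r in rows],
            "acceptable": [r.acceptable for r in rows],
        }
    )
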