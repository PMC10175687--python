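"""Declarative dosing-regimen specifications and their expansion to dose events.

A regimen is described the way dosing tables in the clinical literature are
laid out: a per-day rule (dose in mg/kg and dosing interval) for days 1-3 and
a maintenance rule from day 4 onward, applied to a patient of a given body
weight. ``build_events`` expands this into concrete infusion events on the
simulation horizon (default 264 h, i.e. 11 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .pk import DoseEvent

__all__ = ["DayRule", "RegimenSpec", "build_events", "read_regimens", "write_regimens",
           "recommend_regimen", "RECOMMENDED"]

_ALLOWED_INTERVALS = (12, 24, 48, 72)


@dataclass(frozen=True)
class DayRule:
    """Dose rule for one day: unit dose (mg/kg) given every ``interval`` hours."""

    dose_mg_kg: float
    interval_h: int

    def __post_init__(self) -> None:
        if self.dose_mg_kg < 0:
            raise ValueError("dose must be >= 0 mg/kg")
        if self.interval_h not in _ALLOWED_INTERVALS:
            raise ValueError(
                f"interval must be one of {_ALLOWED_INTERVALS} h, got {self.interval_h}"
            )


@dataclass(frozen=True)
class RegimenSpec:
    """Day 1-3 rules plus a maintenance rule from day 4, for one patient.

    Doses are exact mg/kg * weight by default (975 mg for 15 mg/kg at 65 kg);
    ``rounded_amounts`` switches to the clinically rounded 1,000/800 mg style
    (nearest 100 mg).
    """

    day1: DayRule
    day2: DayRule
    day3: DayRule
    maintenance: DayRule
    weight_kg: float = 65.0
    infusion_duration_h: float = 1.0
    horizon_h: float = 264.0
    rounded_amounts: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0 kg")
        if self.infusion_duration_h <= 0:
            raise ValueError("infusion duration must be > 0 h")
        if self.maintenance.interval_h not in (24, 48, 72):
            raise ValueError("maintenance interval must be 24, 48 or 72 h")

    def with_weight(self, weight_kg: float) -> "RegimenSpec":
        return replace(self, weight_kg=weight_kg)

    def _amount(self, dose_mg_kg: float) -> float:
        amt = dose_mg_kg * self.weight_kg
        if self.rounded_amounts:
            amt = round(amt / 100.0) * 100.0
        return amt


def build_events(spec: RegimenSpec) -> list[DoseEvent]:
    """Expand a regimen spec into timed infusion events.

    Day-d rules cover [24(d-1), 24d) h for d = 1..3; the maintenance rule
    runs from 72 h at its own interval. Only doses starting strictly before
    the horizon are emitted.
    """
    events: list[DoseEvent] = []

    def emit(t: float, dose_mg_kg: float) -> None:
        if t < spec.horizon_h and dose_mg_kg > 0:
            events.append(
                DoseEvent(start=float(t), amount=spec._amount(dose_mg_kg),
                          duration=spec.infusion_duration_h)
            )

    for day_idx, rule in enumerate((spec.day1, spec.day2, spec.day3)):
        t = 24.0 * day_idx
        while t < 24.0 * (day_idx + 1):
            emit(t, rule.dose_mg_kg)
            t += rule.interval_h
    t = 72.0
    while t < spec.horizon_h:
        emit(t, spec.maintenance.dose_mg_kg)
        t += spec.maintenance.interval_h
    return events


_REGIMEN_COLUMNS = [
    "label", "day1_dose", "day1_interval", "day2_dose", "day2_interval",
    "day3_dose", "day3_interval", "maint_dose", "maint_interval",
    "weight_kg", "infusion_duration_h",
]


def read_regimens(path) -> list[RegimenSpec]:
    """Read regimen specs from a CSV with one regimen per row (doses mg/kg)."""
    df = pd.read_csv(path)
    missing = [c for c in _REGIMEN_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise ValueError(f"regimen file {path} is missing columns: {missing}")
    specs = []
    for _, row in df.iterrows():
        specs.append(
            RegimenSpec(
                day1=DayRule(float(row.day1_dose), int(row.day1_interval)),
                day2=DayRule(float(row.day2_dose), int(row.day2_interval)),
                day3=DayRule(float(row.day3_dose), int(row.day3_interval)),
                maintenance=DayRule(float(row.maint_dose), int(row.maint_interval)),
                weight_kg=float(row.weight_kg),
                infusion_duration_h=float(row.infusion_duration_h),
                label=str(row.get("label", "")),
            )
        )
    return specs


def write_regimens(specs: list[RegimenSpec], path) -> None:
    rows = []
    for s in specs:
        rows.append({
            "label": s.label,
            "day1_dose": s.day1.dose_mg_kg, "day1_interval": s.day1.interval_h,
            "day2_dose": s.day2.dose_mg_kg, "day2_interval": s.day2.interval_h,
            "day3_dose": s.day3.dose_mg_kg, "day3_interval": s.day3.interval_h,
            "maint_dose": s.maintenance.dose_mg_kg, "maint_interval": s.maintenance.interval_h,
            "weight_kg": s.weight_kg, "infusion_duration_h": s.infusion_duration_h,
        })
    pd.DataFrame(rows, columns=_REGIMEN_COLUMNS).to_csv(path, index=False)


# Recommended regimens by renal-function stratum: intensified loading then a
# maintenance interval stretched with decreasing GFR.
RECOMMENDED = {
    "gfr>=90": RegimenSpec(
        day1=DayRule(15, 12), day2=DayRule(15, 12), day3=DayRule(15, 24),
        maintenance=DayRule(15, 24), label="15 mg/kg q12h x5 then 15 mg/kg q24h",
    ),
    "30<=gfr<90": RegimenSpec(
        day1=DayRule(15, 12), day2=DayRule(15, 24), day3=DayRule(15, 24),
        maintenance=DayRule(15, 48), label="15 mg/kg q12h x3, 15 mg/kg q24h d2-3, then 15 mg/kg q48h",
    ),
    "gfr<30": RegimenSpec(
        day1=DayRule(12, 12), day2=DayRule(12, 24), day3=DayRule(12, 24),
        maintenance=DayRule(12, 72), label="12 mg/kg q12h x3, 12 mg/kg q24h d2-3, then 12 mg/kg q72h",
    ),
}


def recommend_regimen(gfr: float, weight_kg: float = 65.0) -> RegimenSpec:
    """Recommended regimen for a renal-function stratum (GFR in mL/min/1.73 m^2)."""
    if gfr <= 0:
        raise ValueError("GFR must be > 0")
    if gfr >= 90:
        spec = RECOMMENDED["gfr>=90"]
    elif gfr >= 30:
        spec = RECOMMENDED["30<=gfr<90"]
    else:
        spec = RECOMMENDED["gfr<30"]
    return spec.with_weight(weight_kg)
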