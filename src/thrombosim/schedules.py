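"""Therapy schedules: chemotherapy cycles, peg-TPO injections, transfusions.

Times are accepted in days at the I/O boundary and converted to hours
internally.  Built-in schedules cover the CHOP/CHOEP regimens with 14- or
21-day cycles (6 cycles by default): cyclophosphamide 750 and doxorubicin
50 mg/m^2 on day 1 of each cycle, plus etoposide 3 x 100 mg/m^2 on days 1-3
for the CHOEP variants.  Vincristine and prednisone carry no relevant
haematotoxicity and are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .chemo import Drug, DrugDose

__all__ = ["ChemoDoseEvent", "PegTPOEvent", "TransfusionEvent",
           "TherapySchedule", "built_in_schedule", "BUILT_IN_SCHEDULES"]


@dataclass(frozen=True)
class ChemoDoseEvent:
    drug: Drug
    amount: float          # mg/m^2
    day: float
    infusion_hours: float = 0.0

    def as_dose(self) -> DrugDose:
        return DrugDose(self.drug, self.amount, 24.0 * self.day,
                        self.infusion_hours)


@dataclass(frozen=True)
class PegTPOEvent:
    dose_ug_per_kg: float
    day: float


@dataclass(frozen=True)
class TransfusionEvent:
    amount: float          # platelet increment, 1e9/L
    day: float


@dataclass
class TherapySchedule:
    events: list = field(default_factory=list)
    cycle_starts: list = field(default_factory=list)  # days, for nadir analysis
    name: str = ""

    def __post_init__(self):
        for ev in self.events:
            if ev.day < 0:
                raise ValueError("event times must be nonnegative")
        self.events = sorted(self.events, key=lambda e: e.day)
        self.cycle_starts = sorted(self.cycle_starts)

    @property
    def last_event_day(self) -> float:
        return max((e.day for e in self.events), default=0.0)

    def chemo_doses(self) -> list[DrugDose]:
        return [e.as_dose() for e in self.events
                if isinstance(e, ChemoDoseEvent)]

    def shift_last_cycle(self, shift) -> "TherapySchedule":
        """Shift the last chemotherapy cycle by ``shift`` days or drop it
        (``shift='omit'``)."""
        if len(self.cycle_starts) < 2:
            raise ValueError("need at least two cycles to shift the last one")
        last = self.cycle_starts[-1]
        penult = self.cycle_starts[-2]
        in_last = lambda e: isinstance(e, ChemoDoseEvent) and e.day >= last
        if shift == "omit":
            events = [e for e in self.events if not in_last(e)]
            return TherapySchedule(events, self.cycle_starts[:-1],
                                   name=f"{self.name}(omit last)")
        shift = float(shift)
        if last + shift <= penult:
            raise ValueError("shift would reorder the cycles")
        events = [replace(e, day=e.day + shift) if in_last(e) else e
                  for e in self.events]
        return TherapySchedule(events, self.cycle_starts[:-1] + [last + shift],
                               name=f"{self.name}(shift {shift:+g} d)")

    # -- serialization ------------------------------------------------------
    def to_frame(self, patient_id: str = "") -> pd.DataFrame:
        rows = []
        for e in self.events:
            if isinstance(e, ChemoDoseEvent):
                rows.append(dict(patient_id=patient_id, event_type="chemo",
                                 drug=e.drug.value, dose=e.amount, day=e.day,
                                 infusion_hours=e.infusion_hours))
            elif isinstance(e, PegTPOEvent):
                rows.append(dict(patient_id=patient_id, event_type="peg_tpo",
                                 drug="", dose=e.dose_ug_per_kg, day=e.day,
                                 infusion_hours=0.0))
            elif isinstance(e, TransfusionEvent):
                rows.append(dict(patient_id=patient_id,
                                 event_type="transfusion", drug="",
                                 dose=e.amount, day=e.day, infusion_hours=0.0))
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "",
                   cycle_starts=None) -> "TherapySchedule":
        events = []
        for _, row in frame.iterrows():
            kind = row["event_type"]
            if kind == "chemo":
                events.append(ChemoDoseEvent(
                    Drug(row["drug"]), float(row["dose"]), float(row["day"]),
                    float(row.get("infusion_hours", 0.0) or 0.0)))
            elif kind == "peg_tpo":
                events.append(PegTPOEvent(float(row["dose"]),
                                          float(row["day"])))
            elif kind == "transfusion":
                events.append(TransfusionEvent(float(row["dose"]),
                                               float(row["day"])))
            else:
                raise ValueError(f"unknown event_type {kind!r}")
        if cycle_starts is None:
            cycle_starts = sorted({e.day for e in events
                                   if isinstance(e, ChemoDoseEvent)})
        return cls(events, list(cycle_starts), name=name)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "TherapySchedule":
        return cls.from_frame(pd.read_csv(path), name=name or str(path))


def built_in_schedule(name: str, n_cycles: int = 6,
                      start_day: float = 0.0) -> TherapySchedule:
    """One of CHOP-14, CHOP-21, CHOEP-14, CHOEP-21."""
    key = name.upper().replace("_", "-")
    if key not in BUILT_IN_SCHEDULES:
        raise KeyError(f"unknown schedule {name!r}; "
                       f"choose from {sorted(BUILT_IN_SCHEDULES)}")
    etoposide, cycle_days = BUILT_IN_SCHEDULES[key]
    events, starts = [], []
    for c in range(n_cycles):
        day = start_day + c * cycle_days
        starts.append(day)
        events.append(ChemoDoseEvent(Drug.CYCLOPHOSPHAMIDE, 750.0, day))
        events.append(ChemoDoseEvent(Drug.DOXORUBICIN, 50.0, day))
        if etoposide:
            for d in range(3):
                events.append(ChemoDoseEvent(Drug.ETOPOSIDE, 100.0, day + d,
                                             infusion_hours=1.0))
    return TherapySchedule(events, starts, name=key)


#: name -> (has etoposide, cycle length in days)
BUILT_IN_SCHEDULES = {
    "CHOP-14": (False, 14.0), "CHOP-21": (False, 21.0),
    "CHOEP-14": (True, 14.0), "CHOEP-21": (True, 21.0),
}
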