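"""Dose-event schedule representation, JSON I/O, and the built-in library.

A :class:`Schedule` is a sorted list of timed dose events over one cycle
(default 21 days = 504 h), repeated back-to-back out to a treatment horizon.
The built-in library encodes the ten clinically motivated schedules A-J used
for the monotherapy/combination comparison: A is standard erlotinib
monotherapy (150 mg daily), B and C are the two maximum-tolerated
evofosfamide monotherapies (670 mg/m^2 every 3 weeks; 575 mg/m^2 weekly),
and D-J combine the two drugs in various sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

ERLOTINIB = "erlotinib"
EVOFOSFAMIDE = "evofosfamide"
DRUGS = (ERLOTINIB, EVOFOSFAMIDE)

HOURS_PER_DAY = 24.0
CYCLE_HOURS = 504.0  # 21 days


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A single administration: time (hours from cycle start), drug, dose.

    Erlotinib doses are in mg; evofosfamide doses are in mg/m^2.
    """

    time: float
    drug: str = field(compare=False)
    dose: float = field(compare=False)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")


@dataclass(frozen=True)
class Schedule:
    """A repeating cycle of dose events.

    ``events`` holds one cycle; :meth:`expand` unrolls the cycle to a horizon.
    """

    events: tuple[DoseEvent, ...]
    cycle_hours: float = CYCLE_HOURS
    label: str = ""

    def __post_init__(self):
        ev = tuple(sorted(self.events))
        object.__setattr__(self, "events", ev)
        if self.cycle_hours <= 0:
            raise ValueError("cycle_hours must be positive")
        if ev and ev[-1].time >= self.cycle_hours:
            raise ValueError("all events must fall within one cycle")

    def drug_events(self, drug: str) -> tuple[DoseEvent, ...]:
        return tuple(e for e in self.events if e.drug == drug)

    def expand(self, horizon: float) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Unroll the repeating cycle over ``[0, horizon)``.

        Returns (times, doses, drugs) sorted by time.
        """
        times, doses, drugs = [], [], []
        n_cycles = int(np.ceil(horizon / self.cycle_hours))
        for k in range(n_cycles):
            base = k * self.cycle_hours
            for e in self.events:
                t = base + e.time
                if t < horizon:
                    times.append(t)
                    doses.append(e.dose)
                    drugs.append(e.drug)
        order = np.argsort(times, kind="stable")
        return (
            np.asarray(times, dtype=float)[order],
            np.asarray(doses, dtype=float)[order],
            [drugs[i] for i in order],
        )

    def expand_drug(self, drug: str, horizon: float) -> tuple[np.ndarray, np.ndarray]:
        times, doses, drugs = self.expand(horizon)
        mask = np.array([d == drug for d in drugs], dtype=bool)
        return times[mask], doses[mask]

    def with_label(self, label: str) -> "Schedule":
        return replace(self, label=label)

    # -- JSON dialect -------------------------------------------------------

    def to_dict(self, repeats: int = 1) -> dict:
        return {
            "label": self.label,
            "cycle_hours": self.cycle_hours,
            "repeats": repeats,
            "events": [
                {"t_h": e.time, "drug": e.drug, "dose": e.dose} for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Schedule":
        events = tuple(
            DoseEvent(time=float(e["t_h"]), drug=str(e["drug"]), dose=float(e["dose"]))
            for e in d["events"]
        )
        return cls(
            events=events,
            cycle_hours=float(d.get("cycle_hours", CYCLE_HOURS)),
            label=str(d.get("label", "")),
        )

    def to_json(self, path, repeats: int = 1) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(repeats), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Schedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def daily_events(drug: str, dose: float, days: Iterable[int], hour: float = 0.0):
    """Dose events at a fixed clock hour on the given 1-based cycle days."""
    return [
        DoseEvent(time=(day - 1) * HOURS_PER_DAY + hour, drug=drug, dose=dose)
        for day in days
    ]


def table3_schedules() -> dict[str, Schedule]:
    """The built-in library of comparison schedules A-J (one 21-day cycle).

    Daily doses default to hour 0 of each day; twice-daily doses to hours 0
    and 12.  On days with both drugs, both are placed at hour 0.
    """
    E, V = ERLOTINIB, EVOFOSFAMIDE
    all_days = range(1, 22)
    sched = {}
    sched["A"] = Schedule(tuple(daily_events(E, 150, all_days)), label="A")
    sched["B"] = Schedule(tuple(daily_events(V, 670, [1])), label="B")
    sched["C"] = Schedule(tuple(daily_events(V, 575, [1, 8, 15])), label="C")
    sched["D"] = Schedule(
        tuple(daily_events(E, 150, range(1, 20)) + daily_events(V, 670, [21])),
        label="D",
    )
    sched["E"] = Schedule(
        tuple(
            daily_events(E, 150, [1, 2, 3, 4, 5, 8, 9, 10, 11, 12, 15, 16, 17, 18, 19])
            + daily_events(V, 575, [7, 14, 21])
        ),
        label="E",
    )
    sched["F"] = Schedule(
        tuple(
            daily_events(E, 7, range(1, 20), hour=0.0)
            + daily_events(E, 7, range(1, 20), hour=12.0)
            + daily_events(E, 7, [20], hour=0.0)
            + daily_events(V, 670, [21])
        ),
        label="F",
    )
    g_days = [d for d in all_days if d not in (7, 14, 21)]
    sched["G"] = Schedule(
        tuple(
            daily_events(E, 7, g_days, hour=0.0)
            + daily_events(E, 7, g_days, hour=12.0)
            + daily_events(V, 575, [7, 14, 21])
        ),
        label="G",
    )
    sched["H"] = Schedule(
        tuple(daily_events(E, 150, range(1, 21)) + daily_events(V, 670, [21])),
        label="H",
    )
    i_days = [d for d in all_days if d not in (7, 14, 21)]
    sched["I"] = Schedule(
        tuple(daily_events(E, 150, i_days) + daily_events(V, 575, [7, 14, 21])),
        label="I",
    )
    sched["J"] = Schedule(
        tuple(daily_events(E, 150, all_days) + daily_events(V, 145, all_days)),
        label="J",
    )
    return sched
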