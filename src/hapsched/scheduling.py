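"""Combination-cycle construction and grid optimization over dose density.

Optimized combination schedules are built per *class* from a base erlotinib
regimen plus ``n`` evofosfamide doses per 21-day period (n = 0 is erlotinib
monotherapy, n = N evofosfamide monotherapy).  One cycle of length
``L = 504/n`` hours is assembled in four steps:

(i)   the evofosfamide dose is the MTD-curve value at frequency n, floored
      to an integer mg/m^2;
(ii)  the evofosfamide infusion is placed ``evo_offset`` hours before the end
      of the cycle (24 h for classes 1-2, 6 h for class 3);
(iii) the remaining time is filled with the base erlotinib schedule
      (150 mg daily for classes 1 and 3; 7 mg twice daily for class 2),
      keeping the base inter-dose spacing across the cycle boundary;
(iv)  trailing erlotinib doses are removed, latest-first, until the
      steady-state erlotinib concentration at the evofosfamide instant falls
      to the combination threshold.

The resulting cycles are repeated to the horizon, verified against both
toxicity checks, and scored with the analytic dynamics engine; optimization
is a plain grid search over n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import DynamicsResult, conditional_burden, evaluate_schedule, recurrence_time
from .microenvironment import CompartmentModel
from .pharmacokinetics import min_physical_evo_dose
from .rate_models import RateModel
from .schedule import ERLOTINIB, EVOFOSFAMIDE, CYCLE_HOURS, DoseEvent, Schedule, table3_schedules
from .toxicity import (
    DEFAULT_RULES,
    ToxicityRuleSet,
    check_combination_gaps,
    check_monotherapy,
    evofosfamide_mtd,
    steady_state_erlotinib_at,
)

__all__ = [
    "ClassSpec",
    "CLASS_SPECS",
    "table3_schedules",
    "build_cycle",
    "n_max",
    "erlotinib_monotherapy",
    "evofosfamide_monotherapy",
    "evaluate_class_grid",
    "optimize",
    "optimize_all",
    "compare_endpoints",
    "NINE_WEEKS",
]

NINE_WEEKS = 1512.0  # hours


def _floor_dose(x: float) -> float:
    """Floor to an integer dose, absorbing printed-coefficient rounding.

    The MTD curve evaluates to e.g. 574.9998 at weekly frequency where the
    printed tolerated dose is 575; a 1e-3 cushion keeps such values intact
    while 145.2 still floors to 145.
    """
    return float(math.floor(x + 1e-3))


@dataclass(frozen=True)
class ClassSpec:
    """One optimization class: a base erlotinib regimen + evofosfamide offset."""

    class_id: int
    base_doses: tuple[tuple[float, float], ...]  # (hour within day, mg)
    base_period: float  # hours between consecutive base doses' pattern repeats
    evo_offset: float  # evofosfamide placed at L - evo_offset

    @property
    def label(self) -> str:
        return f"class{self.class_id}"


CLASS_SPECS = {
    1: ClassSpec(1, ((0.0, 150.0),), 24.0, 24.0),
    2: ClassSpec(2, ((0.0, 7.0), (12.0, 7.0)), 12.0, 24.0),
    3: ClassSpec(3, ((0.0, 150.0),), 24.0, 6.0),
}


def n_max(
    class_spec: ClassSpec,
    rules: ToxicityRuleSet = DEFAULT_RULES,
    min_cycle_hours: float | None = None,
) -> int:
    """Largest feasible evofosfamide dose count N per 21-day period.

    Default minimum cycle length is 24 h for the 24-h-offset classes and
    12 h for class 3; N is additionally capped so the floored MTD dose stays
    in the range where the evofosfamide PK fits are physical.
    """
    if min_cycle_hours is None:
        min_cycle_hours = 24.0 if class_spec.evo_offset >= 24.0 else 12.0
    n_geo = int(math.floor(CYCLE_HOURS / min_cycle_hours))
    d_min = min_physical_evo_dose()
    n = n_geo
    while n >= 1 and _floor_dose(evofosfamide_mtd(n, rules)) < d_min:
        n -= 1
    if n < 1:
        raise ValueError("no feasible evofosfamide frequency for this class")
    return n


def _base_slot_times(class_spec: ClassSpec, L: float) -> list[float]:
    """Base erlotinib dose times within one cycle of length L.

    The base schedule repeats every 24 h; a slot is kept only if the base
    spacing to the start of the next cycle is respected (t + spacing <= L),
    so inter-dose gaps never shrink across the cycle boundary.
    """
    if len(class_spec.base_doses) == 1:
        spacing = 24.0
    else:
        hours = sorted(h for h, _ in class_spec.base_doses)
        spacing = min(np.diff(hours + [hours[0] + 24.0]))
    slots = []
    day = 0
    while True:
        base = 24.0 * day
        if base >= L:
            break
        for hour, dose in class_spec.base_doses:
            t = base + hour
            if t + spacing <= L + 1e-9:
                slots.append((t, dose))
        day += 1
    return slots


def build_cycle(
    class_spec: ClassSpec,
    n: int,
    rules: ToxicityRuleSet = DEFAULT_RULES,
) -> Schedule:
    """Construct one combination cycle (steps i-iv) for ``n`` evofosfamide
    doses per 21 days.  Deterministic; raises for infeasible ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1 (use erlotinib_monotherapy for n = 0)")
    L = CYCLE_HOURS / n
    if L < max(class_spec.evo_offset, rules.evo_to_erl_gap_hours) - 1e-9:
        raise ValueError(
            f"cycle of {L:g} h cannot accommodate the {class_spec.evo_offset:g} h "
            "evofosfamide offset"
        )
    evo_dose = _floor_dose(evofosfamide_mtd(n, rules))
    evo_time = L - class_spec.evo_offset

    erl = [
        (t, d)
        for t, d in _base_slot_times(class_spec, L)
        if not math.isclose(t, evo_time, abs_tol=1e-9)
    ]
    # drop erlotinib doses violating the 6 h rule after the evofosfamide dose
    erl = [
        (t, d)
        for t, d in erl
        if ((t - evo_time) % L if not math.isclose((t - evo_time) % L, 0.0, abs_tol=1e-9) else L)
        >= rules.evo_to_erl_gap_hours - 1e-9
    ]

    threshold = rules.erl_to_evo_threshold_uM * (1.0 + rules.threshold_rel_tol)

    def washout_ok(erl_events):
        sched = Schedule(
            events=tuple(
                [DoseEvent(t, ERLOTINIB, d) for t, d in erl_events]
                + [DoseEvent(evo_time, EVOFOSFAMIDE, evo_dose)]
            ),
            cycle_hours=L,
        )
        return steady_state_erlotinib_at(sched, evo_time) <= threshold, sched

    while True:
        ok, sched = washout_ok(erl)
        if ok or not erl:
            break
        # remove the latest erlotinib dose before the evofosfamide infusion
        # (periodic sense: smallest positive lag)
        lags = [
            ((evo_time - t) % L if (evo_time - t) % L > 1e-9 else L, j)
            for j, (t, _) in enumerate(erl)
        ]
        _, j_drop = min(lags)
        erl.pop(j_drop)
    if not ok:
        raise ValueError(f"no erlotinib arrangement satisfies the washout rule at n={n}")
    return sched.with_label(f"{class_spec.label}-n{n}")


def erlotinib_monotherapy(class_spec: ClassSpec) -> Schedule:
    """The class's base erlotinib schedule (the n = 0 grid endpoint)."""
    events = tuple(DoseEvent(h, ERLOTINIB, d) for h, d in class_spec.base_doses)
    return Schedule(events=events, cycle_hours=24.0, label=f"{class_spec.label}-n0")


def evofosfamide_monotherapy(
    class_spec: ClassSpec, n: int, rules: ToxicityRuleSet = DEFAULT_RULES
) -> Schedule:
    """Evofosfamide-only dosing at frequency n (the n = N grid endpoint)."""
    L = CYCLE_HOURS / n
    dose = _floor_dose(evofosfamide_mtd(n, rules))
    evo_time = max(L - class_spec.evo_offset, 0.0)
    return Schedule(
        events=(DoseEvent(evo_time, EVOFOSFAMIDE, dose),),
        cycle_hours=L,
        label=f"{class_spec.label}-n{n}-mono",
    )


def evaluate_class_grid(
    class_spec: ClassSpec,
    compartments: CompartmentModel,
    model: RateModel,
    n_range=None,
    horizon: float = NINE_WEEKS,
    rules: ToxicityRuleSet = DEFAULT_RULES,
    **eval_kw,
) -> pd.DataFrame:
    """Endpoint metrics at the horizon for every dose count n in the class.

    Row n = 0 is erlotinib monotherapy and n = N evofosfamide monotherapy.
    Every generated schedule must pass both toxicity checks before
    evaluation; a failure is a construction bug and raises.
    """
    N = n_max(class_spec, rules)
    if n_range is None:
        n_range = range(0, N + 1)
    rows = []
    for n in n_range:
        if n == 0:
            sched = erlotinib_monotherapy(class_spec)
        elif n >= N:
            sched = evofosfamide_monotherapy(class_spec, n, rules)
        else:
            sched = build_cycle(class_spec, n, rules)
            if not sched.drug_events(ERLOTINIB):
                sched = evofosfamide_monotherapy(class_spec, n, rules)
        mono = check_monotherapy(sched, rules)
        if not mono.tolerated:
            raise RuntimeError(f"constructed schedule n={n} fails monotherapy check: {mono}")
        if sched.drug_events(ERLOTINIB) and sched.drug_events(EVOFOSFAMIDE):
            combo = check_combination_gaps(sched, rules)
            if not combo.tolerated:
                raise RuntimeError(f"constructed schedule n={n} fails combination check: {combo}")
        res = evaluate_schedule(compartments, model, sched, horizon, **eval_kw)
        rows.append(
            {
                "n": n,
                "label": sched.label,
                "E_X": res.E_X[-1],
                "E_Y": res.E_Y[-1],
                "E_total": res.E_total[-1],
                "P": res.P[-1],
            }
        )
    return pd.DataFrame(rows)


OBJECTIVES = ("E_X", "E_Y", "E_total", "P")


def optimize(grid: pd.DataFrame, objective: str) -> tuple[int, float]:
    """Global grid minimizer of one endpoint; ties break toward smaller n.

    A full grid search is used deliberately: the endpoint profiles can have
    two local minima, which descent methods would not resolve.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    if grid.empty:
        raise ValueError("empty grid")
    g = grid.sort_values("n", kind="stable")
    k = int(np.argmin(g[objective].to_numpy()))
    return int(g["n"].iloc[k]), float(g[objective].iloc[k])


def optimize_all(grids: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-class and cross-class optimal n for every objective."""
    rows = []
    for cid, grid in grids.items():
        row = {"class": cid}
        for obj in OBJECTIVES:
            n_opt, val = optimize(grid, obj)
            row[f"n_{obj}"] = n_opt
            row[f"min_{obj}"] = val
        rows.append(row)
    df = pd.DataFrame(rows)
    best = {"class": "best"}
    for obj in OBJECTIVES:
        k = int(np.argmin(df[f"min_{obj}"].to_numpy()))
        best[f"n_{obj}"] = df[f"n_{obj}"].iloc[k]
        best[f"min_{obj}"] = df[f"min_{obj}"].iloc[k]
        best[f"class_{obj}"] = df["class"].iloc[k]
    return pd.concat([df, pd.DataFrame([best])], ignore_index=True)


def compare_endpoints(
    schedules: dict[str, Schedule],
    compartments: CompartmentModel,
    model: RateModel,
    horizon: float = NINE_WEEKS,
    reference: str | None = None,
    **eval_kw,
) -> pd.DataFrame:
    """Endpoint metrics plus recurrence timing for a set of schedules.

    ``recurrence_h`` is the first return of the mean tumor size to its
    initial value M after an initial decline (censored = NaN);
    ``cond_recurrence_h`` applies the same definition to the tumor size
    conditioned on resistance, E[X] + E[Y]/P.  ``delay_pct`` is the percent
    recurrence delay relative to the reference schedule (the first one by
    default), using the conditional recurrence when defined for both.
    """
    M = compartments.total_initial
    rows = []
    results: dict[str, DynamicsResult] = {}
    for label, sched in schedules.items():
        res = evaluate_schedule(compartments, model, sched, horizon, **eval_kw)
        results[label] = res
        cond = conditional_burden(res.E_X, res.E_Y, res.P)
        cond_rec = None
        if np.all(np.isfinite(cond[1:])):
            cond_rec = recurrence_time(res.times[1:], cond[1:], M)
        rows.append(
            {
                "label": label,
                "E_X": res.E_X[-1],
                "E_Y": res.E_Y[-1],
                "E_total": res.E_total[-1],
                "P": res.P[-1],
                "recurrence_h": res.recurrence_time if res.recurrence_time is not None else np.nan,
                "cond_recurrence_h": cond_rec if cond_rec is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    ref = reference if reference is not None else df["label"].iloc[0]
    ref_row = df[df["label"] == ref].iloc[0]

    def delay(row):
        for col in ("cond_recurrence_h", "recurrence_h"):
            a, b = row[col], ref_row[col]
            if np.isfinite(a) and np.isfinite(b) and b > 0:
                return 100.0 * (a - b) / b
        return np.nan

    df["delay_pct"] = df.apply(delay, axis=1)
    return df
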