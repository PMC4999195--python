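"""Maximum-tolerated-dose curves and combination-therapy gap rules.

Monotherapy tolerability is encoded as a dose-versus-frequency constraint
curve per drug: for ``n`` administrations per 21-day period the maximum
tolerated per-dose amount is

* erlotinib:    D1(n) = 2000 mg for n <= 3, else 2000*exp(-0.1439*(n-3))
* evofosfamide: D2(n) = 670 mg/m^2 for n <= 1, else 670*exp(-0.076454*(n-1))

Points on or below a curve are tolerated; points above are dose-limiting.
For combinations two additional rules apply: an erlotinib dose may follow an
evofosfamide dose only after >= 6 h, and an evofosfamide dose may only be
given once the erlotinib plasma concentration has fallen to 2.357 uM or lower
(evaluated at periodic steady state of the repeating schedule, with a 1%
relative tolerance absorbing printed-value rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .pharmacokinetics import (
    DEFAULT_ERLOTINIB_PK,
    ErlotinibPK,
    erlotinib_periodic_concentration,
    ng_per_ml_to_uM,
)
from .schedule import ERLOTINIB, EVOFOSFAMIDE, Schedule

WINDOW_HOURS = 504.0  # 21 days


@dataclass(frozen=True)
class ToxicityRuleSet:
    """All tolerability constants for the erlotinib/evofosfamide pair."""

    erlotinib_plateau: float = 2000.0  # mg, n <= erlotinib_knee
    erlotinib_knee: int = 3
    erlotinib_decay: float = 0.1439
    evofosfamide_plateau: float = 670.0  # mg/m^2, n <= evofosfamide_knee
    evofosfamide_knee: int = 1
    evofosfamide_decay: float = 0.076454
    window_hours: float = WINDOW_HOURS
    evo_to_erl_gap_hours: float = 6.0
    erl_to_evo_threshold_uM: float = 2.357
    threshold_rel_tol: float = 0.01


DEFAULT_RULES = ToxicityRuleSet()


@dataclass(frozen=True)
class Violation:
    rule: str
    where: str
    detail: str


@dataclass(frozen=True)
class ToxicityReport:
    violations: tuple[Violation, ...] = ()

    @property
    def verdict(self) -> str:
        return "tolerated" if not self.violations else "violation"

    @property
    def tolerated(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.tolerated:
            return "tolerated"
        lines = ["violation:"]
        lines += [f"  [{v.rule}] {v.where}: {v.detail}" for v in self.violations]
        return "\n".join(lines)


def erlotinib_mtd(n: float, rules: ToxicityRuleSet = DEFAULT_RULES) -> float:
    """Maximum tolerated erlotinib dose (mg) at n doses per 21 days."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n <= rules.erlotinib_knee:
        return rules.erlotinib_plateau
    return rules.erlotinib_plateau * math.exp(-rules.erlotinib_decay * (n - rules.erlotinib_knee))


def evofosfamide_mtd(n: float, rules: ToxicityRuleSet = DEFAULT_RULES) -> float:
    """Maximum tolerated evofosfamide dose (mg/m^2) at n doses per 21 days."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n <= rules.evofosfamide_knee:
        return rules.evofosfamide_plateau
    return rules.evofosfamide_plateau * math.exp(
        -rules.evofosfamide_decay * (n - rules.evofosfamide_knee)
    )


def classify_point(
    drug: str, n: float, dose: float, rules: ToxicityRuleSet = DEFAULT_RULES
) -> str:
    """Classify a (frequency, dose) point as 'below', 'on' or 'above' the curve.

    'on' uses a relative tolerance (default 1%) to absorb printed rounding.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if drug == ERLOTINIB:
        curve = erlotinib_mtd(n, rules)
    elif drug == EVOFOSFAMIDE:
        curve = evofosfamide_mtd(n, rules)
    else:
        raise ValueError(f"unknown drug {drug!r}")
    if abs(dose - curve) <= rules.threshold_rel_tol * curve:
        return "on"
    return "below" if dose < curve else "above"


def check_monotherapy(
    schedule: Schedule, rules: ToxicityRuleSet = DEFAULT_RULES
) -> ToxicityReport:
    """Check each drug's dose count and amount against its MTD curve.

    Doses are counted in 21-day windows aligned to the schedule's cycle start;
    if several per-dose amounts occur for one drug in a window, the maximum is
    tested (conservative).  The first two windows of the repeating schedule
    are examined (they differ only when the cycle length does not divide the
    window).
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    violations: list[Violation] = []
    horizon = 2 * rules.window_hours
    times, doses, drugs = schedule.expand(horizon)
    for w in range(2):
        lo, hi = w * rules.window_hours, (w + 1) * rules.window_hours
        in_win = (times >= lo) & (times < hi)
        for drug in (ERLOTINIB, EVOFOSFAMIDE):
            mask = in_win & np.array([d == drug for d in drugs])
            n = int(mask.sum())
            if n == 0:
                continue
            amount = float(np.max(doses[mask]))
            if classify_point(drug, n, amount, rules) == "above":
                curve = (
                    erlotinib_mtd(n, rules)
                    if drug == ERLOTINIB
                    else evofosfamide_mtd(n, rules)
                )
                violations.append(
                    Violation(
                        rule="monotherapy_mtd",
                        where=f"window {w + 1} ({lo:g}-{hi:g} h)",
                        detail=(
                            f"{drug}: {n} doses of up to {amount:g} exceed the "
                            f"MTD curve value {curve:.1f}"
                        ),
                    )
                )
        if w == 0 and np.isclose(
            schedule.cycle_hours % rules.window_hours
            if schedule.cycle_hours > rules.window_hours
            else rules.window_hours % schedule.cycle_hours,
            0.0,
            atol=1e-9,
        ):
            break  # second window identical to the first
    # deduplicate identical window findings
    return ToxicityReport(tuple(dict.fromkeys(violations)))


def steady_state_erlotinib_at(
    schedule: Schedule, query_time: float, pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK
) -> float:
    """Steady-state erlotinib concentration (uM) at a phase of the cycle.

    Only erlotinib doses strictly before ``query_time`` (in the periodic
    sense) contribute: a dose exactly at the query instant is attributed to
    its previous-cycle copy.
    """
    erl = schedule.drug_events(ERLOTINIB)
    if not erl:
        return 0.0
    period = schedule.cycle_hours
    pattern = np.array([e.time for e in erl])
    amps = pk.dose_slope * np.array([e.dose for e in erl]) + pk.dose_intercept
    lag = np.mod(query_time - pattern, period)
    lag[np.isclose(lag, 0.0, atol=1e-9)] = period
    conc = float((amps * np.exp(-pk.elimination * lag)).sum() / (1.0 - math.exp(-pk.elimination * period)))
    return float(ng_per_ml_to_uM(conc, pk.molar_mass))


def check_combination_gaps(
    schedule: Schedule,
    rules: ToxicityRuleSet = DEFAULT_RULES,
    pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK,
) -> ToxicityReport:
    """Check the two inter-drug sequencing rules on a repeating schedule.

    (1) every erlotinib dose must come >= 6 h after the nearest preceding
    evofosfamide dose (periodic wrap included); (2) at each evofosfamide dose
    instant the steady-state erlotinib plasma concentration from all earlier
    erlotinib doses must not exceed the 2.357 uM threshold (1% tolerance).
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    violations: list[Violation] = []
    period = schedule.cycle_hours
    erl = schedule.drug_events(ERLOTINIB)
    evo = schedule.drug_events(EVOFOSFAMIDE)

    if erl and evo:
        evo_times = np.array([e.time for e in evo])
        for e in erl:
            gaps = np.mod(e.time - evo_times, period)
            gaps[np.isclose(gaps, 0.0, atol=1e-9)] = period
            gap = float(np.min(gaps))
            if gap < rules.evo_to_erl_gap_hours - 1e-9:
                violations.append(
                    Violation(
                        rule="evo_to_erlotinib_gap",
                        where=f"erlotinib dose at {e.time:g} h",
                        detail=(
                            f"only {gap:g} h after the preceding evofosfamide dose "
                            f"(requires >= {rules.evo_to_erl_gap_hours:g} h)"
                        ),
                    )
                )
    threshold = rules.erl_to_evo_threshold_uM * (1.0 + rules.threshold_rel_tol)
    for e in evo:
        c1 = steady_state_erlotinib_at(schedule, e.time, pk)
        if c1 > threshold:
            violations.append(
                Violation(
                    rule="erlotinib_washout",
                    where=f"evofosfamide dose at {e.time:g} h",
                    detail=(
                        f"erlotinib plasma concentration {c1:.3f} uM exceeds the "
                        f"{rules.erl_to_evo_threshold_uM} uM threshold"
                    ),
                )
            )
    return ToxicityReport(tuple(violations))


def clinical_trial_points() -> pd.DataFrame:
    """The packaged clinical-trial tolerability table (dose, schedule, n, location)."""
    with resources.files("hapsched.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)
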