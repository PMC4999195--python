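"""Plasma pharmacokinetics for erlotinib and evofosfamide.

Erlotinib: a single oral dose of D1 mg produces a plasma concentration
``(7*D1 + 365) * exp(-0.0307 t)`` ng/mL at t hours post-dose; concentrations
from repeated doses superpose linearly.  Within the tumor the drug attenuates
exponentially with distance from the vessel (rate 0.0173 per distance unit).
Concentrations are converted ng/mL -> uM with erlotinib's molar mass
393.44 g/mol (1 ng/mL = 1/MW uM).

Evofosfamide: a dose of D2 mg/m^2 ramps linearly to its peak over the first
half hour and then decays exponentially; peak concentration and decay rate are
cubic functions of dose fitted to phase-1 trial data.  With a half-life under
an hour, doses spaced >= 6 h apart do not accumulate, so the plasma trace is
that of the most recent dose only (a full-superposition mode exists to test
that approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

HOURS_PER_WEEK = 168.0


@dataclass(frozen=True)
class ErlotinibPK:
    """Erlotinib plasma / spatial PK constants."""

    dose_slope: float = 7.0  # (ng/mL) per mg
    dose_intercept: float = 365.0  # ng/mL
    elimination: float = 0.0307  # per hour
    spatial_decay: float = 0.0173  # per distance unit
    molar_mass: float = 393.44  # g/mol

    def __post_init__(self):
        for name in ("dose_slope", "dose_intercept", "elimination", "spatial_decay", "molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EvofosfamidePK:
    """Evofosfamide dose -> (cmax, elimination rate) cubic fits."""

    cmax_coeffs: tuple[float, float, float, float] = (2.008e-7, -0.0003276, 0.1753, -12.54)
    k_coeffs: tuple[float, float, float, float] = (1.302e-7, -0.0002043, 0.08873, -5.829)
    valid_dose_range: tuple[float, float] = (7.5, 940.0)  # mg/m^2, trial range
    min_dose_spacing: float = 6.0  # hours
    ramp_duration: float = 0.5  # hours to reach cmax


DEFAULT_ERLOTINIB_PK = ErlotinibPK()
DEFAULT_EVO_PK = EvofosfamidePK()


@dataclass(frozen=True)
class PlasmaTrace:
    """A sampled plasma-concentration time course."""

    times: np.ndarray  # hours
    concentration: np.ndarray  # drug-specific units
    units: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "concentration": self.concentration, "units": self.units}
        )


# ---------------------------------------------------------------------------
# Erlotinib
# ---------------------------------------------------------------------------

def erlotinib_plasma_after_dose(D1: float, t, pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK):
    """Plasma concentration (ng/mL) t hours after a single D1 mg dose."""
    if D1 <= 0:
        raise ValueError("dose must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since dose must be nonnegative")
    out = (pk.dose_slope * D1 + pk.dose_intercept) * np.exp(-pk.elimination * t)
    return out if out.ndim else float(out)


def erlotinib_plasma_total(
    dose_times: Sequence[float],
    doses: Sequence[float],
    t,
    pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK,
):
    """Superposed plasma concentration (ng/mL) over an arbitrary dose history.

    Doses with ``dose_time <= t`` contribute; times before the first dose give 0.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if dose_times.shape != doses.shape:
        raise ValueError("dose_times and doses must have equal length")
    if np.any(np.diff(dose_times) < 0):
        raise ValueError("dose_times must be sorted")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    t = np.asarray(t, dtype=float)
    amps = pk.dose_slope * doses + pk.dose_intercept
    dt = t[..., None] - dose_times
    contrib = np.where(dt >= 0, amps * np.exp(-pk.elimination * np.maximum(dt, 0.0)), 0.0)
    out = contrib.sum(axis=-1)
    return out if out.ndim else float(out)


def ng_per_ml_to_uM(conc_ng_ml, molar_mass: float = DEFAULT_ERLOTINIB_PK.molar_mass):
    """Convert ng/mL to micromolar: 1 ng/mL = 1 ug/L = (1/MW) umol/L."""
    return np.asarray(conc_ng_ml, dtype=float) / molar_mass


def erlotinib_concentration_in_compartment(
    plasma_ng_ml, distance: float, pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK
):
    """Tissue concentration (uM) at a given distance from the vessel."""
    plasma = np.asarray(plasma_ng_ml, dtype=float)
    if np.any(plasma < 0):
        raise ValueError("plasma concentration must be nonnegative")
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    out = ng_per_ml_to_uM(plasma * np.exp(-pk.spatial_decay * distance), pk.molar_mass)
    return out if out.ndim else float(out)


def erlotinib_periodic_concentration(
    pattern_times: Sequence[float],
    doses,
    query_times,
    period: float = HOURS_PER_WEEK,
    pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK,
):
    """Steady-state plasma concentration (ng/mL) of an infinitely repeated pattern.

    ``pattern_times`` are dose times within one period; the infinite periodic
    superposition has the closed form sum_j amp_j * exp(-k*((s - tau_j) mod P))
    / (1 - exp(-k P)) at query phase s.
    """
    pattern_times = np.asarray(pattern_times, dtype=float)
    doses = np.broadcast_to(np.asarray(doses, dtype=float), pattern_times.shape)
    if pattern_times.size == 0:
        raise ValueError("dose pattern must be nonempty")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    q = np.asarray(query_times, dtype=float)
    amps = pk.dose_slope * doses + pk.dose_intercept
    lag = np.mod(q[..., None] - pattern_times, period)
    geom = 1.0 - np.exp(-pk.elimination * period)
    out = (amps * np.exp(-pk.elimination * lag)).sum(axis=-1) / geom
    return out if out.ndim else float(out)


def erlotinib_steady_state_peak(
    weekly_pattern: Sequence[float],
    D1: float,
    pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK,
) -> float:
    """Peak steady-state concentration (uM) of a weekly-repeating schedule.

    The concentration decays between doses, so the maximum over one period is
    attained at one of the dose instants (immediately post-dose).
    """
    if D1 <= 0:
        raise ValueError("dose must be positive")
    pattern = np.asarray(weekly_pattern, dtype=float)
    if pattern.size == 0:
        raise ValueError("dose pattern must be nonempty")
    peaks = erlotinib_periodic_concentration(pattern, D1, pattern, HOURS_PER_WEEK, pk)
    return float(ng_per_ml_to_uM(np.max(peaks), pk.molar_mass))


# ---------------------------------------------------------------------------
# Evofosfamide
# ---------------------------------------------------------------------------

def _check_evo_dose(D2: float, pk: EvofosfamidePK) -> None:
    lo, hi = pk.valid_dose_range
    if not (lo <= D2 <= hi):
        raise ValueError(
            f"evofosfamide dose {D2} mg/m^2 outside the fitted range [{lo}, {hi}]"
        )


def evo_cmax(D2: float, pk: EvofosfamidePK = DEFAULT_EVO_PK) -> float:
    """Peak plasma concentration (ug/mL) after a D2 mg/m^2 dose."""
    _check_evo_dose(D2, pk)
    val = float(np.polyval(pk.cmax_coeffs, D2))
    if val <= 0:
        raise ValueError(
            f"fitted cmax is nonpositive at {D2} mg/m^2; the cubic fit is only "
            "physical for doses above ~85 mg/m^2"
        )
    return val


def evo_k(D2: float, pk: EvofosfamidePK = DEFAULT_EVO_PK) -> float:
    """Elimination rate (per hour) after a D2 mg/m^2 dose."""
    _check_evo_dose(D2, pk)
    val = float(np.polyval(pk.k_coeffs, D2))
    if val <= 0:
        raise ValueError(
            f"fitted elimination rate is nonpositive at {D2} mg/m^2; the cubic "
            "fit is only physical for doses above ~85 mg/m^2"
        )
    return val


def min_physical_evo_dose(pk: EvofosfamidePK = DEFAULT_EVO_PK) -> float:
    """Smallest integer dose (mg/m^2) at which both PK cubics are positive."""
    lo, hi = pk.valid_dose_range
    for d in range(int(np.ceil(lo)), int(hi) + 1):
        if np.polyval(pk.cmax_coeffs, d) > 0 and np.polyval(pk.k_coeffs, d) > 0:
            return float(d)
    raise RuntimeError("no physical dose in range")  # pragma: no cover


def evo_plasma_after_dose(D2: float, t, pk: EvofosfamidePK = DEFAULT_EVO_PK):
    """Plasma concentration (ug/mL) t hours after a single dose.

    Linear ramp ``2*cmax*t`` for t < 1/2 h, then exponential decay from cmax.
    """
    cmax = evo_cmax(D2, pk)
    k = evo_k(D2, pk)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since dose must be nonnegative")
    ramp = cmax / pk.ramp_duration * t
    decay = cmax * np.exp(-k * (t - pk.ramp_duration))
    out = np.where(t < pk.ramp_duration, ramp, decay)
    return out if out.ndim else float(out)


def evo_plasma_total(
    dose_times: Sequence[float],
    doses: Sequence[float],
    t,
    pk: EvofosfamidePK = DEFAULT_EVO_PK,
    full_superposition: bool = False,
):
    """Plasma concentration (ug/mL) over a dose history.

    By default only the most recent dose contributes (no-accumulation
    approximation, justified by the 0.81 h half-life); doses must be spaced at
    least ``pk.min_dose_spacing`` hours apart.  ``full_superposition=True``
    sums all past doses instead, for testing the approximation.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if dose_times.shape != doses.shape:
        raise ValueError("dose_times and doses must have equal length")
    if np.any(np.diff(dose_times) < pk.min_dose_spacing):
        raise ValueError(
            f"evofosfamide doses must be spaced >= {pk.min_dose_spacing} h apart"
        )
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    if dose_times.size:
        if full_superposition:
            for tau, d in zip(dose_times, doses):
                mask = t >= tau
                if np.any(mask):
                    out[mask] += evo_plasma_after_dose(d, t[mask] - tau, pk)
        else:
            idx = np.searchsorted(dose_times, t, side="right") - 1
            mask = idx >= 0
            for j in np.unique(idx[mask]):
                sel = idx == j
                out[sel] = evo_plasma_after_dose(doses[j], t[sel] - dose_times[j], pk)
    return float(out[0]) if scalar else out


def erlotinib_half_life(pk: ErlotinibPK = DEFAULT_ERLOTINIB_PK) -> float:
    """Plasma half-life in hours (~22.6 h at the default elimination rate)."""
    return float(np.log(2.0) / pk.elimination)
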