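"""Exact stochastic simulation of the multitype birth-death process.

This is the validation oracle for the analytic engine: a statistically exact
simulator of the time-inhomogeneous two-type (sensitive/resistant)
birth-death process with mutation at division.  Events are generated by
thinning (Lewis-Shedler): candidate events are proposed at a per-interval
upper bound on the total event rate and accepted with probability
``true_rate / bound``; rate discontinuities at dose times are handled by
recomputing bounds per inter-breakpoint interval, so no leaping error is
incurred.  Each sensitive division yields a resistant daughter with
probability ``u``.

The simulator targets small instances (cross-validation, conditional-burden
estimation); replicates whose population exceeds the cap are truncated and
flagged rather than simulated to the astronomically large mean sizes the
analytic engine can report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import RateFunctions
from .microenvironment import CompartmentModel
from .rate_models import RateModel
from .schedule import Schedule

__all__ = ["SimConfig", "SimSummary", "simulate", "simulate_compartment", "estimate_prob_resistance"]

_BOUND_SAFETY = 1.005
_BOUND_SAMPLES = 64
_BOUND_FINE_STEP = 0.05  # hours; resolves the sharp post-dose death spike


@dataclass(frozen=True)
class SimConfig:
    """Configuration for a full-model simulation run."""

    compartments: CompartmentModel
    rate_model: RateModel
    schedule: Schedule
    horizon: float
    n_replicates: int = 1000
    seed: int = 0
    max_population: int = 10_000_000
    record_times: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_population <= self.compartments.total_initial:
            raise ValueError("max_population must exceed the initial population")


@dataclass(frozen=True)
class SimSummary:
    """Replicate-level and summary statistics of a simulation run.

    ``sensitive``/``resistant`` have shape (n_replicates, n_times); truncated
    replicates (population-cap hits) are excluded from all summaries.
    """

    times: np.ndarray
    sensitive: np.ndarray
    resistant: np.ndarray
    truncated: np.ndarray  # bool per replicate

    @property
    def n_effective(self) -> int:
        return int((~self.truncated).sum())

    def _ok(self):
        if self.n_effective == 0:
            raise RuntimeError("all replicates were truncated at the population cap")
        return ~self.truncated

    @property
    def mean_sensitive(self) -> np.ndarray:
        return self.sensitive[self._ok()].mean(axis=0)

    @property
    def mean_resistant(self) -> np.ndarray:
        return self.resistant[self._ok()].mean(axis=0)

    @property
    def se_sensitive(self) -> np.ndarray:
        ok = self._ok()
        return self.sensitive[ok].std(axis=0, ddof=1) / np.sqrt(ok.sum())

    @property
    def se_resistant(self) -> np.ndarray:
        ok = self._ok()
        return self.resistant[ok].std(axis=0, ddof=1) / np.sqrt(ok.sum())

    @property
    def fraction_resistant(self) -> np.ndarray:
        return (self.resistant[self._ok()] > 0).mean(axis=0)

    @property
    def fraction_resistant_se(self) -> np.ndarray:
        p, n = self.fraction_resistant, self.n_effective
        return np.sqrt(p * (1.0 - p) / n)

    @property
    def n_truncated(self) -> int:
        return int(self.truncated.sum())

    def recurrence_times(self, M: float) -> np.ndarray:
        """Per-replicate first recorded time back at/above M after dropping below."""
        ok = self._ok()
        total = self.sensitive[ok] + self.resistant[ok]
        out = np.full(total.shape[0], np.nan)
        for r in range(total.shape[0]):
            below = total[r] < M
            if not below.any():
                continue
            k0 = int(np.argmax(below))
            back = total[r, k0:] >= M
            if back.any():
                out[r] = self.times[k0 + int(np.argmax(back))]
        return out

    def conditional_mean_burden(self, t_index: int = -1) -> tuple[float, float]:
        """Mean total burden over resistant replicates at a recorded time,
        with its standard error."""
        ok = self._ok()
        total = self.sensitive[ok][:, t_index] + self.resistant[ok][:, t_index]
        res = self.resistant[ok][:, t_index] > 0
        if not res.any():
            raise RuntimeError("no resistant replicates to condition on")
        vals = total[res]
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0


def _interval_bounds(rates: RateFunctions, t_lo: float, t_hi: float) -> tuple[float, float]:
    """Upper bounds on per-cell (lam+mu) for each type over [t_lo, t_hi].

    Rates are smooth between breakpoints, so a dense sample with a small
    safety factor bounds them; thinning asserts acceptance <= 1 at every
    proposal, which would expose an invalid bound.
    """
    span = t_hi - t_lo
    fine = t_lo + np.arange(0.0, min(6.0, span), _BOUND_FINE_STEP)
    ts = np.unique(np.concatenate([fine, np.linspace(t_lo, t_hi, _BOUND_SAMPLES)]))
    bx = max(rates.lam_X(t) + rates.mu_X(t) for t in ts) * _BOUND_SAFETY
    by = max(rates.lam_Y(t) + rates.mu_Y(t) for t in ts) * _BOUND_SAFETY
    return bx, by


def simulate_compartment(
    M0: int,
    rates: RateFunctions,
    u: float,
    horizon: float,
    n_replicates: int,
    seed,
    max_population: int = 10_000_000,
    record_times: Sequence[float] | None = None,
    y0: int = 0,
) -> SimSummary:
    """Simulate one compartment for many replicates (exact thinning).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if record_times is None:
        record_times = np.linspace(0.0, horizon, 11)
    record_times = np.asarray(sorted(record_times), dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_replicates)

    bps = sorted({0.0, horizon, *[p for p in rates.breakpoints if 0.0 < p < horizon]})
    intervals = list(zip(bps[:-1], bps[1:]))
    bounds = [_interval_bounds(rates, lo, hi) for lo, hi in intervals]

    nt = record_times.size
    S = np.zeros((n_replicates, nt), dtype=np.int64)
    R = np.zeros((n_replicates, nt), dtype=np.int64)
    truncated = np.zeros(n_replicates, dtype=bool)

    for rep in range(n_replicates):
        rng = np.random.default_rng(child_seeds[rep])
        x, y = int(M0), int(y0)
        t = 0.0
        rec_k = 0
        trunc = False
        for (lo, hi), (bx, by) in zip(intervals, bounds):
            t = max(t, lo)
            while t < hi:
                B = x * bx + y * by
                if B <= 0.0:
                    t = hi
                    break
                t_next = t + rng.exponential(1.0 / B)
                if t_next >= hi:
                    t = hi
                    break
                t = t_next
                while rec_k < nt and record_times[rec_k] < t:
                    S[rep, rec_k], R[rep, rec_k] = x, y
                    rec_k += 1
                # propose an event: pick cell class by bound mass, then thin
                v = rng.random() * B
                if v < x * bx:
                    lam, mu = rates.lam_X(t), rates.mu_X(t)
                    total = lam + mu
                    accept = total / bx
                    assert accept <= 1.0 + 1e-12, "thinning bound violated"
                    w = rng.random()
                    if w < lam / bx:
                        if rng.random() < u:
                            y += 1  # division produced one resistant daughter
                        else:
                            x += 1
                    elif w < accept:
                        x -= 1
                else:
                    lam, mu = rates.lam_Y(t), rates.mu_Y(t)
                    total = lam + mu
                    accept = total / by
                    assert accept <= 1.0 + 1e-12, "thinning bound violated"
                    w = rng.random()
                    if w < lam / by:
                        y += 1
                    elif w < accept:
                        y -= 1
                if x + y > max_population:
                    trunc = True
                    break
            if trunc:
                break
        while rec_k < nt:
            S[rep, rec_k], R[rep, rec_k] = x, y
            rec_k += 1
        truncated[rep] = trunc
    return SimSummary(times=record_times, sensitive=S, resistant=R, truncated=truncated)


def _schedule_rate_functions(config: SimConfig) -> list[RateFunctions]:
    """Per-compartment rate callables derived from the schedule (via the
    same concentration model as the analytic engine)."""
    from .dynamics import _build_segments

    times, c1, c2, evo_phase, _seg = _build_segments(
        config.schedule, config.horizon, fine_window=4.0, fine_step=0.02, coarse_step=0.25
    )
    from .pharmacokinetics import DEFAULT_ERLOTINIB_PK, ng_per_ml_to_uM
    from .rate_models import RESISTANT, SENSITIVE

    ev_times, _, _ = config.schedule.expand(config.horizon)
    breaks = tuple(np.unique(ev_times))
    out = []
    for comp in config.compartments:
        C1 = ng_per_ml_to_uM(
            c1 * np.exp(-DEFAULT_ERLOTINIB_PK.spatial_decay * comp.distance),
            DEFAULT_ERLOTINIB_PK.molar_mass,
        )
        lam_X, mu_X = config.rate_model.erlotinib_rates(SENSITIVE, comp.index, C1)
        lam_Y, mu_Y = config.rate_model.erlotinib_rates(RESISTANT, comp.index, C1)
        mu_X = np.broadcast_to(mu_X, lam_X.shape).copy()
        mu_Y = np.broadcast_to(mu_Y, lam_Y.shape).copy()
        if np.any(evo_phase):
            _, mu_X_e = config.rate_model.evofosfamide_rates(SENSITIVE, comp.index, c2[evo_phase])
            _, mu_Y_e = config.rate_model.evofosfamide_rates(RESISTANT, comp.index, c2[evo_phase])
            mu_X[evo_phase] = mu_X_e
            mu_Y[evo_phase] = mu_Y_e

        def interp(arr, _t=times):
            a = arr

            def f(t, _t=_t, a=a):
                return float(np.interp(t, _t, a))

            return f

        out.append(
            RateFunctions(
                lam_X=interp(lam_X),
                mu_X=interp(mu_X),
                lam_Y=interp(lam_Y),
                mu_Y=interp(mu_Y),
                breakpoints=breaks,
            )
        )
    return out


def simulate(config: SimConfig) -> SimSummary:
    """Simulate the full compartment model under a dosing schedule.

    Compartments are independent; one master seed spawns independent streams
    per compartment, and per-compartment summaries are summed replicate-wise
    (replicate r pairs compartment streams (r, i) across i).
    """
    record_times = (
        np.asarray(config.record_times, dtype=float)
        if config.record_times
        else np.linspace(0.0, config.horizon, 11)
    )
    ss = np.random.SeedSequence(config.seed)
    comp_seeds = ss.spawn(len(config.compartments))
    rate_fns = _schedule_rate_functions(config)
    S = np.zeros((config.n_replicates, record_times.size), dtype=np.int64)
    R = np.zeros_like(S)
    truncated = np.zeros(config.n_replicates, dtype=bool)
    for comp, rf, cs in zip(config.compartments, rate_fns, comp_seeds):
        summ = simulate_compartment(
            comp.initial_sensitive,
            rf,
            config.rate_model.mutation_rate,
            config.horizon,
            config.n_replicates,
            cs,
            config.max_population,
            record_times,
        )
        S += summ.sensitive
        R += summ.resistant
        truncated |= summ.truncated
    return SimSummary(times=record_times, sensitive=S, resistant=R, truncated=truncated)


def estimate_prob_resistance(summary: SimSummary, t: float) -> tuple[float, float]:
    """Fraction of (non-truncated) replicates with a live resistant cell at t,
    with its binomial standard error."""
    k = int(np.searchsorted(summary.times, t + 1e-12) - 1)
    if k < 0 or t > summary.times[-1] + 1e-9:
        raise ValueError("t outside the recorded range")
    p = float(summary.fraction_resistant[k])
    return p, float(np.sqrt(p * (1.0 - p) / summary.n_effective))
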