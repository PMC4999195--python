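"""Analytic evolutionary dynamics of the multitype birth-death model.

Within each compartment the sensitive population is a simple birth-death
process with time-varying rates, so its mean is
``E[X](t) = M * exp(int_0^t (lam_X - mu_X))``.  Resistant clones are seeded
at the mutant influx ``b(t) = E[X](t) * lam_X(t) * u`` (one resistant
daughter per sensitive division with probability u) and then grow as an
independent birth-death process, giving

* ``E[Y](t) = int_0^t b(tau) exp(int_tau^t (lam_Y - mu_Y)) dtau``
* ``P[Y(t)>0] = 1 - exp(-int_0^t b(T) (1 - P_ext(T, t)) dT)`` where
  ``P_ext(T, t) = I/(1+I)`` with
  ``I = int_0^{t-T} mu_Y(tau+T) * exp(int_0^tau (mu_Y-lam_Y)(eta+T) deta) dtau``
  is the classic extinction probability of a clone founded at time T.

Compartments evolve independently; tumor-level means add and the tumor-level
resistance probability is ``1 - prod_i (1 - P_i)``.

Two evaluation layers are provided.  The callable-based operations
(:func:`mean_sensitive`, :func:`extinction_prob`, ...) use adaptive
quadrature split at the rate discontinuities and serve small problems and
verification against closed forms.  :func:`evaluate_schedule` is the
production path: it lays down a graded time grid (fine in the hours after
each evofosfamide dose, where the death-rate spike decays on a sub-hour
scale), evaluates all rate and concentration arrays segment-by-segment so
discontinuities at dose instants are never integrated across, and obtains
all integrals from cached cumulative sums in O(grid) per compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_simpson, quad

from .microenvironment import CompartmentModel
from .pharmacokinetics import (
    DEFAULT_ERLOTINIB_PK,
    DEFAULT_EVO_PK,
    evo_cmax,
    evo_k,
    ng_per_ml_to_uM,
)
from .rate_models import RESISTANT, SENSITIVE, RateModel
from .schedule import ERLOTINIB, Schedule

__all__ = [
    "RateFunctions",
    "CompartmentDynamics",
    "DynamicsResult",
    "mean_sensitive",
    "mutant_influx",
    "extinction_prob",
    "mean_resistant",
    "prob_resistance",
    "aggregate",
    "recurrence_time",
    "conditional_burden",
    "evaluate_schedule",
]

_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-11, limit=400)


@dataclass(frozen=True)
class RateFunctions:
    """Scalar-callable birth/death rates with known discontinuity points."""

    lam_X: Callable[[float], float]
    mu_X: Callable[[float], float]
    lam_Y: Callable[[float], float]
    mu_Y: Callable[[float], float]
    breakpoints: tuple[float, ...] = ()

    @classmethod
    def constant(cls, lam_X, mu_X, lam_Y, mu_Y) -> "RateFunctions":
        return cls(
            lam_X=lambda t: lam_X,
            mu_X=lambda t: mu_X,
            lam_Y=lambda t: lam_Y,
            mu_Y=lambda t: mu_Y,
        )

    @classmethod
    def piecewise_constant(cls, bounds: Sequence[float], rates: Sequence[tuple]) -> "RateFunctions":
        """Rates constant on [bounds[k], bounds[k+1]); rates[k] = (lX,mX,lY,mY)."""
        bounds = np.asarray(bounds, dtype=float)
        table = np.asarray(rates, dtype=float)
        if table.shape[0] != bounds.size + 1:
            raise ValueError("need one rate tuple per interval (len(bounds)+1)")

        def pick(col):
            def f(t):
                k = int(np.searchsorted(bounds, t, side="right"))
                return float(table[k, col])

            return f

        return cls(pick(0), pick(1), pick(2), pick(3), breakpoints=tuple(bounds))


def _points_in(breakpoints, lo, hi):
    return [p for p in breakpoints if lo < p < hi] or None


def _quad(f, lo, hi, breakpoints=()):
    if hi <= lo:
        return 0.0
    val, _ = quad(f, lo, hi, points=_points_in(breakpoints, lo, hi), **_QUAD_KW)
    return val


def mean_sensitive(M0: float, rates: RateFunctions, t: float) -> float:
    """E[X](t) = M0 * exp(int_0^t (lam_X - mu_X))."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    expo = _quad(lambda s: rates.lam_X(s) - rates.mu_X(s), 0.0, t, rates.breakpoints)
    return M0 * np.exp(expo)


def mutant_influx(M0: float, rates: RateFunctions, t: float, u: float) -> float:
    """b(t) = E[X](t) * lam_X(t) * u, resistant cells produced per hour."""
    return mean_sensitive(M0, rates, t) * rates.lam_X(t) * u


def extinction_prob(rates: RateFunctions, T: float, t: float) -> float:
    """Probability that a clone founded by one resistant cell at time T is
    extinct by time t."""
    if not (0 <= T <= t):
        raise ValueError("need 0 <= T <= t")
    if t == T:
        return 0.0
    bp = rates.breakpoints

    def net_death(s):
        return rates.mu_Y(s) - rates.lam_Y(s)

    def omega(tau):
        return np.exp(_quad(net_death, T, T + tau, bp))

    shifted = tuple(p - T for p in bp)
    I = _quad(lambda tau: rates.mu_Y(tau + T) * omega(tau), 0.0, t - T, shifted)
    return I / (1.0 + I)


def _grid_for(rates: RateFunctions, t: float, n: int = 4001) -> np.ndarray:
    pts = np.linspace(0.0, t, n)
    extra = [p for p in rates.breakpoints if 0.0 < p < t]
    return np.unique(np.concatenate([pts, np.asarray(extra, dtype=float)]))


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(np.diff(x) * 0.5 * (y[1:] + y[:-1]), out=out[1:])
    return out


# exponent clip: preserves the correct 0/1 limits of extinction weights when
# cumulative net-death integrals are astronomically large
_EXP_CLIP = 500.0


def _exp_clipped(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def mean_resistant(M0: float, rates: RateFunctions, t: float, u: float, n_grid: int = 4001) -> float:
    """E[Y](t) by cached cumulative quadrature of the seeding integral."""
    if t <= 0:
        return 0.0
    g = _grid_for(rates, t, n_grid)
    lam_X = np.array([rates.lam_X(s) for s in g])
    mu_X = np.array([rates.mu_X(s) for s in g])
    lam_Y = np.array([rates.lam_Y(s) for s in g])
    mu_Y = np.array([rates.mu_Y(s) for s in g])
    EX = M0 * np.exp(_cumtrapz(lam_X - mu_X, g))
    b = EX * lam_X * u
    G = _cumtrapz(lam_Y - mu_Y, g)
    return float(_exp_clipped(G[-1]) * _cumtrapz(b * _exp_clipped(-G), g)[-1])


def prob_resistance(M0: float, rates: RateFunctions, t: float, u: float, n_grid: int = 4001) -> float:
    """P[Y(t)>0] from the seeding integral with clone extinction."""
    if t <= 0:
        return 0.0
    g = _grid_for(rates, t, n_grid)
    lam_X = np.array([rates.lam_X(s) for s in g])
    mu_X = np.array([rates.mu_X(s) for s in g])
    lam_Y = np.array([rates.lam_Y(s) for s in g])
    mu_Y = np.array([rates.mu_Y(s) for s in g])
    EX = M0 * np.exp(_cumtrapz(lam_X - mu_X, g))
    b = EX * lam_X * u
    G = _cumtrapz(lam_Y - mu_Y, g)
    CH = _cumtrapz(mu_Y * _exp_clipped(-G), g)
    I = _exp_clipped(G) * (CH[-1] - CH)
    integrand = b / (1.0 + I)
    return float(1.0 - np.exp(-_cumtrapz(integrand, g)[-1]))


# ---------------------------------------------------------------------------
# Aggregation and endpoints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentDynamics:
    """Per-compartment trajectories on a shared output grid."""

    compartment: int
    times: np.ndarray
    mean_sensitive: np.ndarray
    mean_resistant: np.ndarray
    prob_resistance: np.ndarray


@dataclass(frozen=True)
class DynamicsResult:
    """Tumor-level trajectories plus the per-compartment breakdown.

    ``times`` is the output grid; ``dense_times``/``dense_E_total`` carry the
    full integration grid for recurrence detection and plotting.
    """

    times: np.ndarray
    E_X: np.ndarray
    E_Y: np.ndarray
    E_total: np.ndarray
    P: np.ndarray
    per_compartment: tuple[CompartmentDynamics, ...]
    recurrence_time: float | None
    dense_times: np.ndarray | None = None
    dense_E_total: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        rows = [
            pd.DataFrame(
                {
                    "time_h": self.times,
                    "compartment": "total",
                    "E_X": self.E_X,
                    "E_Y": self.E_Y,
                    "P": self.P,
                }
            )
        ]
        for c in self.per_compartment:
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": c.times,
                        "compartment": str(c.compartment),
                        "E_X": c.mean_sensitive,
                        "E_Y": c.mean_resistant,
                        "P": c.prob_resistance,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def aggregate(
    per_compartment: Sequence[CompartmentDynamics],
    M: float | None = None,
    dense_times: np.ndarray | None = None,
    dense_E_total: np.ndarray | None = None,
) -> DynamicsResult:
    """Combine independent compartments: means add, no-resistance probabilities
    multiply."""
    if not per_compartment:
        raise ValueError("no compartments to aggregate")
    times = per_compartment[0].times
    for c in per_compartment[1:]:
        if c.times.shape != times.shape or not np.allclose(c.times, times):
            raise ValueError("per-compartment time grids are misaligned")
    E_X = np.sum([c.mean_sensitive for c in per_compartment], axis=0)
    E_Y = np.sum([c.mean_resistant for c in per_compartment], axis=0)
    with np.errstate(divide="ignore"):  # P_i == 1 -> log 0 -> P == 1 exactly
        log_none = np.sum(
            [np.log1p(-c.prob_resistance) for c in per_compartment], axis=0
        )
    P = 1.0 - np.exp(log_none)
    rec = None
    if M is not None and dense_times is not None and dense_E_total is not None:
        rec = recurrence_time(dense_times, dense_E_total, M)
    return DynamicsResult(
        times=times,
        E_X=E_X,
        E_Y=E_Y,
        E_total=E_X + E_Y,
        P=P,
        per_compartment=tuple(per_compartment),
        recurrence_time=rec,
        dense_times=dense_times,
        dense_E_total=dense_E_total,
    )


def recurrence_time(times: np.ndarray, e_total: np.ndarray, M: float) -> float | None:
    """First time the mean tumor size returns to M after first dropping below.

    Returns None if the population never drops below M, or never returns
    within the grid.  The crossing is located by linear interpolation of
    log E_total between grid points.
    """
    below = e_total < M
    if not np.any(below):
        return None
    first_below = int(np.argmax(below))
    after = e_total[first_below:]
    at_or_above = after >= M
    if not np.any(at_or_above):
        return None
    k = first_below + int(np.argmax(at_or_above))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    y0, y1 = e_total[k - 1], e_total[k]
    if t1 == t0 or y1 == y0 or y0 <= 0:
        return float(t1)
    f = (np.log(M) - np.log(y0)) / (np.log(y1) - np.log(y0))
    return float(t0 + f * (t1 - t0))


def conditional_burden(E_X, E_Y, P):
    """Mean tumor size conditioned on resistance having emerged.

    Analytic approximation ``E[X] + E[Y]/P[Y>0]``; undefined (NaN) where
    P = 0.  Exact when the sensitive population is independent of the event
    and resistant mass is concentrated on resistant trajectories; simulation
    estimates are the reference where the approximation matters.
    """
    E_X = np.asarray(E_X, dtype=float)
    E_Y = np.asarray(E_Y, dtype=float)
    P = np.asarray(P, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(P > 0, E_X + E_Y / np.where(P > 0, P, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Production path: schedule -> concentration/rate arrays -> trajectories
# ---------------------------------------------------------------------------

def _build_segments(
    schedule: Schedule,
    horizon: float,
    fine_window: float,
    fine_step: float,
    coarse_step: float,
):
    """Graded per-segment time grid plus vessel concentrations and phase mask.

    Segment boundaries are the dose instants (and the horizon); within a
    segment the active-dose set is constant so every array is smooth there.
    Returns (times, C1_vessel_ng_ml, C2_ug_ml, evo_death_mask).
    """
    times_ev, doses_ev, drugs_ev = schedule.expand(horizon)
    erl_mask = np.array([d == ERLOTINIB for d in drugs_ev], dtype=bool)
    evo_mask = ~erl_mask

    ramp_ends = times_ev[evo_mask] + DEFAULT_EVO_PK.ramp_duration
    bounds = np.unique(np.concatenate([[0.0], times_ev, ramp_ends, [horizon]]))
    bounds = bounds[bounds <= horizon]

    pk1, pk2 = DEFAULT_ERLOTINIB_PK, DEFAULT_EVO_PK
    erl_t, erl_d = times_ev[erl_mask], doses_ev[erl_mask]
    evo_t, evo_d = times_ev[evo_mask], doses_ev[evo_mask]
    erl_amp = pk1.dose_slope * erl_d + pk1.dose_intercept
    # exp(+k*tau) factors for the superposition sum (grouped per segment)
    evo_cmax_d = np.array([evo_cmax(d, pk2) for d in evo_d]) if evo_t.size else np.array([])
    evo_k_d = np.array([evo_k(d, pk2) for d in evo_d]) if evo_t.size else np.array([])

    seg_times, seg_c1, seg_c2, seg_evo = [], [], [], []
    seg_starts = [0]
    S = 0.0  # sum of amp_j * exp(elim * tau_j) over active erlotinib doses
    n_erl_used = 0
    for a, bnd in zip(bounds[:-1], bounds[1:]):
        while n_erl_used < erl_t.size and erl_t[n_erl_used] <= a + 1e-12:
            S += erl_amp[n_erl_used] * np.exp(pk1.elimination * erl_t[n_erl_used])
            n_erl_used += 1
        j_evo = int(np.searchsorted(evo_t, a + 1e-12)) - 1  # most recent evo dose
        last_erl = erl_t[n_erl_used - 1] if n_erl_used else -np.inf
        last_evo = evo_t[j_evo] if j_evo >= 0 else -np.inf
        in_evo_phase = j_evo >= 0 and last_evo >= last_erl - 1e-12

        fine_until = last_evo + fine_window if j_evo >= 0 else -np.inf
        nodes = [a]
        if fine_until > a:
            fe = min(bnd, fine_until)
            nodes.append(np.arange(a + fine_step, fe, fine_step))
            nodes.append([fe])
            start_coarse = fe
        else:
            start_coarse = a
        if bnd > start_coarse:
            nodes.append(np.arange(start_coarse + coarse_step, bnd, coarse_step))
            nodes.append([bnd])
        tt = np.unique(np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in nodes]))
        if tt.size < 2:
            tt = np.array([a, bnd])

        c1 = np.exp(-pk1.elimination * tt) * S
        if j_evo >= 0:
            dt = tt - evo_t[j_evo]
            ramp = evo_cmax_d[j_evo] / pk2.ramp_duration * dt
            decay = evo_cmax_d[j_evo] * np.exp(-evo_k_d[j_evo] * (dt - pk2.ramp_duration))
            c2 = np.where(dt < pk2.ramp_duration, ramp, decay)
        else:
            c2 = np.zeros_like(tt)

        seg_times.append(tt)
        seg_c1.append(c1)
        seg_c2.append(c2)
        seg_evo.append(np.full(tt.shape, in_evo_phase))
        seg_starts.append(seg_starts[-1] + tt.size)

    return (
        np.concatenate(seg_times),
        np.concatenate(seg_c1),
        np.concatenate(seg_c2),
        np.concatenate(seg_evo),
        np.asarray(seg_starts),
    )


def _cum_segmented(y: np.ndarray, x: np.ndarray, seg_starts: np.ndarray) -> np.ndarray:
    """Cumulative integral via composite Simpson within each smooth segment.

    ``y`` may be 1-D or 2-D (rows integrated along the shared grid); the
    2-D path batches many integrands per segment to amortize call overhead.
    """
    y2 = np.atleast_2d(y)
    out = np.empty_like(y2)
    offset = np.zeros(y2.shape[0])
    for s, e in zip(seg_starts[:-1], seg_starts[1:]):
        if e - s >= 3:
            cs = cumulative_simpson(y2[:, s:e], x=x[s:e], axis=-1, initial=0.0)
        else:
            dx = np.diff(x[s:e])
            cs = np.concatenate(
                [np.zeros((y2.shape[0], 1)), np.cumsum(dx * 0.5 * (y2[:, s + 1:e] + y2[:, s:e - 1]), axis=-1)],
                axis=-1,
            )
        out[:, s:e] = offset[:, None] + cs
        offset = out[:, e - 1]
    return out if np.ndim(y) == 2 else out[0]


def evaluate_schedule(
    compartments: CompartmentModel,
    model: RateModel,
    schedule: Schedule,
    horizon: float,
    n_output: int = 41,
    fine_window: float = 4.0,
    fine_step: float = 0.02,
    coarse_step: float = 0.25,
) -> DynamicsResult:
    """Analytic tumor dynamics for a repeating schedule over ``[0, horizon]``.

    Mean trajectories are computed on the full graded grid; the resistance
    probability (quadratic cost in grid size) is evaluated at ``n_output``
    output times including the horizon.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times, c1_vessel, c2, evo_phase, seg_starts = _build_segments(
        schedule, horizon, fine_window, fine_step, coarse_step
    )
    pk1 = DEFAULT_ERLOTINIB_PK
    u = model.mutation_rate

    out_idx = np.unique(
        np.searchsorted(times, np.linspace(0.0, horizon, n_output), side="right") - 1
    )
    out_idx = out_idx[out_idx >= 0]
    if out_idx[-1] != times.size - 1:
        out_idx = np.append(out_idx, times.size - 1)
    out_times = times[out_idx]

    # rate matrices, one row per compartment, shared grid columns
    K = len(compartments)
    n = times.size
    lam_X = np.empty((K, n))
    mu_X = np.empty((K, n))
    lam_Y = np.empty((K, n))
    mu_Y = np.empty((K, n))
    M_init = np.array([c.initial_sensitive for c in compartments], dtype=float)
    for row, comp in enumerate(compartments):
        i = comp.index
        C1_uM = ng_per_ml_to_uM(
            c1_vessel * np.exp(-pk1.spatial_decay * comp.distance), pk1.molar_mass
        )
        lx, mx = model.erlotinib_rates(SENSITIVE, i, C1_uM)
        ly, my = model.erlotinib_rates(RESISTANT, i, C1_uM)
        lam_X[row], lam_Y[row] = lx, ly
        mu_X[row] = np.broadcast_to(mx, lx.shape)
        mu_Y[row] = np.broadcast_to(my, ly.shape)
        if np.any(evo_phase):
            _, mx_e = model.evofosfamide_rates(SENSITIVE, i, c2[evo_phase])
            _, my_e = model.evofosfamide_rates(RESISTANT, i, c2[evo_phase])
            lam_X[row], lam_Y[row] = lx, ly
            mu_X[row, evo_phase] = mx_e
            mu_Y[row, evo_phase] = my_e

    net = _cum_segmented(np.vstack([lam_X - mu_X, lam_Y - mu_Y]), times, seg_starts)
    EX = M_init[:, None] * np.exp(net[:K])
    G = net[K:]
    b = EX * lam_X * u
    expG = _exp_clipped(G)
    expnG = _exp_clipped(-G)
    seeds = _cum_segmented(np.vstack([b * expnG, mu_Y * expnG]), times, seg_starts)
    EY = expG * seeds[:K]
    CH = seeds[K:]
    dense_E_total = np.sum(EX + EY, axis=0)

    panel = np.diff(times) * 0.5
    per_comp = []
    for row, comp in enumerate(compartments):
        P_out = np.empty(out_idx.size)
        for m, k in enumerate(out_idx):
            if k == 0 or M_init[row] == 0 or u == 0:
                P_out[m] = 0.0
                continue
            I = expG[row, : k + 1] * (CH[row, k] - CH[row, : k + 1])
            integrand = b[row, : k + 1] / (1.0 + I)
            P_out[m] = 1.0 - np.exp(
                -np.sum(panel[:k] * (integrand[1:] + integrand[:-1]))
            )
        per_comp.append(
            CompartmentDynamics(
                compartment=comp.index,
                times=out_times,
                mean_sensitive=EX[row, out_idx],
                mean_resistant=EY[row, out_idx],
                prob_resistance=P_out,
            )
        )

    return aggregate(
        per_comp,
        M=compartments.total_initial,
        dense_times=times,
        dense_E_total=dense_E_total,
    )
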