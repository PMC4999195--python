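"""Per-compartment birth/death rates as functions of local drug concentration.

Cell kinetics are governed by three ingredients:

* **Control rates** — drug-free birth and death rates per compartment; the
  net control growth rate is positive everywhere and increases with oxygen.
* **Erlotinib response** — erlotinib is primarily cytostatic, so its effect
  enters through a Hill-type inhibition of the birth rate.  Sensitive cells
  respond strongly at all oxygen levels (with a mild gain in tolerance under
  hypoxia); resistant cells are untouched in the most hypoxic compartment and
  only partially inhibited near the vessel.
* **Evofosfamide response** — the prodrug is cytotoxic and hypoxia-activated:
  it leaves birth rates alone and raises the death rate by ``-0.5*ln(v)``
  where ``v(C2)`` is the cell-viability fraction, more potent at low oxygen.

During a combination cycle of length ``t1 + t2`` the first ``t1`` hours are
erlotinib-governed (both birth and death from the erlotinib curves) and the
last ``t2`` hours are the evofosfamide phase, during which births still track
the residual erlotinib concentration while deaths reflect evofosfamide.

The quantitative calibration (Hill coefficients as smooth functions of
compartment oxygen) is a pluggable configuration artifact validated against
the qualitative constraints above; the packaged default ships as JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from typing import Callable

import numpy as np

from .microenvironment import CompartmentModel, build_compartment_model

SENSITIVE = "sensitive"
RESISTANT = "resistant"
GENOTYPES = (SENSITIVE, RESISTANT)


class CalibrationError(ValueError):
    """A calibration parameter set violates a qualitative rate constraint."""


@dataclass(frozen=True)
class CalibrationParams:
    """Coefficients of the default oxygen-parametric rate calibration.

    Oxygen ``o`` is in percent O2 throughout.  Control kinetics:
    ``mu_c`` constant death, net growth ``net_base + net_span*o/(o+net_k_o)``.
    Erlotinib inhibits sensitive birth by a Hill factor with maximum
    ``imax_base + imax_span*o/(o+imax_k_o)`` and EC50
    ``ec50_base*(1 + ec50_tolerance/(o+ec50_k_o))`` uM; the resistant maximum
    inhibition scales linearly from 0 at the lowest-oxygen compartment to
    ``res_imax_top`` at the highest.  Evofosfamide viability is
    ``exp(-A(o)*C2/(C2+viab_k_c2))`` with activation ``A(o) =
    viab_a_max*viab_k_o/(o+viab_k_o)``.
    """

    control_death: float = 0.01  # per hour, both genotypes
    control_net_base: float = 0.018  # per hour at o -> 0
    control_net_span: float = 0.010  # additional net growth at high o
    control_net_k_o: float = 2.0  # percent O2 half-saturation

    sens_imax_base: float = 0.70
    sens_imax_span: float = 0.25
    sens_imax_k_o: float = 1.0
    sens_ec50_base: float = 0.06  # uM
    sens_ec50_tolerance: float = 0.5
    sens_ec50_k_o: float = 0.5
    sens_death_span: float = 0.0  # optional cytotoxic component, per hour
    hill_erlotinib: float = 2.0

    res_imax_top: float = 0.50
    res_ec50: float = 1.0  # uM
    res_hill: float = 2.0

    viab_a_max: float = 6.0
    viab_k_o: float = 0.4  # percent O2
    viab_k_c2: float = 4.0  # ug/mL

    mutation_rate: float = 1e-7
    literal_eq9: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationParams":
        if hasattr(path, "read"):
            payload = json.load(path)
        else:
            with open(path) as fh:
                payload = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise CalibrationError(
                f"unknown calibration keys: {sorted(unknown)}"
            )
        return cls(**payload)


def default_params() -> CalibrationParams:
    """The packaged default calibration."""
    with resources.files("hapsched.data").joinpath("default_calibration.json").open() as fh:
        return CalibrationParams.from_json(fh)


class RateModel:
    """Per-compartment, per-genotype rate curves bound to a compartment model.

    Rate curves are evaluated lazily at query time, so arbitrary dose
    histories are honored exactly.  Compartments are addressed by their
    1-based index.
    """

    def __init__(self, compartments: CompartmentModel, params: CalibrationParams):
        self.compartments = compartments
        self.params = params
        self._oxy = compartments.oxygen_fracs
        o_min, o_max = float(self._oxy.min()), float(self._oxy.max())
        span = o_max - o_min
        # resistant max inhibition: exactly zero in the most hypoxic compartment
        if span > 0:
            self._res_imax = params.res_imax_top * (self._oxy - o_min) / span
        else:
            self._res_imax = np.zeros_like(self._oxy)

    # -- lookups ------------------------------------------------------------

    def _pos(self, compartment: int) -> int:
        pos = compartment - 1
        if not (0 <= pos < len(self.compartments)):
            raise KeyError(f"unknown compartment index {compartment}")
        return pos

    @property
    def mutation_rate(self) -> float:
        return self.params.mutation_rate

    def control_rates(self, genotype: str, compartment: int) -> tuple[float, float]:
        """Drug-free (birth, death) rates, per hour."""
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r}")
        p = self.params
        o = self._oxy[self._pos(compartment)]
        net = p.control_net_base + p.control_net_span * o / (o + p.control_net_k_o)
        return p.control_death + net, p.control_death

    # -- erlotinib ----------------------------------------------------------

    def _erl_inhibition(self, genotype: str, pos: int, C1):
        p = self.params
        o = self._oxy[pos]
        C = np.asarray(C1, dtype=float)
        if genotype == SENSITIVE:
            imax = p.sens_imax_base + p.sens_imax_span * o / (o + p.sens_imax_k_o)
            ec50 = p.sens_ec50_base * (1.0 + p.sens_ec50_tolerance / (o + p.sens_ec50_k_o))
            h = p.hill_erlotinib
        elif genotype == RESISTANT:
            imax = self._res_imax[pos]
            ec50 = p.res_ec50
            h = p.res_hill
        else:
            raise ValueError(f"unknown genotype {genotype!r}")
        Ch = C ** h
        return imax * Ch / (Ch + ec50 ** h)

    def erlotinib_rates(self, genotype: str, compartment: int, C1):
        """(birth, death) per hour at local erlotinib concentration C1 (uM)."""
        C = np.asarray(C1, dtype=float)
        if np.any(C < 0):
            raise ValueError("concentration must be nonnegative")
        pos = self._pos(compartment)
        lam_c, mu_c = self.control_rates(genotype, compartment)
        inhib = self._erl_inhibition(genotype, pos, C)
        birth = lam_c * (1.0 - inhib)
        if genotype == SENSITIVE and self.params.sens_death_span:
            death = mu_c + self.params.sens_death_span * inhib
        else:
            death = mu_c * np.ones_like(birth) if np.ndim(birth) else mu_c
        if np.ndim(birth) == 0:
            return float(birth), float(death)
        return birth, np.broadcast_to(death, birth.shape).astype(float)

    # -- evofosfamide --------------------------------------------------------

    def viability(self, compartment: int, C2):
        """Cell-viability fraction v in (0, 1] at evofosfamide concentration C2."""
        C = np.asarray(C2, dtype=float)
        if np.any(C < 0):
            raise ValueError("concentration must be nonnegative")
        p = self.params
        o = self._oxy[self._pos(compartment)]
        A = p.viab_a_max * p.viab_k_o / (o + p.viab_k_o)
        out = np.exp(-A * C / (C + p.viab_k_c2))
        return float(out) if out.ndim == 0 else out

    def evofosfamide_rates(self, genotype: str, compartment: int, C2):
        """(birth, death) per hour during evofosfamide exposure.

        Birth stays at the control rate (the prodrug is cytotoxic, not
        cytostatic); death is raised by ``-0.5 * ln(v)``.  With
        ``literal_eq9`` both genotypes use the sensitive control birth rate.
        """
        v = self.viability(compartment, C2)
        if np.any(np.asarray(v) <= 0):
            raise ValueError("viability must be positive")
        birth_genotype = SENSITIVE if self.params.literal_eq9 else genotype
        lam_c, mu_c = self.control_rates(birth_genotype, compartment)
        _, mu_own = self.control_rates(genotype, compartment)
        death = mu_own - 0.5 * np.log(v)
        if np.ndim(death) == 0:
            return float(lam_c), float(death)
        return np.broadcast_to(lam_c, death.shape).astype(float), death

    def evo_death_rate(self, genotype: str, compartment: int, C2):
        return self.evofosfamide_rates(genotype, compartment, C2)[1]


# ---------------------------------------------------------------------------
# Combination-cycle rate composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationCycle:
    """One periodic treatment cycle: erlotinib phase then evofosfamide phase.

    ``erlotinib_conc(t, compartment)`` returns the local erlotinib
    concentration (uM) and ``evo_conc(t)`` the plasma evofosfamide
    concentration (ug/mL) at cycle time t; both are defined on
    ``[0, t1 + t2)``.
    """

    t1: float
    t2: float
    erlotinib_conc: Callable[[float, int], float]
    evo_conc: Callable[[float], float]
    periodic: bool = True

    @property
    def period(self) -> float:
        return self.t1 + self.t2


def combined_rates(
    model: RateModel, cycle: CombinationCycle, compartment: int, t: float
) -> tuple[float, float, float, float]:
    """(lam_X, mu_X, lam_Y, mu_Y) per hour at cycle time t.

    During the erlotinib phase ``[0, t1)`` all four rates come from the
    erlotinib dose-response curves at the local concentration; during the
    evofosfamide phase ``[t1, t1+t2)`` births still track residual erlotinib
    while deaths follow the evofosfamide viability response.
    """
    period = cycle.period
    if cycle.periodic:
        t = t % period
    elif not (0.0 <= t < period):
        raise ValueError(f"time {t} outside the cycle [0, {period})")
    C1 = cycle.erlotinib_conc(t, compartment)
    lam_X, mu_X = model.erlotinib_rates(SENSITIVE, compartment, C1)
    lam_Y, mu_Y = model.erlotinib_rates(RESISTANT, compartment, C1)
    if t >= cycle.t1:
        C2 = cycle.evo_conc(t)
        _, mu_X = model.evofosfamide_rates(SENSITIVE, compartment, C2)
        _, mu_Y = model.evofosfamide_rates(RESISTANT, compartment, C2)
    return lam_X, mu_X, lam_Y, mu_Y


# ---------------------------------------------------------------------------
# Calibration validation
# ---------------------------------------------------------------------------

def validate_calibration(model: RateModel) -> None:
    """Check the qualitative constraints every calibration must satisfy.

    Raises :class:`CalibrationError` naming the first violated constraint.
    """
    K = len(model.compartments)
    idx = np.arange(1, K + 1)
    C_grid = np.linspace(0.0, 20.0, 81)  # uM
    C2_grid = np.linspace(0.0, 25.0, 51)  # ug/mL
    C_large = 1e6

    nets = []
    for i in idx:
        lam, mu = model.control_rates(SENSITIVE, int(i))
        if lam - mu <= 0:
            raise CalibrationError(
                f"constraint (i) violated: control net growth <= 0 in compartment {i}"
            )
        nets.append(lam - mu)
    if np.any(np.diff(nets) < -1e-12):
        raise CalibrationError(
            "constraint (i) violated: control net growth not nondecreasing in oxygen"
        )

    def net(genotype, i, C):
        b, d = model.erlotinib_rates(genotype, int(i), C)
        return np.asarray(b) - np.asarray(d)

    lo, hi = 1, K
    for i in idx:
        drops = np.diff(net(SENSITIVE, i, C_grid))
        if np.any(drops > 1e-12):
            raise CalibrationError(
                f"constraint (ii) violated: sensitive net rate not nonincreasing "
                f"in erlotinib concentration in compartment {i}"
            )
    drop_lo = net(SENSITIVE, lo, 0.0) - net(SENSITIVE, lo, C_large)
    drop_hi = net(SENSITIVE, hi, 0.0) - net(SENSITIVE, hi, C_large)
    if not (drop_hi > drop_lo > 0):
        raise CalibrationError(
            "constraint (ii) violated: sensitive response must be strong at high "
            "oxygen and weaker (but present) at low oxygen"
        )
    if net(SENSITIVE, hi, C_large) >= 0:
        raise CalibrationError(
            "constraint (ii) violated: sensitive net rate must go negative at "
            "saturating erlotinib in the best-oxygenated compartment"
        )

    res_ctrl = net(RESISTANT, lo, 0.0)
    if abs(net(RESISTANT, lo, C_large) - res_ctrl) > 0.05 * abs(res_ctrl):
        raise CalibrationError(
            "constraint (iii) violated: resistant cells must be essentially "
            "unaffected by erlotinib in the most hypoxic compartment"
        )
    res_drop_hi = net(RESISTANT, hi, 0.0) - net(RESISTANT, hi, C_large)
    if not (0 < res_drop_hi < net(RESISTANT, hi, 0.0) - net(SENSITIVE, hi, C_large)):
        raise CalibrationError(
            "constraint (iii) violated: resistant cells must be partially (not "
            "fully) inhibited in the best-oxygenated compartment"
        )

    v_prev = None
    for i in idx:
        v = model.viability(int(i), C2_grid)
        if not math.isclose(float(v[0]), 1.0, abs_tol=1e-12):
            raise CalibrationError(
                f"constraint (iv) violated: v(0) != 1 in compartment {i}"
            )
        if np.any(np.diff(v) > 1e-12):
            raise CalibrationError(
                f"constraint (iv) violated: viability not nonincreasing in "
                f"evofosfamide concentration in compartment {i}"
            )
        if v_prev is not None and np.any(v[1:] < v_prev[1:] - 1e-12):
            raise CalibrationError(
                "constraint (iv) violated: evofosfamide potency must not "
                "increase with oxygen"
            )
        v_prev = v


def default_calibration(
    compartments: CompartmentModel | None = None,
    params: CalibrationParams | None = None,
) -> RateModel:
    """Build and validate a rate model (packaged defaults unless overridden)."""
    if compartments is None:
        compartments = build_compartment_model()
    if params is None:
        params = default_params()
    model = RateModel(compartments, params)
    validate_calibration(model)
    return model


def load_calibration(path, compartments: CompartmentModel | None = None) -> RateModel:
    """Load a calibration JSON file, validate it, and bind it to a model."""
    return default_calibration(compartments, CalibrationParams.from_json(path))
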