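"""Core 14-compartment ODE system for platelet reconstitution after allo-HCT.

Two Friberg-type transit chains run in parallel: a *patient* submodel
(proliferating HSCs -> TR1..TR3 -> circulating platelets) that is suppressed
by the conditioning regimen and by ATG, and a *graft* submodel whose HSC
compartment is fed by the transplanted cells (two transit compartments,
Graft1 -> Graft2 -> HSC_GT), up-regulated by a platelet feedback term
``(Graft1_0 / PLT_GT)^gamma`` and inhibited by a transplant-associated
effect compartment (HCT) that declines first-order.  Observed platelets are
the sum of the two circulating compartments.

State layout (index constants below)::

    0  HSC_PAT   5  ATG        9  HSC_GT    13 PLT_GT
    1  TR1_PAT   6  HCT       10  TR1_GT
    2  TR2_PAT   7  GRAFT1    11  TR2_GT
    3  TR3_PAT   8  GRAFT2    12  TR3_GT
    4  PLT_PAT
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .parameters import IndividualParameters, PopulationParameters

__all__ = [
    "HSC_PAT",
    "TR1_PAT",
    "TR2_PAT",
    "TR3_PAT",
    "PLT_PAT",
    "ATG",
    "HCT",
    "GRAFT1",
    "GRAFT2",
    "HSC_GT",
    "TR1_GT",
    "TR2_GT",
    "TR3_GT",
    "PLT_GT",
    "N_STATE",
    "STATE_NAMES",
    "TreatmentRegimen",
    "CovariateSeries",
    "Bolus",
    "transit_rate",
    "drug_effect",
    "initialize_state",
    "event_schedule",
    "derivatives",
    "rhs_numba",
    "pack_rate_constants",
]

(
    HSC_PAT,
    TR1_PAT,
    TR2_PAT,
    TR3_PAT,
    PLT_PAT,
    ATG,
    HCT,
    GRAFT1,
    GRAFT2,
    HSC_GT,
    TR1_GT,
    TR2_GT,
    TR3_GT,
    PLT_GT,
) = range(14)

N_STATE = 14

STATE_NAMES = (
    "HSC_PAT",
    "TR1_PAT",
    "TR2_PAT",
    "TR3_PAT",
    "PLT_PAT",
    "ATG",
    "HCT",
    "GRAFT1",
    "GRAFT2",
    "HSC_GT",
    "TR1_GT",
    "TR2_GT",
    "TR3_GT",
    "PLT_GT",
)


@dataclass(frozen=True)
class TreatmentRegimen:
    """Treatment schedule for one subject, times in days relative to transplant.

    ``atg_doses`` is a sequence of ``(time, dose_mg)`` pairs;
    ``transfusion_times`` are the days on which a platelet concentrate was
    (or is imputed to have been) given.
    """

    conditioning_start: float = -6.0
    conditioning_stop: float = -2.0
    atg_doses: tuple = ()
    transplant_time: float = 0.0
    transfusion_times: tuple = ()
    donor_relation: str = "unrelated"

    def __post_init__(self) -> None:
        if not self.conditioning_start < self.conditioning_stop <= self.transplant_time:
            raise ValueError(
                "require conditioning_start < conditioning_stop <= transplant_time"
            )
        if self.donor_relation not in ("related", "unrelated"):
            raise ValueError(f"unknown donor relation {self.donor_relation!r}")
        object.__setattr__(self, "atg_doses", tuple(tuple(d) for d in self.atg_doses))
        object.__setattr__(
            self, "transfusion_times", tuple(float(t) for t in self.transfusion_times)
        )
        for t, dose in self.atg_doses:
            if dose <= 0:
                raise ValueError("ATG doses must be positive")

    def with_transfusions(self, times) -> "TreatmentRegimen":
        return TreatmentRegimen(
            conditioning_start=self.conditioning_start,
            conditioning_stop=self.conditioning_stop,
            atg_doses=self.atg_doses,
            transplant_time=self.transplant_time,
            transfusion_times=tuple(times),
            donor_relation=self.donor_relation,
        )


@dataclass
class CovariateSeries:
    """Time-stamped serum total-protein measurements (g/dL).

    Evaluated last-observation-carried-forward: the multiplier is neutral (1)
    before the first measurement and after ``cutoff_day`` (used during
    forecasting, where future covariate values are unknown).
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    cutoff_day: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("total-protein times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("total-protein values must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    def value_at(self, t: float) -> float | None:
        """LOCF total protein at time t, or None where the effect is uninformed."""
        if self.cutoff_day is not None and t > self.cutoff_day:
            return None
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return None
        return float(self.values[idx])

    def censored(self, cutoff_day: float | None) -> "CovariateSeries":
        return CovariateSeries(self.times, self.values, cutoff_day=cutoff_day)

    def change_times(self, t_start: float, t_end: float) -> np.ndarray:
        """Times in (t_start, t_end) at which the LOCF multiplier changes."""
        pts = list(self.times)
        if self.cutoff_day is not None:
            pts.append(self.cutoff_day)
        pts = [t for t in pts if t_start < t < t_end]
        return np.asarray(sorted(set(pts)))


def transit_rate(mmt: float, n_transit: int) -> float:
    """Transit rate K = (n + 1) / MMT of a maturation chain (1/day)."""
    if mmt <= 0:
        raise ValueError(f"mean maturation time must be positive, got {mmt}")
    if n_transit < 1:
        raise ValueError("n_transit must be >= 1")
    return (n_transit + 1) / mmt


def drug_effect(t: float, regimen: TreatmentRegimen, rho: float) -> float:
    """Fractional proliferation inhibition at time t.

    Equal to rho on the closed conditioning interval and 0 elsewhere.
    """
    if regimen.conditioning_start <= t <= regimen.conditioning_stop:
        return rho
    return 0.0


def initialize_state(params: PopulationParameters) -> np.ndarray:
    """Pre-conditioning steady state: all five patient compartments at baseline.

    ATG, the HCT effect and the entire graft side start at zero; the graft is
    introduced by the day-0 boluses of :func:`event_schedule`.
    """
    y = np.zeros(N_STATE)
    y[HSC_PAT : PLT_PAT + 1] = params.baseline_plt_pat
    return y


@dataclass(frozen=True)
class Bolus:
    """An instantaneous amount added to one compartment."""

    time: float
    compartment: int
    amount: float

    @property
    def compartment_name(self) -> str:
        return STATE_NAMES[self.compartment]


def event_schedule(
    params: IndividualParameters | PopulationParameters,
    regimen: TreatmentRegimen,
) -> list[Bolus]:
    """All bolus events implied by a regimen, time-sorted.

    At transplant (day 0): the graft-cell dose into GRAFT1, the HCT-effect
    magnitude into HCT (limit of a short zero-order input), and the day-+1
    platelet boost into PLT_PAT (multiplied by ``sibling_boost_ratio`` for
    related donors).  ATG doses enter the virtual ATG compartment in mg, one
    bolus per administration; each transfusion adds ``transfusion_boost``
    to PLT_PAT.
    """
    t0 = regimen.transplant_time
    boost = params.day1_boost
    if regimen.donor_relation == "related":
        boost *= params.sibling_boost_ratio
    events = [
        Bolus(t0, GRAFT1, params.graft10),
        Bolus(t0, HCT, params.hct0),
        Bolus(t0, PLT_PAT, boost),
    ]
    for t, dose in regimen.atg_doses:
        events.append(Bolus(float(t), ATG, float(dose)))
    for t in regimen.transfusion_times:
        events.append(Bolus(float(t), PLT_PAT, params.transfusion_boost))
    events.sort(key=lambda e: (e.time, e.compartment))
    return events


# --- right-hand side ---------------------------------------------------------
#
# The fast path packs all rate constants into a flat vector so the RHS can be
# jit-compiled.  DRUG(t) and the total-protein multiplier are piecewise
# constant, so the integrator treats their change points as segment
# boundaries and passes the in-segment constants here.

#: layout of the parameter vector consumed by :func:`rhs_numba`
_P_KPAT, _P_KGT, _P_KGR, _P_GAMMA, _P_KEL, _P_ALPHA, _P_KINT = range(7)
_P_GRAFT10, _P_DRUG, _P_TPMULT, _P_FLOOR = range(7, 11)
_NP = 11


@numba.njit(cache=True)
def rhs_numba(t, y, p):  # pragma: no cover - exercised via the wrapper
    kpat = p[0]
    kgt = p[1]
    kgr = p[2]
    gamma = p[3]
    kel = p[4]
    alpha = p[5]
    kint = p[6]
    graft10 = p[7]
    drug = p[8]
    tpmult = p[9]
    floor = p[10]

    d = np.empty(14)
    # patient submodel
    d[0] = kpat * (1.0 - drug) * y[0] - kpat * y[0]
    d[1] = kpat * (y[0] - y[1])
    d[2] = kpat * (y[1] - y[2])
    d[3] = kpat * (y[2] - y[3])
    d[4] = kpat * y[3] - kpat * y[4] * (1.0 + alpha * y[5])
    d[5] = -kint * y[5]
    # graft submodel
    d[6] = -kel * y[6]
    d[7] = -kgr * y[7]
    d[8] = kgr * (y[7] - y[8])
    plt_gt = y[13] if y[13] > floor else floor
    ratio = (graft10 / plt_gt) ** gamma
    hsc_gt = y[9] if y[9] > 0.0 else 0.0
    d[9] = kgt * tpmult * ratio * (1.0 - y[6]) * hsc_gt - kgt * y[9] + kgr * y[8]
    d[10] = kgt * (y[9] - y[10])
    d[11] = kgt * (y[10] - y[11])
    d[12] = kgt * (y[11] - y[12])
    d[13] = kgt * y[12] - kgt * y[13]
    return d


def pack_rate_constants(
    params: PopulationParameters, drug: float = 0.0, tp_mult: float = 1.0
) -> np.ndarray:
    """Flat parameter vector for :func:`rhs_numba` with in-segment constants."""
    p = np.empty(_NP)
    p[_P_KPAT] = transit_rate(params.mmt_pat, params.n_transit)
    p[_P_KGT] = transit_rate(params.mmt_gt, params.n_transit)
    p[_P_KGR] = 2.0 / params.ttbm
    p[_P_GAMMA] = params.gamma
    p[_P_KEL] = params.kel
    p[_P_ALPHA] = params.atg_alpha
    p[_P_KINT] = params.atg_kint
    p[_P_GRAFT10] = params.graft10
    p[_P_DRUG] = drug
    p[_P_TPMULT] = tp_mult
    p[_P_FLOOR] = params.feedback_floor
    return p


def derivatives(
    t: float,
    state: np.ndarray,
    params: IndividualParameters | PopulationParameters,
    regimen: TreatmentRegimen | None = None,
    covariates: CovariateSeries | None = None,
) -> np.ndarray:
    """Full 14-dimensional rate vector at time ``t``.

    Convenience wrapper around the jit-compiled RHS that evaluates the
    piecewise-constant inputs (conditioning effect, total-protein multiplier)
    at ``t``.  Raises on NaN or negative state, which indicates a caller bug.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite values")
    if np.any(state < 0):
        raise ValueError("state contains negative amounts")
    drug = drug_effect(t, regimen, params.rho) if regimen is not None else 0.0
    tp_mult = 1.0
    if covariates is not None:
        tp = covariates.value_at(t)
        if tp is not None:
            tp_mult = (tp / params.tp_median) ** params.tp_exponent
    return rhs_numba(t, state, pack_rate_constants(params, drug, tp_mult))
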