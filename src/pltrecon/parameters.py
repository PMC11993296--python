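"""Population and individual parameterization of the platelet-reconstitution model.

The model is a nonlinear mixed-effects (NLME) structure: a vector of typical
(population) values, log-normal inter-individual variability (IIV) on a subset
of parameters, and a combined residual-error model on the observations.
Published coefficients of variation (%CV) are mapped to log-normal variances
via ``omega^2 = ln(1 + CV^2)``, the standard NLME convention, which keeps every
realized parameter strictly positive.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ResidualError",
    "PopulationParameters",
    "IndividualParameters",
    "IIV_PARAMETERS",
    "DEFAULT_CV",
    "cv_to_omega",
    "load_parameters",
    "save_parameters",
]

#: Parameters that carry inter-individual variability (those with a printed %CV).
IIV_PARAMETERS: tuple[str, ...] = (
    "baseline_plt_pat",
    "rho",
    "day1_boost",
    "transfusion_boost",
    "graft10",
    "mmt_gt",
    "gamma",
    "hct0",
)

#: Published %CVs, expressed as fractions (1.15 == 115 %CV).
DEFAULT_CV: Mapping[str, float] = {
    "baseline_plt_pat": 1.150,
    "rho": 1.523,
    "day1_boost": 2.897,
    "transfusion_boost": 0.679,
    "graft10": 0.829,
    "mmt_gt": 0.909,
    "gamma": 0.487,
    "hct0": 0.871,
}


def cv_to_omega(cv: float) -> float:
    """Standard deviation of the log-normal random effect for a given CV.

    ``omega^2 = ln(1 + CV^2)``; a CV of zero maps to omega = 0 (no IIV).
    """
    if cv < 0:
        raise ValueError(f"CV must be non-negative, got {cv}")
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class ResidualError:
    """Combined proportional + additive residual error on platelet observations.

    sigma(f)^2 = (proportional * f)^2 + additive^2, with f the model prediction
    in 1e9/L.  Defaults: 20 % proportional, 2e9/L additive.
    """

    proportional: float = 0.20
    additive: float = 2.0

    def sigma(self, prediction):
        import numpy as np

        f = np.asarray(prediction, dtype=float)
        return np.sqrt((self.proportional * f) ** 2 + self.additive**2)


@dataclass
class PopulationParameters:
    """Typical values of the 14-compartment platelet reconstitution model.

    Units: platelet amounts in 1e9/L, times in days, rates in 1/day.  The
    defaults are the published typical estimates; ``atg_alpha`` (linear
    ATG concentration-effect slope, per mg) and ``atg_kint`` (first-order
    decline of the virtual ATG amount, 1/day) are kinetic-pharmacodynamic
    settings calibrated so that a typical 800 mg/day ATG course on days
    -4..-2 crashes platelets immediately and places the pre-transplant
    nadir during ATG treatment (see docs/methods.md).
    """

    baseline_plt_pat: float = 90.5  # pre-HCT baseline platelet count, 1e9/L
    mmt_pat: float = 6.1  # mean maturation time pre-HCT, days
    rho: float = 0.945  # fractional proliferation inhibition during conditioning
    day1_boost: float = 20.1  # day-0 platelet bolus (unrelated donor), 1e9/L
    sibling_boost_ratio: float = 2.75  # multiplier on day1_boost for related donors
    transfusion_boost: float = 10.6  # platelet bolus per transfusion, 1e9/L
    atg_alpha: float = 0.01  # ATG concentration-effect slope, per mg
    atg_kint: float = 1.386  # ATG first-order decline, 1/day (t1/2 = 0.5 d)
    graft10: float = 72.4  # graft-cell dose / post-HCT baseline, 1e9/L
    mmt_gt: float = 7.0  # mean maturation time post-HCT, days
    gamma: float = 0.19  # feedback exponent
    ttbm: float = 1.5  # time to bone marrow, days
    kel: float = 0.353  # HCT-effect elimination rate, 1/day
    hct0: float = 4.22  # HCT-effect magnitude at day 0
    tp_median: float = 5.43  # total-protein centering constant, g/dL
    tp_exponent: float = 0.197  # total-protein effect exponent
    n_transit: int = 3  # transit compartments per submodel
    feedback_floor: float = 1e-3  # clamp on PLT_GT inside the feedback ratio, 1e9/L
    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    residual_error: ResidualError = field(default_factory=ResidualError)

    def __post_init__(self) -> None:
        positive = (
            "baseline_plt_pat",
            "mmt_pat",
            "day1_boost",
            "sibling_boost_ratio",
            "transfusion_boost",
            "atg_kint",
            "graft10",
            "mmt_gt",
            "ttbm",
            "kel",
            "tp_median",
            "feedback_floor",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("gamma", "hct0"):  # effect magnitudes: zero disables them
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_transit < 1:
            raise ValueError("n_transit must be >= 1")
        if self.atg_alpha < 0:
            raise ValueError("atg_alpha must be non-negative")
        for name, cv in self.cv.items():
            if name not in IIV_PARAMETERS:
                raise ValueError(f"unknown IIV parameter {name!r}")
            if cv < 0:
                raise ValueError(f"CV for {name} must be non-negative")

    def omega(self, name: str) -> float:
        """Log-normal standard deviation of the random effect on ``name``."""
        return cv_to_omega(self.cv.get(name, 0.0))

    def omegas(self) -> dict[str, float]:
        return {name: self.omega(name) for name in IIV_PARAMETERS}


@dataclass
class IndividualParameters(PopulationParameters):
    """One subject's realized parameters plus the eta vector that produced them.

    Values are ``typical * exp(eta)`` for parameters with IIV; rho is clipped
    at 1 (full proliferation arrest) because a log-normal draw around 0.945
    can exceed the physical bound.
    """

    eta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        for name, value in self.eta.items():
            if name not in IIV_PARAMETERS:
                raise ValueError(f"eta on unknown parameter {name!r}")
            if not math.isfinite(value):
                raise ValueError(f"eta[{name!r}] must be finite")

    @classmethod
    def from_population(
        cls, pop: PopulationParameters, eta: Mapping[str, float] | None = None
    ) -> "IndividualParameters":
        """Realize individual parameters from population typicals and an eta vector."""
        eta = dict(eta or {})
        values = dataclasses.asdict(pop)
        values.pop("cv")
        values.pop("residual_error")
        for name, e in eta.items():
            if name not in IIV_PARAMETERS:
                raise ValueError(f"eta on unknown parameter {name!r}")
            values[name] = values[name] * math.exp(e)
        values["rho"] = min(values["rho"], 1.0)
        return cls(
            cv=dict(pop.cv),
            residual_error=pop.residual_error,
            eta=eta,
            **values,
        )


def _as_plain_dict(params: PopulationParameters) -> dict:
    d = dataclasses.asdict(params)
    d["residual_error"] = dataclasses.asdict(params.residual_error)
    return d


def save_parameters(params: PopulationParameters, path) -> None:
    """Write a population-parameter profile as JSON."""
    with open(path, "w") as fh:
        json.dump(_as_plain_dict(params), fh, indent=2)
        fh.write("\n")


def load_parameters(path) -> PopulationParameters:
    """Read a population-parameter profile from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    raw.pop("eta", None)
    err = raw.pop("residual_error", None)
    kwargs = dict(raw)
    if err is not None:
        kwargs["residual_error"] = ResidualError(**err)
    return PopulationParameters(**kwargs)
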