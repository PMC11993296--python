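"""The three retained covariate effects: ATG, donor relation, total protein.

ATG is handled kinetic-pharmacodynamically: recorded doses (mg) feed a virtual
amount that declines first-order and multiplies platelet elimination linearly.
Donor relation scales the day-0 platelet boost.  Serum total protein enters as
a power function of the level centered at the cohort median, multiplying the
graft HSC proliferation term.
"""

from __future__ import annotations

import numpy as np

from .parameters import PopulationParameters

__all__ = [
    "atg_elimination",
    "atg_amount",
    "platelet_elimination_multiplier",
    "total_protein_multiplier",
    "day1_boost_amount",
]


def atg_elimination(amount: float, kint: float, dt: float) -> float:
    """Virtual ATG amount after first-order decline over an interval ``dt``."""
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if kint <= 0:
        raise ValueError("kint must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return amount * np.exp(-kint * dt)


def atg_amount(t: float, doses, kint: float) -> float:
    """Superposition of all doses administered at or before ``t``.

    ``doses`` is a sequence of ``(time, dose_mg)`` pairs.  This closed form
    equals the solution of dATG/dt = -K_INT * ATG with bolus inputs.
    """
    total = 0.0
    for td, dose in doses:
        if td <= t:
            total += atg_elimination(dose, kint, t - td)
    return total


def platelet_elimination_multiplier(atg: float, alpha: float) -> float:
    """Linear concentration-effect factor ``1 + alpha * ATG`` on platelet loss."""
    if atg < 0:
        raise ValueError("ATG amount must be non-negative")
    factor = 1.0 + alpha * atg
    if factor < 1.0:
        raise ValueError("elimination multiplier fell below 1; alpha must be >= 0")
    return factor


def total_protein_multiplier(
    tp: float, tp_median: float = 5.43, tp_exponent: float = 0.197
) -> float:
    """Proliferation multiplier ``(TP / median)^exponent`` for the graft HSCs."""
    if tp <= 0:
        raise ValueError(f"total protein must be positive, got {tp}")
    return (tp / tp_median) ** tp_exponent


def day1_boost_amount(donor_relation: str, params: PopulationParameters) -> float:
    """Day-0 platelet bolus; related donors get ``sibling_boost_ratio`` times more."""
    if donor_relation == "related":
        return params.day1_boost * params.sibling_boost_ratio
    if donor_relation == "unrelated":
        return params.day1_boost
    raise ValueError(f"unknown donor relation {donor_relation!r}")
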