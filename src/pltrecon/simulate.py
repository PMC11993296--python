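"""Trajectory integration and population simulation.

Integration is segmented: every bolus time, conditioning boundary and
total-protein change point restarts the solver, so dose events are exact
discontinuities and the right-hand side is smooth inside each segment
(which also lets the jit-compiled RHS receive the piecewise-constant
conditioning and total-protein inputs as plain numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import model
from .model import CovariateSeries, TreatmentRegimen
from .parameters import (
    IIV_PARAMETERS,
    IndividualParameters,
    PopulationParameters,
    ResidualError,
)

__all__ = [
    "Trajectory",
    "ObservationRecord",
    "simulate_individual",
    "sample_individual_parameters",
    "simulate_population",
    "add_residual_error",
    "default_grid",
]

#: default output grid spacing, days
GRID_SPACING = 0.25


def default_grid(t_start: float = -30.0, t_end: float = 180.0) -> np.ndarray:
    n = int(round((t_end - t_start) / GRID_SPACING))
    return t_start + GRID_SPACING * np.arange(n + 1)


@dataclass
class ObservationRecord:
    """One measured (or simulated-noisy) platelet count, optionally with TP."""

    time: float
    platelet: float
    total_protein: float | None = None

    def __post_init__(self) -> None:
        if self.platelet < 0:
            raise ValueError("platelet count must be non-negative")


class SolverFailure(RuntimeError):
    """Integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time: {last_time:g})")
        self.last_time = last_time


class _Integrator:
    """Advances the 14-compartment system through its event schedule."""

    def __init__(
        self,
        params: IndividualParameters | PopulationParameters,
        regimen: TreatmentRegimen,
        covariates: CovariateSeries | None,
        t_start: float,
        t_end: float,
        rtol: float,
        atol: float,
        method: str = "LSODA",
        fallback_method: str | None = "Radau",
    ):
        self.params = params
        self.regimen = regimen
        self.covariates = covariates
        self.rtol = rtol
        self.atol = atol
        self.method = method
        self.fallback_method = fallback_method
        self.t = float(t_start)
        self.t_end = float(t_end)
        self.y = model.initialize_state(params)

        events = model.event_schedule(params, regimen)
        for ev in events:
            if ev.time < t_start:
                raise ValueError(
                    f"event at day {ev.time:g} precedes simulation start {t_start:g}"
                )
        self._pending = [ev for ev in events if ev.time <= t_end]

        breaks = {regimen.conditioning_start, regimen.conditioning_stop}
        if covariates is not None:
            # the TP multiplier only touches graft proliferation, and the graft
            # is empty before transplant: changes before day 0 need no restart
            breaks.update(
                t
                for t in covariates.change_times(t_start, t_end).tolist()
                if t > regimen.transplant_time
            )
        self._breaks = sorted(b for b in breaks if t_start < b < t_end)

        # dense solution segments: parallel lists of start times and OdeSolution
        self._seg_t0: list[float] = []
        self._seg_sol: list = []
        self._apply_due_events()

    # -- event handling -------------------------------------------------------

    def _apply_due_events(self) -> None:
        while self._pending and self._pending[0].time <= self.t + 1e-12:
            ev = self._pending.pop(0)
            self.y[ev.compartment] += ev.amount

    def inject(self, compartment: int, amount: float) -> None:
        """Add a bolus at the current time (used by the transfusion trigger)."""
        self.y[compartment] += amount

    # -- integration ----------------------------------------------------------

    def _segment_constants(self, t_mid: float) -> np.ndarray:
        drug = model.drug_effect(t_mid, self.regimen, self.params.rho)
        tp_mult = 1.0
        if self.covariates is not None:
            tp = self.covariates.value_at(t_mid)
            if tp is not None:
                tp_mult = (tp / self.params.tp_median) ** self.params.tp_exponent
        return model.pack_rate_constants(self.params, drug, tp_mult)

    def advance(self, t_target: float) -> None:
        """Integrate up to ``t_target``, applying boluses as they fall due."""
        t_target = min(float(t_target), self.t_end)
        while self.t < t_target - 1e-12:
            stops = [t_target]
            if self._pending:
                stops.append(self._pending[0].time)
            nxt = [b for b in self._breaks if b > self.t + 1e-12]
            if nxt:
                stops.append(nxt[0])
            t_stop = min(stops)
            if t_stop > self.t + 1e-12:
                p = self._segment_constants(0.5 * (self.t + t_stop))
                sol = None
                methods = (self.method,) if self.fallback_method is None else (
                    self.method, self.fallback_method)
                for method in methods:  # optional stiff fallback
                    sol = solve_ivp(
                        model.rhs_numba,
                        (self.t, t_stop),
                        self.y,
                        method=method,
                        rtol=self.rtol,
                        atol=self.atol,
                        dense_output=True,
                        args=(p,),
                    )
                    if sol.success:
                        break
                if not sol.success:
                    raise SolverFailure(sol.message, self.t)
                self._seg_t0.append(self.t)
                self._seg_sol.append(sol.sol)
                self.y = sol.y[:, -1].copy()
                np.clip(self.y, 0.0, None, out=self.y)
            self.t = t_stop
            self._apply_due_events()

    # -- dense readout --------------------------------------------------------

    def states_at(self, times) -> np.ndarray:
        """State matrix (n_state, n_times); at a bolus time the post-bolus value."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if not self._seg_sol:
            raise SolverFailure("no integrated segments", self.t)
        t0 = np.asarray(self._seg_t0)
        out = np.empty((model.N_STATE, times.size))
        idx = np.clip(np.searchsorted(t0, times, side="right") - 1, 0, len(t0) - 1)
        for k in range(times.size):
            out[:, k] = self._seg_sol[idx[k]](times[k])
        np.clip(out, 0.0, None, out=out)
        return out


@dataclass
class Trajectory:
    """Dense solution of the platelet model on an output grid.

    ``plt_total`` is by construction the pointwise sum of the patient and
    graft circulating-platelet compartments.
    """

    t: np.ndarray
    plt_pat: np.ndarray
    plt_gt: np.ndarray
    states: np.ndarray | None = None
    _integrator: _Integrator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory grid must be strictly increasing")

    @property
    def plt_total(self) -> np.ndarray:
        return self.plt_pat + self.plt_gt

    def at(self, times) -> np.ndarray:
        """Total platelet count at arbitrary times within the solved span."""
        s = self.states_at(times)
        return s[model.PLT_PAT] + s[model.PLT_GT]

    def states_at(self, times) -> np.ndarray:
        if self._integrator is None:
            raise ValueError("trajectory carries no dense solution")
        return self._integrator.states_at(times)

    def to_frame(self, subject_id=None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time": self.t,
                "plt_pat": self.plt_pat,
                "plt_gt": self.plt_gt,
                "plt_total": self.plt_total,
            }
        )
        if subject_id is not None:
            df.insert(0, "subject", subject_id)
        return df


def simulate_individual(
    params: IndividualParameters | PopulationParameters,
    regimen: TreatmentRegimen | None = None,
    covariates: CovariateSeries | None = None,
    t_span: tuple[float, float] = (-30.0, 180.0),
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    keep_states: bool = False,
    fallback_method: str | None = "Radau",
) -> Trajectory:
    """Deterministic trajectory for one subject.

    Reproducible bit-for-bit for fixed inputs and tolerances.  ``grid``
    defaults to 0.25-day spacing over ``t_span``; arbitrary times within the
    span can be read off afterwards via :meth:`Trajectory.at`.
    """
    if regimen is None:
        regimen = TreatmentRegimen()
    if grid is None:
        grid = default_grid(*t_span)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < t_span[0] - 1e-9 or grid[-1] > t_span[1] + 1e-9:
        raise ValueError("grid must lie within t_span")
    integ = _Integrator(
        params, regimen, covariates, t_span[0], t_span[1], rtol, atol, method,
        fallback_method,
    )
    integ.advance(t_span[1])
    states = integ.states_at(grid)
    return Trajectory(
        t=grid,
        plt_pat=states[model.PLT_PAT],
        plt_gt=states[model.PLT_GT],
        states=states if keep_states else None,
        _integrator=integ,
    )


def sample_individual_parameters(
    pop: PopulationParameters, seed=None
) -> IndividualParameters:
    """Draw one subject's parameters from the log-normal IIV model.

    ``seed`` may be an int, a ``numpy.random.Generator`` or a ``SeedSequence``.
    Parameters without a printed %CV have no random effect; a CV of zero
    reproduces the typical value exactly.
    """
    rng = np.random.default_rng(seed)
    eta = {}
    for name in IIV_PARAMETERS:
        omega = pop.omega(name)
        if omega > 0:
            eta[name] = rng.normal(0.0, omega)
    return IndividualParameters.from_population(pop, eta)


def simulate_population(
    pop: PopulationParameters,
    n: int,
    seed,
    regimen_factory=None,
    t_span: tuple[float, float] = (-30.0, 180.0),
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[tuple[IndividualParameters, Trajectory]]:
    """Simulate ``n`` independent subjects.

    Per-subject random streams are spawned from the master seed by counter
    (``SeedSequence.spawn``), so results do not depend on execution order.
    ``regimen_factory(index, rng)`` may return a regimen or a
    ``(regimen, covariates)`` pair; by default every subject receives the
    typical regimen (conditioning -6..-2, unrelated donor, no ATG).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        params = sample_individual_parameters(pop, rng)
        covariates = None
        regimen = None
        if regimen_factory is not None:
            made = regimen_factory(i, rng)
            if isinstance(made, tuple):
                regimen, covariates = made
            else:
                regimen = made
        try:
            traj = simulate_individual(
                params, regimen, covariates, t_span=t_span, grid=grid,
                rtol=rtol, atol=atol,
            )
        except SolverFailure as err:  # annotate with the subject index
            raise SolverFailure(f"subject {i}: {err}", err.last_time) from err
        out.append((params, traj))
    return out


def add_residual_error(
    traj: Trajectory,
    times,
    error_model: ResidualError | None = None,
    seed=None,
) -> list[ObservationRecord]:
    """Perturb model predictions at ``times`` with the residual-error model.

    Observations are floored at zero (a platelet count cannot be negative).
    """
    if error_model is None:
        error_model = ResidualError()
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    f = traj.at(times)
    sigma = error_model.sigma(f)
    y = np.maximum(f + sigma * rng.standard_normal(times.size), 0.0)
    return [ObservationRecord(float(t), float(v)) for t, v in zip(times, y)]
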