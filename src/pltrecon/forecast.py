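"""MAP (empirical-Bayes) forecasting of individual platelet trajectories.

Given a subject's early data (all pre-transplant counts plus, depending on the
prediction day, the weekly post-transplant counts at days +7/+14/+21/+28), the
subject's random effects eta are estimated as the posterior mode under the
population priors:

    -2 log posterior  ~  sum_i [ (y_i - f_i(eta))^2 / sigma_i^2 + ln sigma_i^2 ]
                         + eta' Omega^{-1} eta

with diagonal Omega from the published %CVs (log-scale random effects) and
sigma_i from the residual-error model evaluated at the prediction.  The MAP
parameters then drive a 180-day prediction; transfusion information enters
only up to the prediction day, and the total-protein effect is neutral after
it (the future covariate is unknown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .cohort import SubjectDataset
from .parameters import (
    IIV_PARAMETERS,
    IndividualParameters,
    PopulationParameters,
)
from .simulate import SolverFailure, Trajectory, simulate_individual
from .outcomes import THROMBOCYTOPENIA_THRESHOLD, thrombocytopenia_score

__all__ = [
    "WEEKLY_ANCHORS",
    "fit_parameter_names",
    "select_fit_observations",
    "map_objective",
    "map_estimate",
    "MapResult",
    "forecast",
    "ForecastResult",
    "prediction_interval",
]

#: conventional weekly forecasting anchors, days post-HCT
WEEKLY_ANCHORS = (7.0, 14.0, 21.0, 28.0)

#: default solver tolerance during estimation (cheaper than simulation default)
MAP_RTOL = 1e-6
MAP_ATOL = 1e-8


def fit_parameter_names(pop: PopulationParameters) -> tuple[str, ...]:
    """Parameters that receive a random effect: exactly those with CV > 0."""
    return tuple(n for n in IIV_PARAMETERS if pop.omega(n) > 0)


def select_fit_observations(
    subject: SubjectDataset,
    cutoff_day: float,
    mode: str = "weekly",
    anchor_tolerance: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Observations contributing to the MAP fit.

    All pre-transplant measurements (t <= 0) always contribute.  In the
    default ``weekly`` mode the post-transplant data are the measurements
    closest to each weekly anchor (+7/+14/+21/+28) up to the cutoff; in
    ``all`` mode every measurement up to the cutoff contributes.
    """
    t, v = subject.times, subject.platelets
    if mode == "all":
        keep = t <= cutoff_day
        return t[keep], v[keep]
    if mode != "weekly":
        raise ValueError(f"unknown fit mode {mode!r}")
    keep = t <= 0
    idx = set(np.nonzero(keep)[0].tolist())
    for anchor in WEEKLY_ANCHORS:
        if anchor > cutoff_day:
            break
        j = int(np.argmin(np.abs(t - anchor))) if t.size else None
        if j is not None and abs(t[j] - anchor) <= anchor_tolerance and t[j] > 0:
            idx.add(j)
    idx = sorted(idx)
    return t[idx], v[idx]


def _fit_inputs(subject: SubjectDataset, cutoff_day: float):
    """Regimen and covariates as known at the prediction day."""
    regimen = subject.regimen.with_transfusions(
        t for t in subject.regimen.transfusion_times if t <= cutoff_day
    )
    covariates = (
        subject.covariates.censored(cutoff_day)
        if subject.covariates is not None and len(subject.covariates)
        else None
    )
    return regimen, covariates


def _realize(pop, names, eta_vec) -> IndividualParameters:
    return IndividualParameters.from_population(
        pop, {n: float(e) for n, e in zip(names, eta_vec)}
    )


def map_objective(
    eta,
    subject: SubjectDataset,
    pop: PopulationParameters,
    cutoff_day: float,
    mode: str = "weekly",
    prior_weight: float = 1.0,
    rtol: float = MAP_RTOL,
    atol: float = MAP_ATOL,
) -> float:
    """-2 log posterior (up to a constant) of the random-effect vector.

    ``eta`` is ordered like :func:`fit_parameter_names`.  ``prior_weight``
    scales the Omega^{-1} penalty (0 gives the unpenalized weighted
    least-squares limit).  Raises when no observation can contribute.
    """
    names = fit_parameter_names(pop)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(names),):
        raise ValueError(f"eta must have length {len(names)}")
    t_fit, y_fit = select_fit_observations(subject, cutoff_day, mode)
    if t_fit.size == 0:
        raise ValueError(
            "no usable observations before the cutoff; fall back to the "
            "population prediction (eta = 0)"
        )
    regimen, covariates = _fit_inputs(subject, cutoff_day)
    params = _realize(pop, names, eta)
    # Cheap plausibility guard: the worst-case feedback-amplified proliferation
    # rate kgt * (Graft1_0 / floor)^gamma.  Parameter combinations implying
    # growth beyond ~2000/day are unphysiological (doubling time < 30 s) and
    # make the ODE pathologically stiff; treat them as posterior cliffs.
    kgt = (params.n_transit + 1) / params.mmt_gt
    if kgt * (params.graft10 / params.feedback_floor) ** params.gamma > 2e3:
        return 1e12
    t_end = max(float(np.max(t_fit)), regimen.transplant_time) + 1e-6
    try:
        traj = simulate_individual(
            params,
            regimen,
            covariates,
            t_span=(min(-30.0, float(np.min(t_fit))), t_end),
            grid=np.array([min(-30.0, float(np.min(t_fit))), t_end]),
            rtol=rtol,
            atol=atol,
            fallback_method=None,  # fail fast: the cliff below handles it
        )
        f = traj.at(t_fit)
    except SolverFailure:
        # implausible eta region (e.g. runaway feedback): steer the
        # optimizer away with a large but finite objective value
        return 1e12
    if not np.all(np.isfinite(f)):
        return 1e12
    sigma2 = pop.residual_error.sigma(f) ** 2
    loglik_term = float(np.sum((y_fit - f) ** 2 / sigma2 + np.log(sigma2)))
    omega = np.array([pop.omega(n) for n in names])
    penalty = float(np.sum((eta / omega) ** 2))
    return loglik_term + prior_weight * penalty


@dataclass
class MapResult:
    """MAP estimate of one subject's random effects."""

    params: IndividualParameters
    eta: np.ndarray
    parameter_names: tuple
    objective: float
    converged: bool
    n_obs: int
    cutoff_day: float


def map_estimate(
    subject: SubjectDataset,
    pop: PopulationParameters,
    cutoff_day: float,
    mode: str = "weekly",
    prior_weight: float = 1.0,
    rtol: float = MAP_RTOL,
    atol: float = MAP_ATOL,
    tol: float = 1e-6,
    maxiter: int = 100,
) -> MapResult:
    """Minimize :func:`map_objective` from eta = 0 (quasi-Newton, bounded).

    Deterministic for fixed inputs and tolerances.  Non-convergence is flagged
    on the result, which still carries the best eta found.
    """
    names = fit_parameter_names(pop)
    t_fit, _ = select_fit_observations(subject, cutoff_day, mode)
    if t_fit.size == 0:
        raise ValueError(
            "no usable observations before the cutoff; fall back to the "
            "population prediction (eta = 0)"
        )
    fun = lambda e: map_objective(
        e, subject, pop, cutoff_day, mode, prior_weight, rtol, atol
    )
    if not names:  # no parameter carries IIV: the prior is degenerate at 0
        return MapResult(
            params=_realize(pop, names, np.empty(0)),
            eta=np.empty(0),
            parameter_names=names,
            objective=float(fun(np.empty(0))),
            converged=True,
            n_obs=int(t_fit.size),
            cutoff_day=float(cutoff_day),
        )
    omega = np.array([pop.omega(n) for n in names])
    bounds = [(-3.0 * w, 3.0 * w) for w in omega]
    res = minimize(
        fun,
        np.zeros(len(names)),
        method="L-BFGS-B",
        bounds=bounds,
        # finite-difference step well above the integrator's noise floor
        # (rtol ~1e-6 would otherwise swamp the default ~1e-8 step)
        options={"ftol": tol, "maxiter": maxiter, "eps": 1e-3},
    )
    if not res.success:
        warnings.warn(f"MAP optimizer did not converge: {res.message}", stacklevel=2)
    return MapResult(
        params=_realize(pop, names, res.x),
        eta=np.asarray(res.x),
        parameter_names=names,
        objective=float(res.fun),
        converged=bool(res.success),
        n_obs=int(t_fit.size),
        cutoff_day=float(cutoff_day),
    )


@dataclass
class ForecastResult:
    """180-day MAP prediction with the thrombocytopenia call."""

    cutoff_day: float
    map_result: MapResult
    trajectory: Trajectory
    predicted_last12_mean: float | None
    thrombocytopenia: bool | None
    thrombocytopenia_score: float | None  # larger = more at risk
    interval_level: float | None = None
    interval_times: np.ndarray | None = None
    interval_lower: np.ndarray | None = None
    interval_upper: np.ndarray | None = None

    @property
    def params(self) -> IndividualParameters:
        return self.map_result.params


def forecast(
    subject: SubjectDataset,
    pop: PopulationParameters,
    cutoff_day: float,
    mode: str = "weekly",
    t_span: tuple = (-30.0, 180.0),
    rtol: float = MAP_RTOL,
    atol: float = MAP_ATOL,
    interval_level: float | None = None,
    interval_samples: int = 200,
    seed=None,
    window: tuple = (29.0, 180.0),
) -> ForecastResult:
    """MAP-estimate, then predict platelets to day 180.

    The thrombocytopenia score is the (negated) mean of the last 12 predicted
    counts at the subject's own observation times inside the prediction window
    (day +29 to the latest measurement); the binary call compares that mean
    with the 75e9/L threshold.
    """
    map_result = map_estimate(subject, pop, cutoff_day, mode, rtol=rtol, atol=atol)
    regimen, covariates = _fit_inputs(subject, cutoff_day)
    traj = simulate_individual(
        map_result.params, regimen, covariates, t_span=t_span, rtol=rtol, atol=atol
    )
    eval_times = subject.times[
        (subject.times >= window[0]) & (subject.times <= window[1])
    ]
    if eval_times.size:
        pred = traj.at(eval_times)
        mean12 = thrombocytopenia_score(eval_times, pred, *window)
    else:
        mean12 = None
    result = ForecastResult(
        cutoff_day=float(cutoff_day),
        map_result=map_result,
        trajectory=traj,
        predicted_last12_mean=mean12,
        thrombocytopenia=None if mean12 is None else mean12 < THROMBOCYTOPENIA_THRESHOLD,
        thrombocytopenia_score=None if mean12 is None else -mean12,
    )
    if interval_level is not None:
        lo, hi, times = prediction_interval(
            subject, pop, map_result, level=interval_level,
            n_samples=interval_samples, seed=seed, t_span=t_span,
        )
        result.interval_level = interval_level
        result.interval_times = times
        result.interval_lower = lo
        result.interval_upper = hi
    return result


def _laplace_covariance(subject, pop, map_result, mode, step=0.05):
    """Posterior covariance of eta from the Hessian of the -2 log posterior."""
    names = map_result.parameter_names
    k = len(names)
    eta0 = map_result.eta
    fun = lambda e: map_objective(e, subject, pop, map_result.cutoff_day, mode)
    f0 = fun(eta0)
    H = np.empty((k, k))
    shifts = step * np.eye(k)
    f_plus = np.array([fun(eta0 + shifts[i]) for i in range(k)])
    f_minus = np.array([fun(eta0 - shifts[i]) for i in range(k)])
    for i in range(k):
        H[i, i] = (f_plus[i] - 2 * f0 + f_minus[i]) / step**2
        for j in range(i + 1, k):
            fpp = fun(eta0 + shifts[i] + shifts[j])
            H[i, j] = H[j, i] = (
                fpp - f_plus[i] - f_plus[j] + f0
            ) / step**2
    # -2 log posterior: covariance = 2 * H^{-1}.  Directions the data leave
    # flat have curvature at (or, with finite-difference noise, below) the
    # prior contribution 2/omega^2.  Whiten by the prior and floor the
    # eigenvalues at the prior precision, so no direction of the Laplace
    # posterior is ever wider than the prior in its own scale.
    omega = np.array([pop.omega(n) for n in names])
    try:
        H = 0.5 * (H + H.T)
        B = (omega[:, None] * H * omega[None, :]) / 2.0  # prior-whitened
        w, V = np.linalg.eigh(B)
        w = np.maximum(w, 1.0)
        cov_w = V @ np.diag(1.0 / w) @ V.T
        return omega[:, None] * cov_w * omega[None, :]
    except np.linalg.LinAlgError:
        return None


def prediction_interval(
    subject: SubjectDataset,
    pop: PopulationParameters,
    map_result: MapResult,
    level: float = 0.95,
    n_samples: int = 200,
    seed=None,
    mode: str = "weekly",
    t_span: tuple = (-30.0, 180.0),
    grid: np.ndarray | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time prediction bounds around the MAP trajectory.

    Monte-Carlo: eta is sampled from the Laplace approximation of the
    posterior at the MAP (falling back to the prior when the Hessian is
    ill-conditioned), each sample is simulated, and residual error is added;
    the bounds are the corresponding percentiles.  Seed-reproducible.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    names = map_result.parameter_names
    omega = np.array([pop.omega(n) for n in names])
    if names:
        cov = _laplace_covariance(subject, pop, map_result, mode)
        if cov is None:
            cov = np.diag(omega**2)  # prior-predictive fallback
    else:
        cov = np.zeros((0, 0))
    if grid is None:
        grid = np.arange(t_span[0], t_span[1] + 1e-9, 1.0)
    grid = np.asarray(grid, dtype=float)
    regimen, covariates = _fit_inputs(subject, map_result.cutoff_day)
    if names:
        etas = rng.multivariate_normal(map_result.eta, cov, size=n_samples)
        # keep samples inside the plausible prior range (and away from
        # numerically explosive feedback regimes)
        etas = np.clip(etas, -3.5 * omega, 3.5 * omega)
    else:
        etas = np.zeros((n_samples, 0))
    sims = np.full((n_samples, grid.size), np.nan)
    for s in range(n_samples):
        params = _realize(pop, names, etas[s])
        kgt = (params.n_transit + 1) / params.mmt_gt
        if kgt * (params.graft10 / params.feedback_floor) ** params.gamma > 2e3:
            continue  # implausible feedback regime: drop the sample
        traj = simulate_individual(
            params, regimen, covariates, t_span=t_span, grid=grid,
            rtol=rtol, atol=atol,
        )
        f = traj.plt_total
        sims[s] = np.maximum(
            f + pop.residual_error.sigma(f) * rng.standard_normal(grid.size), 0.0
        )
    valid = ~np.isnan(sims[:, 0])
    if valid.sum() < max(10, 0.5 * n_samples):
        raise RuntimeError("too many posterior samples fell in implausible regions")
    if (~valid).any():
        warnings.warn(
            f"dropped {int((~valid).sum())} implausible posterior sample(s)",
            stacklevel=2,
        )
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(sims[valid], alpha, axis=0)
    hi = np.quantile(sims[valid], 1.0 - alpha, axis=0)
    return lo, hi, grid
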