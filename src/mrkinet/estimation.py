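"""Multi-response estimation of the network rate constants.

Given a timecourse of the observable species (everything except the
latent 1,2-enediol), the 15 rate constants are estimated by weighted
least squares.  Responses span six orders of magnitude (sugars in g/g DS,
trace products in ug/g DS), so each response is weighted by the inverse
square of its mean observed value, making the residuals scale-free.

The optimizer works in log10-parameter space — the published constants
span seven orders of magnitude, and a log parameterization turns that
dynamic range into a well-scaled box — using bounded trust-region least
squares with a deterministic central start plus seeded log-uniform
multistarts.  The initial state is anchored to the t = 0 observation
(latent and unobserved species start at zero), and model trajectories use
the closed-form matrix-exponential propagator of the linear system.

Several steps are structurally non-identifiable from these data (sucrose
hydrolysis when its rate is nil; the enediol-to-glucose back reaction,
invisible because the enediol is unmeasured).  Such parameters are
flagged ``indeterminate`` from three symptoms: a vanishing scale-free
sensitivity, an estimate pinned at a box bound, or a confidence half-width
at least as large as the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datamodel import RunConfig, Timecourse
from .errors import EstimationError, ValidationError
from .network import (PARAM_NAMES, RateConstants, ReactionNetwork,
                      RESPONSE_TO_SPECIES, SPECIES, SPECIES_RESPONSE_NAMES,
                      build_mcsj_network, propagate_expm)

#: Scale-free RMS sensitivity below which a parameter is considered
#: structurally invisible: a factor-e change perturbs the (dimensionless,
#: mean-normalized) model output by less than one part in 10^4, far below
#: any plausible measurement precision.
SENSITIVITY_FLOOR = 1e-4


@dataclass(frozen=True)
class EstimationResult:
    """Multi-response fit of the 15 network rate constants."""

    estimates: dict[str, float]
    half_widths: dict[str, float]
    indeterminate: dict[str, bool]
    objective: float
    weights: dict[str, float]
    converged: bool
    n_multistarts: int
    seed: int
    n_residuals: int = 0
    ci_method: str = "linearized"
    start_costs: tuple[float, ...] = ()

    def rate_constants(self, temperature: float = float("nan")) -> RateConstants:
        return RateConstants.from_dict(self.estimates, temperature)


# ---------------------------------------------------------------------------
# data plumbing

def _observation_arrays(data: Timecourse):
    """Species indices, observation matrix and y0 anchored at t = 0."""
    if data.times[0] != 0.0:
        raise ValidationError("network fitting needs a t = 0 sample "
                              "to anchor the initial state")
    latent = SPECIES_RESPONSE_NAMES["ED"]
    species_idx, names, obs_cols = [], [], []
    for name in sorted(data.responses):  # sorted: order-invariant estimates
        if name == latent:
            raise ValidationError(
                "the 1,2-enediol is unobservable and cannot enter the fit"
            )
        sp = RESPONSE_TO_SPECIES.get(name)
        if sp is None:
            raise ValidationError(f"response {name!r} is not a network species")
        species_idx.append(SPECIES.index(sp))
        names.append(name)
        obs_cols.append(np.asarray(data.responses[name].values, dtype=float))
    obs = np.column_stack(obs_cols)  # (n_times, n_responses)
    y0 = np.zeros(len(SPECIES))
    for j, idx in enumerate(species_idx):
        y0[idx] = obs[0, j]
    return names, np.array(species_idx), obs, y0


def default_weights(data: Timecourse) -> dict[str, float]:
    """Inverse-square-mean weights, one per observed response."""
    weights = {}
    latent = SPECIES_RESPONSE_NAMES["ED"]
    for name, series in data.responses.items():
        if name == latent:
            continue
        m = float(np.mean(series.values))
        weights[name] = 1.0 / m**2 if m > 0 else 1.0
    return weights


def _weight_vector(names: Sequence[str],
                   weights: Mapping[str, float]) -> np.ndarray:
    w = []
    for name in names:
        if name not in weights:
            raise ValidationError(f"no weight for response {name!r}")
        if weights[name] <= 0:
            raise ValidationError("weights must be positive")
        w.append(float(weights[name]))
    return np.array(w)


def _residual_vector(kvec: np.ndarray, network: ReactionNetwork,
                     y0: np.ndarray, times: np.ndarray,
                     species_idx: np.ndarray, obs: np.ndarray,
                     sqrt_w: np.ndarray) -> np.ndarray:
    k = RateConstants(tuple(kvec))
    ys = propagate_expm(network, k, y0, times)
    model = ys[:, species_idx]
    return ((model - obs) * sqrt_w).ravel()


def objective(k: RateConstants | Mapping[str, float], data: Timecourse,
              weights: Mapping[str, float] | None = None) -> float:
    """Weighted sum of squared residuals of the network against the data."""
    if not isinstance(k, RateConstants):
        k = RateConstants.from_dict(k)
    names, species_idx, obs, y0 = _observation_arrays(data)
    weights = dict(weights) if weights is not None else default_weights(data)
    sqrt_w = np.sqrt(_weight_vector(names, weights))
    r = _residual_vector(np.array(k.k), build_mcsj_network(), y0,
                         np.asarray(data.times), species_idx, obs, sqrt_w)
    return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# fitting

def fit_network(data: Timecourse, config: RunConfig | None = None,
                weights: Mapping[str, float] | None = None) -> EstimationResult:
    """Estimate k1..k15 from an observed timecourse.

    Runs ``config.multistarts`` bounded least-squares optimizations in
    log10-parameter space (one deterministic central start, the rest
    seeded log-uniform draws) and returns the best optimum, with
    linearized confidence half-widths and indeterminacy flags attached.
    """
    config = config or RunConfig()
    if data.n_points < 4:
        raise ValidationError("network fitting needs at least 4 time points")
    names, species_idx, obs, y0 = _observation_arrays(data)
    if len(names) < 5:
        raise ValidationError("network fitting needs at least 5 observed species")
    weights = dict(weights) if weights is not None else default_weights(data)
    sqrt_w = _weight_vector(names, weights) ** 0.5
    network = build_mcsj_network()
    times = np.asarray(data.times)

    lo = np.full(15, math.log10(config.log_floor))
    hi = np.array([math.log10(config.upper_for(p)) for p in PARAM_NAMES])

    def resid_log(p):
        return _residual_vector(10.0 ** p, network, y0, times,
                                species_idx, obs, sqrt_w)

    rng = np.random.default_rng(config.seed)
    starts = [0.5 * (lo + hi)]
    for _ in range(config.multistarts - 1):
        starts.append(rng.uniform(lo, hi))

    best = None
    diagnostics = []
    for x0 in starts:
        try:
            sol = least_squares(resid_log, x0, bounds=(lo, hi), method="trf",
                                ftol=1e-14, xtol=1e-13, gtol=1e-14,
                                max_nfev=6000)
        except Exception as exc:  # numerical failure in one start
            diagnostics.append({"status": "error", "message": str(exc)})
            continue
        diagnostics.append({"status": int(sol.status), "cost": float(sol.cost)})
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise EstimationError("no optimization start converged", diagnostics)

    k_hat = 10.0 ** best.x
    estimates = dict(zip(PARAM_NAMES, (float(v) for v in k_hat)))
    result = EstimationResult(
        estimates=estimates,
        half_widths={p: float("nan") for p in PARAM_NAMES},
        indeterminate={p: False for p in PARAM_NAMES},
        objective=float(2.0 * best.cost),
        weights=weights,
        converged=True,
        n_multistarts=config.multistarts,
        seed=int(config.seed),
        n_residuals=obs.size,
        start_costs=tuple(d.get("cost", math.inf) for d in diagnostics),
    )
    return confidence_intervals(result, data, method="linearized",
                                config=config)


# ---------------------------------------------------------------------------
# uncertainty

def _jacobian(kvec: np.ndarray, network: ReactionNetwork, y0: np.ndarray,
              times: np.ndarray, species_idx: np.ndarray, obs: np.ndarray,
              sqrt_w: np.ndarray) -> np.ndarray:
    """Forward-difference Jacobian of the weighted residuals w.r.t. k."""
    r0 = _residual_vector(kvec, network, y0, times, species_idx, obs, sqrt_w)
    J = np.empty((r0.size, kvec.size))
    for j in range(kvec.size):
        step = max(1e-6 * abs(kvec[j]), 1e-10)
        kp = kvec.copy()
        kp[j] += step
        J[:, j] = (_residual_vector(kp, network, y0, times, species_idx,
                                    obs, sqrt_w) - r0) / step
    return J


def confidence_intervals(fit: EstimationResult, data: Timecourse,
                         method: str = "linearized",
                         config: RunConfig | None = None,
                         n_boot: int = 200) -> EstimationResult:
    """Attach 95% half-widths and indeterminacy flags to a converged fit.

    ``linearized`` uses the finite-difference Jacobian at the estimate,
    half-width 1.96*sqrt(diag(pinv(J'J)*s^2)); ``bootstrap`` refits
    ``n_boot`` residual-resampled datasets (seeded) and takes percentile
    intervals.  A singular information matrix flags the affected
    parameters rather than raising.
    """
    if method not in ("linearized", "bootstrap"):
        raise ValidationError(f"unknown CI method {method!r}")
    config = config or RunConfig()
    names, species_idx, obs, y0 = _observation_arrays(data)
    sqrt_w = _weight_vector(names, fit.weights) ** 0.5
    network = build_mcsj_network()
    times = np.asarray(data.times)
    kvec = np.array([fit.estimates[p] for p in PARAM_NAMES])

    J = _jacobian(kvec, network, y0, times, species_idx, obs, sqrt_w)
    n, p = J.shape
    r = _residual_vector(kvec, network, y0, times, species_idx, obs, sqrt_w)
    s2 = float(np.dot(r, r)) / max(n - p, 1)

    # scale-free sensitivity of each parameter (log-space column norm)
    sens = np.linalg.norm(J * kvec[None, :], axis=0) / math.sqrt(n)

    if method == "linearized":
        JtJ = J.T @ J
        cov = np.linalg.pinv(JtJ, rcond=1e-12) * s2
        half = 1.96 * np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        rng = np.random.default_rng(fit.seed + 7919)
        resid = (obs - _model_values(kvec, network, y0, times, species_idx))
        boot = np.empty((n_boot, 15))
        lo = np.full(15, math.log10(config.log_floor))
        hi = np.array([math.log10(config.upper_for(q)) for q in PARAM_NAMES])
        x_hat = np.clip(np.log10(np.maximum(kvec, config.log_floor)), lo, hi)
        for b in range(n_boot):
            idx = rng.integers(0, obs.shape[0], size=obs.shape[0])
            obs_b = _model_values(kvec, network, y0, times, species_idx) \
                + resid[idx, :]
            obs_b = np.clip(obs_b, 0.0, None)
            y0_b = y0.copy()
            for j, si in enumerate(species_idx):
                y0_b[si] = obs_b[0, j]

            def resid_log(q, _obs=obs_b, _y0=y0_b):
                return _residual_vector(10.0 ** q, network, _y0, times,
                                        species_idx, _obs, sqrt_w)

            sol = least_squares(resid_log, x_hat, bounds=(lo, hi),
                                method="trf", ftol=1e-10, xtol=1e-10,
                                max_nfev=400)
            boot[b] = 10.0 ** sol.x
        q_lo, q_hi = np.percentile(boot, [2.5, 97.5], axis=0)
        half = (q_hi - q_lo) / 2.0

    flags = {}
    half_widths = {}
    max_sens = float(sens.max()) if sens.size else 0.0
    for j, pname in enumerate(PARAM_NAMES):
        hw = float(half[j])
        est = kvec[j]
        at_lower = est <= 10.0 * config.log_floor
        at_upper = est >= 0.95 * config.upper_for(pname)
        insensitive = sens[j] < SENSITIVITY_FLOOR \
            or (max_sens > 0 and sens[j] < 1e-10 * max_sens)
        flags[pname] = bool(insensitive or at_lower or at_upper
                            or hw >= est)
        half_widths[pname] = hw
    return replace(fit, half_widths=half_widths, indeterminate=flags,
                   ci_method=method)


def _model_values(kvec, network, y0, times, species_idx):
    ys = propagate_expm(network, RateConstants(tuple(kvec)), y0, times)
    return ys[:, species_idx]
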