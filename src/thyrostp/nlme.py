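"""Nonlinear mixed-effects estimation of population biokinetic parameters.

Hierarchical model: patient ``i`` has parameters
``theta_i = exp(mu + eta_i)`` with ``eta_i ~ N(0, diag(omega^2))`` on the
log scale (log-normal individual parameters, which enforces positivity),
and observations

    y_ij = f(t_ij; theta_i) + g_ij * eps_ij,      eps_ij ~ N(0, 1)

where ``f`` is a sum-of-exponentials retention model and ``g`` is a
proportional, additive, or combined residual error.

Estimation is an alternating (Lindstrom–Bates-style) scheme:

1. *PNLS step* — jointly optimize the fixed effects ``mu`` and all random
   effects ``eta_i`` of the penalized weighted least-squares objective
   (batched Levenberg–Marquardt over patients, damped Gauss–Newton for
   ``mu``).
2. *Variance step* — update ``omega^2`` from the empirical-Bayes modes plus
   their Laplace posterior variances, and the residual sigma by (profile)
   maximum likelihood.

The reported objective is the Laplace approximation of the −2 log marginal
likelihood, evaluated at the empirical-Bayes modes; the fit tracks the
objective across iterations and returns the best visited state, so the
returned objective is never worse than at any screened starting point.

Multi-start: ``n_starts`` log-uniform fixed-effect vectors are screened
with a cheap pooled weighted least-squares objective and the best
``n_refine`` are refined with the full scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import BiokineticRecord
from .soef import SOEFParams, analytic_tia

__all__ = [
    "FitConfig",
    "PopulationEstimate",
    "IndividualEstimate",
    "EstimationError",
    "random_starts",
    "fit_population",
    "empirical_bayes",
]

_LOG_2PI = math.log(2.0 * math.pi)


class EstimationError(RuntimeError):
    """Raised when estimation cannot proceed (degenerate input)."""


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the population fit.

    Notes on defaults: start bounds span physiologic uptake/washout scales
    (rates 1e-5 to 1 /h, blood-pool amplitude 1e-4 to 0.5); the residual
    model is proportional with a small prediction floor ``f_floor`` inside
    the variance so weights stay finite; convergence is declared when the
    relative change of the objective falls below ``obj_tol``.
    """

    error_model: str = "proportional"
    sigma_init: float = 0.1
    sigma_add: float = 0.002  # fixed additive sd in the combined model
    omega_init: float = 0.09  # initial log-scale variance (30% CV)
    n_starts: int = 1000
    n_refine: int = 5
    lambda_bounds: tuple[float, float] = (1e-5, 1.0)
    a1_bounds: tuple[float, float] = (1e-4, 0.5)
    max_outer: int = 500
    obj_tol: float = 1e-6
    max_inner: int = 30
    inner_tol: float = 1e-9
    pnls_rounds: int = 2
    f_floor: float = 1e-4
    sigma_floor: float = 1e-6
    omega_floor: float = 1e-10
    seed: int = 0
    stp_mode: str = "joint_refit"  # or "frozen_prior"
    warm_only: bool = False  # with a warm start, skip the random-start refinement
    laplace_polish: bool = True  # final direct minimization of the Laplace
    # objective over the fixed effects (the alternating scheme maximizes the
    # penalized data likelihood, which is slightly biased for strongly
    # nonlinear parameters; the polish removes most of that bias)
    polish_maxiter: int = 300

    def __post_init__(self) -> None:
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.stp_mode not in ("joint_refit", "frozen_prior"):
            raise ValueError(f"unknown stp_mode {self.stp_mode!r}")
        if self.n_starts < 1 or self.n_refine < 1:
            raise ValueError("n_starts and n_refine must be >= 1")

    def bounds_for(self, model_id: str) -> np.ndarray:
        rows = [self.lambda_bounds] * 3
        if model_id == "a4c":
            rows.append(self.a1_bounds)
        return np.asarray(rows, dtype=float)


@dataclass
class PopulationEstimate:
    """Result of a population fit."""

    model_id: str
    fixed_effects: SOEFParams
    omega2: np.ndarray  # log-scale random-effect variances, model order
    sigma_prop: float
    sigma_add: float
    error_model: str
    objective: float
    converged: bool
    n_starts_used: int
    seed: int
    n_iter: int
    n_patients: int
    n_obs: int
    f_floor: float
    start_objectives: tuple[float, ...] = ()
    patient_ids: tuple[str, ...] = ()
    individual_eta: np.ndarray | None = field(default=None, repr=False)

    @property
    def mu(self) -> np.ndarray:
        return np.log(self.fixed_effects.as_array())

    def individual_params(self, patient_id: str) -> SOEFParams:
        """Empirical-Bayes parameters of a patient seen by the fit."""
        i = self.patient_ids.index(patient_id)
        theta = np.exp(self.mu + self.individual_eta[i])
        return self.fixed_effects.with_values(theta)


@dataclass(frozen=True)
class IndividualEstimate:
    """Empirical-Bayes (MAP) individual parameters and their analytic TIA."""

    patient_id: str
    params: SOEFParams
    tia: float
    eta: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# data marshalling

@dataclass
class _Data:
    ids: tuple[str, ...]
    t: np.ndarray  # (n, m) padded
    y: np.ndarray  # (n, m)
    mask: np.ndarray  # (n, m) bool
    model4: bool

    @property
    def n(self) -> int:
        return len(self.ids)


def _prepare(records: Sequence[BiokineticRecord], model_id: str) -> _Data:
    by_patient: dict[str, list[BiokineticRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    ids = tuple(by_patient)
    if any(len(v) == 0 for v in by_patient.values()):
        raise ValueError("every patient needs at least one observation")
    m = max(len(v) for v in by_patient.values())
    n = len(ids)
    t = np.ones((n, m))
    y = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for i, pid in enumerate(ids):
        rs = sorted(by_patient[pid], key=lambda r: r.time_h)
        t[i, : len(rs)] = [r.time_h for r in rs]
        y[i, : len(rs)] = [r.retention for r in rs]
        mask[i, : len(rs)] = True
    if not np.any(y[mask] > 0.0):
        raise EstimationError("all observations are zero")
    return _Data(ids, t, y, mask, model_id == "a4c")


# ---------------------------------------------------------------------------
# batched model evaluation

def _f_batch(theta: np.ndarray, t: np.ndarray, model4: bool) -> np.ndarray:
    """Retention for a batch: theta (n, p), t (n, m) -> (n, m)."""
    from .soef import LAMBDA_PHYS_PER_H, _pq

    lp = LAMBDA_PHYS_PER_H
    l1 = theta[:, 0:1]
    l2 = theta[:, 1:2]
    l3 = theta[:, 2:3]
    a1 = theta[:, 3:4] if model4 else 0.0
    s = l1 + l2
    e3 = np.exp(-(l3 + lp) * t)
    es = np.exp(-(s + lp) * t)
    P, _ = _pq((s - l3) * t, e3, es)
    return l1 * t * P + a1 * es


def _f_grad_batch(theta: np.ndarray, t: np.ndarray, model4: bool):
    """Retention and gradient w.r.t. theta: (n, m) and (n, m, p)."""
    from .soef import LAMBDA_PHYS_PER_H, _pq

    lp = LAMBDA_PHYS_PER_H
    l1 = theta[:, 0:1]
    l2 = theta[:, 1:2]
    l3 = theta[:, 2:3]
    a1 = theta[:, 3:4] if model4 else 0.0
    s = l1 + l2
    e3 = np.exp(-(l3 + lp) * t)
    es = np.exp(-(s + lp) * t)
    P, Q = _pq((s - l3) * t, e3, es)
    f = l1 * t * P + a1 * es
    d1 = t * (P + l1 * t * Q) - a1 * t * es
    d2 = l1 * t * t * Q - a1 * t * es
    d3 = -l1 * t * t * (P + Q)
    cols = [d1, d2, d3]
    if model4:
        cols.append(es)
    return f, np.stack(cols, axis=-1)


def _error_var(f: np.ndarray, cfg_like) -> np.ndarray:
    """Residual variance g^2 given predictions."""
    h2 = f * f + cfg_like.f_floor**2
    em = cfg_like.error_model
    sp2 = cfg_like.sigma_prop**2
    sa2 = cfg_like.sigma_add**2
    if em == "proportional":
        return sp2 * h2
    if em == "additive":
        return np.broadcast_to(np.asarray(sa2), f.shape).copy()
    return sp2 * h2 + sa2


@dataclass
class _Hyper:
    """Mutable hyper-parameter state during estimation."""

    error_model: str
    sigma_prop: float
    sigma_add: float
    f_floor: float


_ETA_CLIP = 35.0


def _theta_of(mu: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(mu[None, :] + eta, -_ETA_CLIP, 3.0))


def _map_objective(mu, eta, omega2, hyp, data: _Data) -> np.ndarray:
    """Per-patient penalized objective (obs -2ll pieces + prior quadratic)."""
    theta = _theta_of(mu, eta)
    f = _f_batch(theta, data.t, data.model4)
    g2 = _error_var(f, hyp)
    r = data.y - f
    obs = np.sum(data.mask * (r * r / g2 + np.log(g2)), axis=1)
    prior = np.sum(eta * eta / omega2[None, :], axis=1)
    return obs + prior


def _eta_map(mu, eta0, omega2, hyp, data: _Data, max_iter, tol):
    """Batched Levenberg-Marquardt MAP estimation of all random effects."""
    n, p = eta0.shape
    eta = eta0.copy()
    damp = np.full(n, 1e-3)
    obj = _map_objective(mu, eta, omega2, hyp, data)
    eye = np.eye(p)
    for _ in range(max_iter):
        theta = _theta_of(mu, eta)
        f, J = _f_grad_batch(theta, data.t, data.model4)
        g2 = _error_var(f, hyp)
        w = data.mask / g2
        # gradient in eta-space: chain rule theta = exp(mu+eta)
        Jt = J * theta[:, None, :]
        r = data.y - f
        A = np.einsum("nmp,nm,nmq->npq", Jt, w, Jt)
        b = np.einsum("nmp,nm->np", Jt, w * r) - eta / omega2[None, :]
        A = A + np.diag(1.0 / omega2)[None, :, :]
        diagA = np.einsum("npp->np", A)
        M = A + damp[:, None, None] * (diagA[:, :, None] * eye[None, :, :])
        try:
            step = np.linalg.solve(M, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(M + 1e-8 * eye[None, :, :], b[..., None])[..., 0]
        cand = np.clip(eta + step, -_ETA_CLIP, _ETA_CLIP)
        obj_c = _map_objective(mu, cand, omega2, hyp, data)
        better = obj_c < obj
        eta = np.where(better[:, None], cand, eta)
        obj = np.where(better, obj_c, obj)
        damp = np.where(better, damp * 0.3, damp * 5.0)
        damp = np.clip(damp, 1e-12, 1e10)
        max_step = np.max(np.abs(step[better])) if np.any(better) else 0.0
        if max_step < tol and np.all(~better | (np.abs(step).max(axis=1) < tol)):
            break
        if not np.any(better) and np.all(damp > 1e8):
            break
    return eta, obj


def _pooled_objective(mu, eta, hyp, data: _Data) -> float:
    theta = _theta_of(mu, eta)
    f = _f_batch(theta, data.t, data.model4)
    g2 = _error_var(f, hyp)
    r = data.y - f
    return float(np.sum(data.mask * (r * r / g2 + np.log(g2))))


def _mu_step(mu, eta, hyp, data: _Data, max_iter=8, tol=1e-10):
    """Damped Gauss-Newton update of the fixed effects with eta fixed."""
    p = mu.size
    damp = 1e-4
    obj = _pooled_objective(mu, eta, hyp, data)
    eye = np.eye(p)
    for _ in range(max_iter):
        theta = _theta_of(mu, eta)
        f, J = _f_grad_batch(theta, data.t, data.model4)
        g2 = _error_var(f, hyp)
        w = data.mask / g2
        Jt = J * theta[:, None, :]
        r = data.y - f
        A = np.einsum("nmp,nm,nmq->pq", Jt, w, Jt)
        b = np.einsum("nmp,nm->p", Jt, w * r)
        accepted = False
        for _try in range(8):
            M = A + damp * np.diag(np.diag(A)) + 1e-14 * eye
            try:
                step = np.linalg.solve(M, b)
            except np.linalg.LinAlgError:
                damp *= 10.0
                continue
            cand = np.clip(mu + step, -_ETA_CLIP, 3.0)
            obj_c = _pooled_objective(cand, eta, hyp, data)
            if obj_c < obj:
                mu, obj = cand, obj_c
                damp = max(damp * 0.3, 1e-12)
                accepted = True
                break
            damp *= 5.0
        if not accepted or np.max(np.abs(step)) < tol:
            break
    return mu


def _posterior_info(mu, eta, omega2, hyp, data: _Data):
    """Gauss-Newton Hessian A_i = J'WJ + Omega^-1 per patient."""
    theta = _theta_of(mu, eta)
    f, J = _f_grad_batch(theta, data.t, data.model4)
    g2 = _error_var(f, hyp)
    w = data.mask / g2
    Jt = J * theta[:, None, :]
    A = np.einsum("nmp,nm,nmq->npq", Jt, w, Jt)
    A = A + np.diag(1.0 / omega2)[None, :, :]
    return A, f, g2


def _laplace_objective(mu, eta, omega2, hyp, data: _Data) -> float:
    A, f, g2 = _posterior_info(mu, eta, omega2, hyp, data)
    r = data.y - f
    obs = np.sum(data.mask * (r * r / g2 + np.log(g2) + _LOG_2PI))
    prior = np.sum(eta * eta / omega2[None, :]) + data.n * np.sum(np.log(omega2))
    sign, logdet = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        return float("inf")
    return float(obs + prior + np.sum(logdet))


def _variance_proposal(mu, eta, omega2, hyp, data: _Data, cfg: FitConfig):
    """EM-style update proposals for omega^2 and the residual sigma.

    Both use the Laplace posterior covariance ``V_i`` of the random
    effects: omega^2 gets the usual ``mean(eta^2 + V_kk)``, and the
    residual second moments get the propagated-model-variance correction
    ``diag(J V J')`` — without it the MAP residuals understate sigma
    (shrinkage) and the variance components drift.
    """
    theta = _theta_of(mu, eta)
    f, J = _f_grad_batch(theta, data.t, data.model4)
    g2 = _error_var(f, hyp)
    w = data.mask / g2
    Jt = J * theta[:, None, :]
    A = np.einsum("nmp,nm,nmq->npq", Jt, w, Jt) + np.diag(1.0 / omega2)[None, :, :]
    V = np.linalg.inv(A)
    vdiag = np.einsum("npp->np", V)
    omega2_new = np.maximum(np.mean(eta * eta + vdiag, axis=0), cfg.omega_floor)

    c = np.einsum("nmp,npq,nmq->nm", Jt, V, Jt)
    r2c = (data.y - f) ** 2 + c
    h2 = f * f + cfg.f_floor**2
    m = data.mask
    nobs = m.sum()
    sp, sa = hyp.sigma_prop, hyp.sigma_add
    if hyp.error_model == "proportional":
        sp = max(math.sqrt(float(np.sum(m * r2c / h2)) / nobs), cfg.sigma_floor)
    elif hyp.error_model == "additive":
        sa = max(math.sqrt(float(np.sum(m * r2c)) / nobs), cfg.sigma_floor)
    else:  # combined: sigma_add fixed, profile sigma_prop by 1-d MLE
        from scipy.optimize import minimize_scalar

        sa2 = hyp.sigma_add**2
        r2m = r2c[m]
        h2m = h2[m]

        def nll(log_sp):
            g2_ = math.exp(2.0 * log_sp) * h2m + sa2
            return float(np.sum(r2m / g2_ + np.log(g2_)))

        res = minimize_scalar(
            nll,
            bounds=(math.log(cfg.sigma_floor), math.log(10.0)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        sp = max(math.exp(res.x), cfg.sigma_floor)
    return omega2_new, sp, sa


@dataclass
class _EMResult:
    mu: np.ndarray
    eta: np.ndarray
    omega2: np.ndarray
    hyp: _Hyper
    objective: float
    initial_objective: float
    converged: bool
    n_iter: int


def _em_fit(mu0, omega2_0, hyp0: _Hyper, data: _Data, cfg: FitConfig) -> _EMResult:
    mu = mu0.copy()
    omega2 = omega2_0.copy()
    hyp = _Hyper(hyp0.error_model, hyp0.sigma_prop, hyp0.sigma_add, hyp0.f_floor)
    eta = np.zeros((data.n, mu.size))

    # objective at the starting point itself (inner MAP only)
    eta, _ = _eta_map(mu, eta, omega2, hyp, data, cfg.max_inner, cfg.inner_tol)
    initial_obj = _laplace_objective(mu, eta, omega2, hyp, data)
    best = (initial_obj, mu.copy(), eta.copy(), omega2.copy(),
            _Hyper(hyp.error_model, hyp.sigma_prop, hyp.sigma_add, hyp.f_floor))

    prev_obj = initial_obj
    converged = False
    it = 0
    for it in range(1, cfg.max_outer + 1):
        for _ in range(cfg.pnls_rounds):
            eta, _ = _eta_map(mu, eta, omega2, hyp, data, cfg.max_inner, cfg.inner_tol)
            mu = _mu_step(mu, eta, hyp, data)
        # re-center the random effects (removes mu/eta aliasing)
        shift = eta.mean(axis=0)
        mu = np.clip(mu + shift, -_ETA_CLIP, 3.0)
        eta = eta - shift
        eta, _ = _eta_map(mu, eta, omega2, hyp, data, cfg.max_inner, cfg.inner_tol)

        obj = _laplace_objective(mu, eta, omega2, hyp, data)
        if obj < best[0]:
            best = (obj, mu.copy(), eta.copy(), omega2.copy(),
                    _Hyper(hyp.error_model, hyp.sigma_prop, hyp.sigma_add, hyp.f_floor))

        # variance step, backtracked against the Laplace objective so the
        # outer iteration is monotone in the reported criterion
        om_prop, sp_prop, sa_prop = _variance_proposal(mu, eta, omega2, hyp, data, cfg)
        log_om, log_om_p = np.log(omega2), np.log(om_prop)
        improved = False
        for frac in (1.0, 0.5, 0.25, 0.125):
            om_c = np.exp(log_om + frac * (log_om_p - log_om))
            hyp_c = _Hyper(
                hyp.error_model,
                math.exp(
                    math.log(hyp.sigma_prop)
                    + frac * (math.log(sp_prop) - math.log(hyp.sigma_prop))
                ),
                math.exp(
                    math.log(max(hyp.sigma_add, cfg.sigma_floor))
                    + frac
                    * (
                        math.log(max(sa_prop, cfg.sigma_floor))
                        - math.log(max(hyp.sigma_add, cfg.sigma_floor))
                    )
                ),
                hyp.f_floor,
            )
            eta_c, _ = _eta_map(mu, eta, om_c, hyp_c, data, cfg.max_inner, cfg.inner_tol)
            obj_c = _laplace_objective(mu, eta_c, om_c, hyp_c, data)
            if obj_c < obj:
                omega2, hyp, eta, obj = om_c, hyp_c, eta_c, obj_c
                improved = True
                break
        if improved and obj < best[0]:
            best = (obj, mu.copy(), eta.copy(), omega2.copy(),
                    _Hyper(hyp.error_model, hyp.sigma_prop, hyp.sigma_add, hyp.f_floor))
        if abs(obj - prev_obj) < cfg.obj_tol * (abs(obj) + 1.0):
            converged = True
            break
        prev_obj = obj

    obj, mu, eta, omega2, hyp = best
    if cfg.laplace_polish:
        mu, eta, obj = _laplace_polish(mu, eta, omega2, hyp, data, cfg, obj)
    return _EMResult(mu, eta, omega2, hyp, obj, initial_obj, converged, it)


def _laplace_polish(mu, eta, omega2, hyp, data: _Data, cfg: FitConfig, obj0):
    """Directly minimize the Laplace objective over the fixed effects.

    The PNLS/variance alternation targets the penalized data likelihood;
    its stationary point ignores the curvature (log-determinant) term of
    the marginal and is mildly biased for strongly nonlinear parameters
    such as the washout rate.  A derivative-free polish of mu against the
    full Laplace objective (random effects re-optimized at every trial
    point) removes most of that bias at modest cost.
    """
    from scipy.optimize import minimize

    state = {"eta": eta.copy()}

    def objective(m):
        e, _ = _eta_map(m, state["eta"], omega2, hyp, data, cfg.max_inner,
                        cfg.inner_tol)
        state["eta"] = e
        return _laplace_objective(m, e, omega2, hyp, data)

    res = minimize(
        objective,
        mu,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": cfg.polish_maxiter},
    )
    if res.fun < obj0:
        eta_f, _ = _eta_map(res.x, state["eta"], omega2, hyp, data,
                            cfg.max_inner, cfg.inner_tol)
        return np.asarray(res.x), eta_f, float(res.fun)
    return mu, eta, obj0


# ---------------------------------------------------------------------------
# public API

def random_starts(n_starts: int, bounds: np.ndarray, seed: int) -> np.ndarray:
    """Draw ``n_starts`` log-uniform parameter vectors within ``bounds``.

    ``bounds`` is ``(p, 2)`` with positive finite columns ``(low, high)``.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must have shape (p, 2)")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo <= 0) or np.any(hi <= lo) or not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite, positive and increasing")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_starts, bounds.shape[0]))
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def _screen_starts(starts: np.ndarray, data: _Data, n_refine: int) -> np.ndarray:
    """Rank starts by a cheap pooled relative least-squares objective."""
    yf = data.y[data.mask]
    tf = data.t[data.mask]
    delta = max(0.05 * float(yf.mean()), 1e-3)
    w = 1.0 / (yf + delta) ** 2
    f = _f_batch(starts, np.broadcast_to(tf, (starts.shape[0], tf.size)), data.model4)
    sse = np.sum(w[None, :] * (f - yf[None, :]) ** 2, axis=1)
    order = np.argsort(sse)
    return starts[order[:n_refine]]


def fit_population(
    records: Sequence[BiokineticRecord],
    model_id: str = "a4c",
    config: FitConfig = FitConfig(),
    warm_start: "PopulationEstimate | None" = None,
) -> PopulationEstimate:
    """Fit the population model to multi-patient biokinetic records.

    Deterministic given ``config.seed``.  Non-convergence within
    ``max_outer`` iterations is flagged on the result, not raised.
    ``warm_start`` adds a previously fitted population state to the refined
    candidate set (used to chain the many closely related fits of a
    single-time-point grid).
    """
    if model_id not in ("a4c", "a3b"):
        raise ValueError(f"unknown model_id {model_id!r}")
    data = _prepare(records, model_id)
    if data.n < 2:
        raise ValueError("need at least 2 patients for a population fit")
    p = 4 if model_id == "a4c" else 3

    candidates: list[tuple[np.ndarray, np.ndarray, _Hyper]] = []
    refine = []
    if not (config.warm_only and warm_start is not None):
        bounds = config.bounds_for(model_id)
        starts = random_starts(config.n_starts, bounds, config.seed)
        refine = _screen_starts(starts, data, config.n_refine)
    for s in refine:
        candidates.append(
            (
                np.log(s),
                np.full(p, config.omega_init),
                _Hyper(config.error_model, config.sigma_init, config.sigma_add,
                       config.f_floor),
            )
        )
    if warm_start is not None:
        if warm_start.model_id != model_id:
            raise ValueError("warm_start model_id mismatch")
        candidates.insert(
            0,
            (
                warm_start.mu.copy(),
                warm_start.omega2.copy(),
                _Hyper(warm_start.error_model, warm_start.sigma_prop,
                       warm_start.sigma_add, warm_start.f_floor),
            ),
        )

    best: _EMResult | None = None
    start_objs = []
    for mu0, om0, hyp0 in candidates:
        res = _em_fit(mu0, om0, hyp0, data, config)
        start_objs.append(res.initial_objective)
        if best is None or res.objective < best.objective:
            best = res

    theta_pop = np.exp(best.mu)
    fixed = SOEFParams(
        *(theta_pop[:3]),
        a1=float(theta_pop[3]) if p == 4 else 0.0,
        model_id=model_id,
    )
    return PopulationEstimate(
        model_id=model_id,
        fixed_effects=fixed,
        omega2=best.omega2,
        sigma_prop=best.hyp.sigma_prop,
        sigma_add=best.hyp.sigma_add,
        error_model=config.error_model,
        objective=best.objective,
        converged=best.converged,
        n_starts_used=config.n_starts,
        seed=config.seed,
        n_iter=best.n_iter,
        n_patients=data.n,
        n_obs=int(data.mask.sum()),
        f_floor=config.f_floor,
        start_objectives=tuple(start_objs),
        patient_ids=data.ids,
        individual_eta=best.eta,
    )


def empirical_bayes(
    population: PopulationEstimate,
    patient_records: Sequence[BiokineticRecord],
    max_inner: int = 60,
    inner_tol: float = 1e-11,
) -> IndividualEstimate:
    """Maximum-a-posteriori individual parameters under a fitted population.

    The mode of the conditional distribution of the patient's log-parameters
    given their observations, with the fitted population as prior; the
    analytic TIA of the mode is attached.
    """
    recs = list(patient_records)
    if not recs:
        raise ValueError("patient has no observations")
    pids = {r.patient_id for r in recs}
    if len(pids) != 1:
        raise ValueError(f"records from multiple patients: {sorted(pids)}")
    data = _prepare(recs, population.model_id)
    hyp = _Hyper(population.error_model, population.sigma_prop,
                 population.sigma_add, population.f_floor)
    mu = population.mu
    eta0 = np.zeros((1, mu.size))
    eta, _ = _eta_map(mu, eta0, population.omega2, hyp, data, max_inner, inner_tol)
    theta = np.exp(np.clip(mu + eta[0], -_ETA_CLIP, 3.0))
    params = population.fixed_effects.with_values(theta)
    return IndividualEstimate(
        patient_id=recs[0].patient_id,
        params=params,
        tia=analytic_tia(params),
        eta=eta[0],
    )
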