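"""Empirical-Bayes mixed-effects estimation of agent parameters.

Each subject's seven parameters are estimated by maximum a posteriori (MAP)
optimisation on the unconstrained scale under an independent-Gaussian
population prior; the prior's mean and variance are re-estimated by
expectation-maximisation, with the E-step approximated by a Laplace
(inverse-Hessian) covariance around each subject's MAP.  This is the standard
hierarchical random-effects scheme for behavioural model fitting: subjects
with noisy data are shrunk toward the population, and the population moments
are informed by all subjects jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .agent import (
    PARAM_NAMES,
    TrialRecord,
    negloglik,
    trials_to_arrays,
    untransform_params,
)
from .task import TaskConfig

__all__ = [
    "PopulationPrior",
    "SubjectFit",
    "map_fit",
    "em_fit",
    "laplace_evidence",
    "summarize_population",
]

SIGMA_FLOOR = 1e-3
HESS_STEP = 1e-4
EIG_FLOOR = 1e-6

# optimizer box on the unconstrained scale: log-betas, logit-rates, raw p;
# generous enough to be non-binding for any behaviourally plausible subject
BOUNDS_LO = np.array([-8.0, -8.0, -12.0, -12.0, -12.0, -12.0, -20.0])
BOUNDS_HI = np.array([8.0, 8.0, 12.0, 12.0, 12.0, 12.0, 20.0])


@dataclass(frozen=True)
class PopulationPrior:
    """Diagonal Gaussian over unconstrained parameters (mu, sigma per parameter)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != (7,) or sigma.shape != (7,):
            raise ValueError("mu and sigma must each have 7 entries")
        if (sigma <= 0).any():
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @classmethod
    def default(cls) -> "PopulationPrior":
        """Weakly informative starting prior: broad Gaussians around mild values."""
        mu = np.array([np.log(3.0), np.log(3.0), 0.0, 0.0, 0.0, 0.0, 0.0])
        sigma = np.full(7, 2.0)
        return cls(mu, sigma)


@dataclass
class SubjectFit:
    map_estimate: np.ndarray
    laplace_cov: np.ndarray = field(repr=False)
    nll_at_map: float
    penalized_obj: float
    converged: bool

    @property
    def params_model_scale(self):
        return untransform_params(self.map_estimate)


def _penalized(x: np.ndarray, arrays, prior: PopulationPrior, config: TaskConfig) -> float:
    params = untransform_params(x)
    z = (x - prior.mu) / prior.sigma
    return negloglik(params, arrays, config) + 0.5 * float(z @ z)


def _fd_hessian(f, x: np.ndarray, h: float = HESS_STEP) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def _psd_inverse(H: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Inverse of the PSD repair of H (symmetrise, floor eigenvalues)."""
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    w = np.maximum(w, floor)
    return (V / w) @ V.T


def map_fit(
    trials: list[TrialRecord],
    prior: PopulationPrior,
    starts: int = 10,
    seed: int | np.random.Generator = 0,
    config: TaskConfig | None = None,
    x0_extra: np.ndarray | None = None,
) -> SubjectFit:
    """Multi-start MAP fit of one subject on the unconstrained scale.

    Minimises negloglik(theta) - sum_k log N(theta_k; mu_k, sigma_k^2) with
    L-BFGS-B from ``starts`` seeded initial points (prior mean first, the rest
    perturbed by the prior s.d.); the best optimum is kept.  ``x0_extra`` adds
    a warm-start point (used by :func:`em_fit` across iterations).  The
    Laplace covariance is the inverse finite-difference Hessian at the
    optimum, repaired to be positive definite.
    """
    if not trials:
        raise ValueError("cannot fit an empty trial sequence")
    if starts < 1:
        raise ValueError("starts must be >= 1")
    config = config or TaskConfig()
    arrays = trials_to_arrays(trials) if not isinstance(trials, tuple) else trials
    rng = np.random.default_rng(seed)

    def objective(x):
        return _penalized(x, arrays, prior, config)

    x0s = [prior.mu.copy()]
    if x0_extra is not None:
        x0s.append(np.asarray(x0_extra, dtype=float))
    while len(x0s) < starts + (x0_extra is not None):
        x0s.append(prior.mu + prior.sigma * rng.standard_normal(7) * 0.5)

    best, best_obj, any_ok = None, np.inf, False
    for x0 in x0s:
        res = minimize(objective, np.clip(x0, BOUNDS_LO, BOUNDS_HI),
                       method="L-BFGS-B", bounds=list(zip(BOUNDS_LO, BOUNDS_HI)),
                       options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8})
        if np.isfinite(res.fun) and res.fun < best_obj:
            best, best_obj = res, res.fun
            any_ok = any_ok or res.success
    if best is None:
        raise RuntimeError("all optimizer starts returned non-finite objectives")
    xhat = best.x
    cov = _psd_inverse(_fd_hessian(objective, xhat))
    return SubjectFit(
        map_estimate=xhat,
        laplace_cov=cov,
        nll_at_map=negloglik(untransform_params(xhat), arrays, config),
        penalized_obj=best_obj,
        converged=bool(any_ok),
    )


def laplace_evidence(fit: SubjectFit, prior: PopulationPrior) -> float:
    """Laplace approximation to one subject's log marginal likelihood.

    log p(data | prior) ~ -penalized_obj - sum_k log sigma_k
                          + 0.5 log det(laplace_cov).
    Used as a convergence diagnostic for EM (non-decreasing within tolerance).
    """
    sign, logdet = np.linalg.slogdet(fit.laplace_cov)
    return float(-fit.penalized_obj - np.log(prior.sigma).sum() + 0.5 * logdet)


def em_fit(
    cohort: list[list[TrialRecord]],
    init_prior: PopulationPrior | None = None,
    max_iter: int = 10,
    tol: float = 1e-2,
    starts: int = 10,
    seed: int = 0,
    config: TaskConfig | None = None,
    verbose: bool = False,
    return_history: bool = False,
):
    """Expectation-maximisation over the population prior.

    E-step: MAP-fit every subject under the current prior (multi-start on the
    first iteration, warm starts from the previous MAPs afterwards).
    M-step: moment updates
    mu_k = mean_i(theta_ik), sigma_k^2 = mean_i(theta_ik^2 + cov_ikk) - mu_k^2,
    with sigma floored at 1e-3.  Stops when max |delta mu| < tol.
    """
    if len(cohort) < 2:
        raise ValueError("em_fit needs at least 2 subjects")
    prior = init_prior or PopulationPrior.default()
    config = config or TaskConfig()
    arrays = [trials_to_arrays(t) for t in cohort]
    ss = np.random.SeedSequence(seed)
    fits: list[SubjectFit] = []
    prev_maps: list[np.ndarray] | None = None
    history: list[dict] = []

    for it in range(max_iter):
        child_seeds = ss.spawn(len(cohort))
        it_starts = starts if it == 0 else 2
        fits = [
            map_fit(
                arr, prior, starts=it_starts,
                seed=np.random.default_rng(cs), config=config,
                x0_extra=None if prev_maps is None else prev_maps[i],
            )
            for i, (arr, cs) in enumerate(zip(arrays, child_seeds))
        ]
        if return_history:
            history.append(
                {
                    "prior": prior,
                    "evidence": sum(laplace_evidence(f, prior) for f in fits),
                }
            )
        theta = np.array([f.map_estimate for f in fits])
        covdiag = np.array([np.diag(f.laplace_cov) for f in fits])
        mu_new = theta.mean(axis=0)
        var = (theta**2 + covdiag).mean(axis=0) - mu_new**2
        clipped = var < SIGMA_FLOOR**2
        if clipped.any():
            warnings.warn(
                f"population sigma floored for parameters "
                f"{[PARAM_NAMES[k] for k in np.where(clipped)[0]]}",
                stacklevel=2,
            )
        sigma_new = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        delta = np.abs(mu_new - prior.mu).max()
        prior = PopulationPrior(mu_new, sigma_new)
        prev_maps = [f.map_estimate for f in fits]
        if verbose:
            print(f"EM iter {it + 1}: max |delta mu| = {delta:.4f}")
        if delta < tol:
            break
    if return_history:
        return prior, fits, history
    return prior, fits


def summarize_population(
    prior: PopulationPrior, fits: list[SubjectFit]
) -> pd.DataFrame:
    """Per-parameter summary across subjects.

    Columns: ``mean_model`` and ``sd_model`` (sample statistics of the
    inverse-transformed per-subject MAPs), plus the prior's ``mu_unc`` and
    ``sigma_unc`` on the unconstrained scale — both conventions are emitted
    because group tables in this literature mix them.
    """
    theta_model = np.array(
        [untransform_params(f.map_estimate).to_array() for f in fits]
    )
    return pd.DataFrame(
        {
            "mean_model": theta_model.mean(axis=0),
            "sd_model": theta_model.std(axis=0, ddof=1),
            "mu_unc": prior.mu,
            "sigma_unc": prior.sigma,
        },
        index=list(PARAM_NAMES),
    )
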