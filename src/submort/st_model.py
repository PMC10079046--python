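"""Stage model 2: Bayesian spatiotemporal smoothing of log rates.

log rate = intercept + linear time trend
         + BYM2 spatial effect (scaled ICAR structured + iid unstructured)
         + RW2 temporal effect + province-year interaction (type I, iid),

with a normal likelihood on observed log rates using each observation's
design variance plus a small nugget. The improper ICAR and RW2 priors are
represented on their proper eigen-subspaces, so the structured spatial
effect sums to zero and the RW2 effect is orthogonal to constants and linear
trends by construction; the RW2 null space (linear trends go unpenalized) is
carried by the explicit intercept and linear-trend fixed effects.

Given the variance hyperparameters the model is jointly Gaussian, so
inference optimises the hyperparameters by marginal likelihood (the
default, a deterministic Laplace-style empirical Bayes) or samples them with
an ensemble MCMC sampler, and draws all effects exactly from their Gaussian
conditional in either case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .core import (
    RATE_SCALE,
    AdjacencyGraph,
    MortalityObservation,
    RateSurface,
    icar_basis,
    log_rate_bias_correction,
    rw2_basis,
)

logger = logging.getLogger(__name__)


@dataclass
class STSpec:
    """Hyperpriors and inference settings for the spatiotemporal model."""

    #: half-normal prior scales for the component standard deviations
    precision_priors: dict = field(
        default_factory=lambda: {
            "spatial_sd": 0.5,
            "rw2_sd": 0.5,
            "interaction_sd": 0.2,
            "nugget_sd": 0.1,
        }
    )
    interaction_type: str = "spaceXtime-type-I"  # iid province-year effects
    inference: str = "Laplace-approx"  # or "MCMC"
    seed: int = 0
    draws: int = 200
    max_opt_iter: int = 150
    #: propagate variance-parameter uncertainty (Laplace around the optimum)
    laplace_hyperparameters: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.precision_priors.values()):
            raise ValueError("precision prior scales must be positive")
        if self.interaction_type not in ("iid", "spaceXtime-type-I"):
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.inference not in ("Laplace-approx", "MCMC"):
            raise ValueError(f"unknown inference {self.inference!r}")


class _STProblem:
    """Gaussian linear mixed model on the province × year grid."""

    _FIXED_PRIOR_SD = 10.0  # weakly-informative proper prior on fixed effects

    def __init__(self, observations, graph, spec, years, completeness_adjustment):
        self.spec = spec
        self.graph = graph
        self.provinces = graph.provinces
        self.years = np.asarray(years, dtype=int)
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous")
        self.n_p, self.n_t = len(self.provinces), len(self.years)

        comp = completeness_adjustment or {}
        pidx, tidx, yv, dv = [], [], [], []
        for o in observations:
            j = int(np.argmin(np.abs(self.years - o.reference_year)))
            if abs(self.years[j] - o.reference_year) > 1.0:
                logger.warning("dropping observation at %s outside grid", o.reference_year)
                continue
            c = comp.get(o.source, 1.0) if o.completeness_adjustable else 1.0
            pidx.append(self.provinces.index(o.province))
            tidx.append(j)
            yv.append(np.log(o.value / c) + log_rate_bias_correction(o.design_variance))
            dv.append(o.design_variance)
        if not yv:
            raise ValueError("no observations fall inside the model grid")
        self.pidx = np.asarray(pidx)
        self.tidx = np.asarray(tidx)
        self.y = np.asarray(yv)
        self.design_var = np.asarray(dv)

        self.sp_basis = icar_basis(graph)
        self.t_basis = rw2_basis(self.n_t)

        tt = (self.years - self.years.mean()) / max(self.n_t - 1, 1)
        n = len(self.y)
        # observation-level design: [fixed | struct | iid | rw2 | interaction]
        blocks = [
            np.column_stack([np.ones(n), tt[self.tidx]]),
            self.sp_basis.basis[self.pidx],
            np.eye(self.n_p)[self.pidx],
            self.t_basis.basis[self.tidx],
        ]
        cell = self.pidx * self.n_t + self.tidx
        inter = np.zeros((n, self.n_p * self.n_t))
        inter[np.arange(n), cell] = 1.0
        blocks.append(inter)
        self.design = np.hstack(blocks)

        self.block_dims = [2, self.sp_basis.dim, self.n_p, self.t_basis.dim,
                           self.n_p * self.n_t]
        # grid-level design for reconstructing the latent surface
        gp = np.repeat(np.arange(self.n_p), self.n_t)
        gt = np.tile(np.arange(self.n_t), self.n_p)
        self.grid_design = np.hstack(
            [
                np.column_stack([np.ones(self.n_p * self.n_t), tt[gt]]),
                self.sp_basis.basis[gp],
                np.eye(self.n_p)[gp],
                self.t_basis.basis[gt],
                np.eye(self.n_p * self.n_t),
            ]
        )
        self.param_names = ["log_spatial_sd", "logit_phi", "log_rw2_sd",
                            "log_interaction_sd", "log_nugget_sd"]

    def initial_point(self) -> np.ndarray:
        pr = self.spec.precision_priors
        return np.array(
            [
                np.log(pr["spatial_sd"] / 2.0),
                0.0,
                np.log(pr["rw2_sd"] / 2.0),
                np.log(pr["interaction_sd"] / 2.0),
                np.log(pr["nugget_sd"] / 2.0),
            ]
        )

    #: box in transformed space keeping exp/expit finite and well-conditioned
    BOUNDS = [(-12.0, 4.0), (-8.0, 8.0), (-12.0, 4.0), (-12.0, 4.0), (-12.0, 4.0)]

    def unpack(self, x: np.ndarray) -> dict:
        x = np.clip(x, [b[0] for b in self.BOUNDS], [b[1] for b in self.BOUNDS])
        return {
            "spatial_sd": float(np.exp(x[0])),
            "phi": float(1.0 / (1.0 + np.exp(-x[1]))),
            "rw2_sd": float(np.exp(x[2])),
            "interaction_sd": float(np.exp(x[3])),
            "nugget_sd": float(np.exp(x[4])),
        }

    def pack(self, params: dict) -> np.ndarray:
        phi = min(max(params.get("phi", 0.5), 1e-6), 1 - 1e-6)
        return np.array(
            [
                np.log(max(params["spatial_sd"], 1e-12)),
                np.log(phi / (1.0 - phi)),
                np.log(max(params["rw2_sd"], 1e-12)),
                np.log(max(params["interaction_sd"], 1e-12)),
                np.log(max(params.get("nugget_sd", 1e-6), 1e-12)),
            ]
        )

    def prior_sd_vector(self, params: dict) -> np.ndarray:
        """Prior standard deviations of every latent coordinate."""
        s_struct = params["spatial_sd"] * np.sqrt(params["phi"]) * self.sp_basis.sd_weights()
        s_iid = np.full(self.n_p, params["spatial_sd"] * np.sqrt(1.0 - params["phi"]))
        s_rw2 = params["rw2_sd"] * self.t_basis.sd_weights()
        s_int = np.full(self.n_p * self.n_t, params["interaction_sd"])
        fixed = np.full(2, self._FIXED_PRIOR_SD)
        return np.concatenate([fixed, s_struct, s_iid, s_rw2, s_int])

    def log_prior(self, params: dict) -> float:
        pr = self.spec.precision_priors
        lp = 0.0
        for key in ("spatial_sd", "rw2_sd", "interaction_sd", "nugget_sd"):
            lp += -0.5 * (params[key] / pr[key]) ** 2
        return lp  # phi uniform on (0, 1)

    def _posterior_factor(self, params: dict):
        s = self.prior_sd_vector(params)
        noise = self.design_var + params["nugget_sd"] ** 2
        gw = self.design / noise[:, None]
        a = self.design.T @ gw + np.diag(1.0 / np.maximum(s, 1e-12) ** 2)
        b = gw.T @ self.y
        cf = cho_factor(a, lower=True)
        mean = cho_solve(cf, b)
        return cf, mean, noise, s

    def log_marginal(self, x: np.ndarray) -> float:
        params = self.unpack(x)
        try:
            cf, mean, noise, s = self._posterior_factor(params)
        except np.linalg.LinAlgError:
            return -np.inf
        # Gaussian marginal: y ~ N(0, G S Gᵀ + D), via the precision identity
        quad = self.y @ (self.y / noise) - mean @ (
            self.design.T @ (self.y / noise)
        )
        logdet_a = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdet = np.sum(np.log(noise)) + 2.0 * np.sum(np.log(s)) + logdet_a
        loglik = -0.5 * (quad + logdet + len(self.y) * np.log(2.0 * np.pi))
        out = loglik + self.log_prior(params)
        return out if np.isfinite(out) else -np.inf

    def draw_coefficients(self, params: dict, n_draws: int, rng) -> tuple[np.ndarray, np.ndarray]:
        cf, mean, _, _ = self._posterior_factor(params)
        lower = cf[0] if cf[1] else cf[0].T
        z = rng.standard_normal((len(mean), n_draws))
        dev = solve_triangular(lower.T, z, lower=False)
        return mean, mean[:, None] + dev


def fit_st(
    observations: list[MortalityObservation],
    adjacency: AdjacencyGraph,
    spec: STSpec,
    years: np.ndarray | None = None,
    measure: str = "U5MR",
    completeness_adjustment: dict[str, float] | None = None,
    level_uncertainty_sd: float = 0.0,
    hyperparameters: dict | None = None,
) -> RateSurface:
    """Posterior draws of the latent rate surface under the spatiotemporal model.

    ``completeness_adjustment`` divides completeness-adjustable observations
    by a working completeness per source (e.g. the GP stage's estimate)
    before fitting — this model has no completeness parameter of its own.
    ``level_uncertainty_sd`` propagates the uncertainty of that working
    completeness as a common log-scale level shift per draw (the adjustment
    moves every registration observation together, so its error is a level
    error, not independent noise). ``hyperparameters`` fixes the variance
    parameters instead of optimising them (used for validation against
    brute-force penalized least squares).
    """
    obs = [o for o in observations if o.measure == measure]
    if not obs:
        raise ValueError(f"no observations with measure {measure}")
    if not adjacency.is_connected():
        raise ValueError("adjacency graph must be connected")
    if years is None:
        lo = int(np.floor(min(o.reference_year for o in obs)))
        hi = int(np.ceil(max(o.reference_year for o in obs) - 0.5))
        years = np.arange(lo, hi + 1)

    problem = _STProblem(obs, adjacency, spec, years, completeness_adjustment)
    rng = np.random.default_rng(spec.seed)

    theta_draws = None
    if hyperparameters is not None:
        params = dict(hyperparameters)
        params.setdefault("nugget_sd", 1e-4)
        params.setdefault("phi", 0.5)
    elif spec.inference == "Laplace-approx":
        res = minimize(
            lambda x: -problem.log_marginal(x),
            problem.initial_point(),
            method="L-BFGS-B",
            bounds=problem.BOUNDS,
            options={"maxiter": spec.max_opt_iter},
        )
        params = problem.unpack(res.x)
        if spec.laplace_hyperparameters:
            from .gpr_model import laplace_hyper_draws

            theta_draws = laplace_hyper_draws(
                problem.log_marginal, res.x, spec.draws, rng
            )
    else:  # MCMC over hyperparameters
        import emcee

        ndim = len(problem.param_names)
        nwalkers = 2 * ndim + 2
        p0 = problem.initial_point() + 0.05 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, problem.log_marginal)
        state = sampler.run_mcmc(p0, 300, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, max(spec.draws // nwalkers + 1, 20), progress=False)
        flat = sampler.get_chain(flat=True)
        params = problem.unpack(np.median(flat, axis=0))

    if theta_draws is not None:
        mean, _ = problem.draw_coefficients(params, 1, rng)
        cols = [
            problem.draw_coefficients(problem.unpack(xk), 1, rng)[1][:, 0]
            for xk in theta_draws
        ]
        coef_draws = np.column_stack(cols)
    else:
        mean, coef_draws = problem.draw_coefficients(params, spec.draws, rng)
    log_grid = problem.grid_design @ coef_draws
    if level_uncertainty_sd > 0:
        log_grid = log_grid + rng.normal(
            scale=level_uncertainty_sd, size=log_grid.shape[1]
        )[None, :]
    draws = np.exp(log_grid).reshape(problem.n_p, problem.n_t, -1)
    draws = np.clip(draws, 1e-9, RATE_SCALE - 1e-6)

    dims = problem.block_dims
    slices = {}
    start = 0
    for name, dim in zip(("fixed", "struct", "iid", "rw2", "interaction"), dims):
        slices[name] = slice(start, start + dim)
        start += dim
    struct_draws = problem.sp_basis.basis @ coef_draws[slices["struct"]]
    rw2_draws = problem.t_basis.basis @ coef_draws[slices["rw2"]]

    hyper_draws = None
    if theta_draws is not None:
        hyper_draws = {
            name: theta_draws[:, k] for k, name in enumerate(problem.param_names)
        }
    metadata = {
        "model_tag": "st",
        "seed": spec.seed,
        "measure": measure,
        "inference": spec.inference if hyperparameters is None else "fixed",
        "hyperparameters": params,
        "hyperparameter_draws": hyper_draws,
        "completeness": dict(completeness_adjustment or {}),
        "conditional_mean": (problem.grid_design @ mean).reshape(problem.n_p, problem.n_t),
        "coefficient_mode": mean,
        "spatial_structured_draws": struct_draws,
        "rw2_draws": rw2_draws,
        "fixed_draws": coef_draws[slices["fixed"]],
    }
    return RateSurface(problem.provinces, problem.years, draws, metadata)
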