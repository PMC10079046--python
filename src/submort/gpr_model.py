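"""Stage model 1: Gaussian-process regression for log rates.

The mean function is a generalized linear mixed model (fixed covariate
effects, random province intercepts) on log rates; deviations from the mean
follow a zero-mean Gaussian process over the province × year grid with a
separable covariance — Matérn(ν, ℓ) in time, and either a graph-diffusion
kernel on the adjacency structure or an exchangeable correlation in space.

Death-registration observations enter with an additive log-completeness
offset carrying a Beta prior (registration records only a fraction of true
deaths, so the observed log rate is the latent log rate plus log
completeness). Each observation's noise variance is its design variance plus
a source-specific non-sampling variance with a half-normal prior.

Because the likelihood is normal on log rates, the latent surface is
conditionally Gaussian given the hyperparameters: the default inference
optimises the hyperparameters by penalized marginal likelihood and draws the
surface exactly from its Gaussian conditional; the MCMC route samples the
hyperparameters with an affine-invariant ensemble sampler (the latent field
stays analytically marginalised) and draws one conditional surface per
retained hyperparameter sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, expm
from scipy.optimize import minimize
from scipy.special import gammaln, kv
from scipy.stats import beta as beta_dist

from .core import (
    RATE_SCALE,
    AdjacencyGraph,
    MortalityObservation,
    RateSurface,
    log_rate_bias_correction,
)

logger = logging.getLogger(__name__)


@dataclass
class GPRSpec:
    """Hyperpriors and inference settings for the GP stage model."""

    matern_smoothness: float = 1.5
    length_scale_time: float = 5.0  # years; prior median
    spatial_kernel: str = "adjacency-diffusion"  # or "exchangeable"
    spatial_range: float = 1.0  # diffusion time; prior median
    amplitude_sd: float = 0.5  # half-normal prior scale for the GP amplitude
    completeness_prior: dict = field(default_factory=lambda: {"DRS": (9.0, 3.0)})
    nonsampling_sd_prior: dict = field(
        default_factory=lambda: {"DRS": 0.05, "SBH_MAC": 0.15, "SBH_MAP": 0.15, "CBH": 0.10}
    )
    #: zero-centred normal prior scales for per-source systematic offsets
    #: (the mean component of non-sampling error in indirect estimates)
    source_bias_prior_sd: dict = field(
        default_factory=lambda: {"SBH_MAC": 0.1, "SBH_MAP": 0.1, "CBH": 0.05}
    )
    fixed_completeness: dict | None = None  # point-mass completeness per source
    #: propagate hyperparameter uncertainty by a Laplace approximation around
    #: the penalized-likelihood optimum (False: point empirical Bayes)
    laplace_hyperparameters: bool = True
    inference: str = "map"  # "map" (empirical Bayes) or "mcmc"
    chains: int = 4
    warmup: int = 300
    draws: int = 200
    seed: int = 0
    max_opt_iter: int = 150

    def __post_init__(self) -> None:
        if self.matern_smoothness <= 0 or self.length_scale_time <= 0:
            raise ValueError("Matérn smoothness and length scale must be positive")
        if self.spatial_kernel not in ("adjacency-diffusion", "exchangeable"):
            raise ValueError(f"unknown spatial kernel {self.spatial_kernel!r}")
        if self.draws < 10:
            raise ValueError("draws must be at least 10 (≥100 for production use)")


# ---------------------------------------------------------------------------
# GLMM mean function
# ---------------------------------------------------------------------------

@dataclass
class GLMMResult:
    coefficients: pd.Series
    coef_sd: pd.Series
    random_effects: pd.Series
    residuals: np.ndarray
    covariate_cols: list[str]
    covariate_table: pd.DataFrame  # indexed by (province, year)
    sigma_re: float
    sigma_resid: float
    year_effects: pd.Series = None

    def _covariate_row(self, province: str, year: int) -> np.ndarray:
        table = self.covariate_table
        years = table.loc[province].index.to_numpy()
        nearest = years[np.argmin(np.abs(years - year))]
        return table.loc[(province, nearest), self.covariate_cols].to_numpy(dtype=float)

    def predict(self, province: str, year: float) -> float:
        # the year random intercepts are an estimation nuisance (they
        # de-confound the covariate slopes); prediction leaves temporal
        # structure to the downstream smoother
        x = self._covariate_row(province, int(round(year)))
        fixed = self.coefficients["intercept"] + float(
            x @ self.coefficients[self.covariate_cols].to_numpy()
        )
        return fixed + float(self.random_effects.get(province, 0.0))

    def predict_grid(self, provinces: list[str], years: np.ndarray) -> np.ndarray:
        out = np.empty((len(provinces), len(years)))
        for i, p in enumerate(provinces):
            for j, y in enumerate(years):
                out[i, j] = self.predict(p, int(y))
        return out


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        resid = x[:, j] - others @ np.linalg.lstsq(others, x[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(x[:, j]), 1.0):
            bad.append(names[j])
    return bad


def fit_glmm_mean(
    observations: list[MortalityObservation],
    covariates: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    completeness_correction: dict[str, float] | None = None,
) -> GLMMResult:
    """Log-linear mean with fixed covariate effects and province random intercepts.

    ``completeness_correction`` optionally divides completeness-adjustable
    observations by a working completeness (e.g. the Beta-prior mean) so the
    mean function is not dragged down by under-registration; the GP stage
    then refines the completeness with its full prior.
    """
    if not observations:
        raise ValueError("no observations")
    if covariate_cols is None:
        covariate_cols = [c for c in covariates.columns if c not in ("province", "year")]
    table = covariates.set_index(["province", "year"]).sort_index()
    if table[covariate_cols].isna().any().any():
        raise ValueError("covariates must be complete (NaNs found)")

    provinces = [o.province for o in observations]
    y = np.empty(len(observations))
    x = np.empty((len(observations), len(covariate_cols)))
    for i, o in enumerate(observations):
        corr = 1.0
        if completeness_correction and o.completeness_adjustable:
            corr = completeness_correction.get(o.source, 1.0)
        y[i] = np.log(o.value / corr) + log_rate_bias_correction(o.design_variance)
        years = table.loc[o.province].index.to_numpy()
        nearest = years[np.argmin(np.abs(years - o.reference_year))]
        x[i] = table.loc[(o.province, nearest), covariate_cols].to_numpy(dtype=float)

    design = np.column_stack([np.ones(len(y)), x])
    names = ["intercept"] + list(covariate_cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(design, names)}"
        )

    import statsmodels.api as sm

    nearest_years = np.array([
        int(table.loc[o.province].index.to_numpy()[
            np.argmin(np.abs(table.loc[o.province].index.to_numpy() - o.reference_year))
        ])
        for o in observations
    ])

    re_series = pd.Series(dtype=float)
    year_series = None
    sigma_re = 0.0
    coefs = coef_sd = None

    # preferred: crossed province + year random intercepts — the shared year
    # effect soaks up common temporal shocks that would otherwise confound
    # the covariate slopes and deflate their standard errors
    if len(set(provinces)) >= 3 and len(set(nearest_years)) >= 3:
        frame = pd.DataFrame({"y": y, "province": provinces, "year": nearest_years})
        cnames = [f"c{k}" for k in range(len(covariate_cols))]
        for k, cn in enumerate(cnames):
            frame[cn] = x[:, k]
        formula = "y ~ " + (" + ".join(cnames) if cnames else "1")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    formula,
                    groups=np.ones(len(frame)),
                    vc_formula={"province": "0 + C(province)", "year": "0 + C(year)"},
                    data=frame,
                )
                fit = model.fit(reml=True, method="lbfgs")
            est = fit.fe_params.to_numpy()
            sd = fit.bse_fe.to_numpy()
            if np.all(np.isfinite(est)) and np.all(np.isfinite(sd)):
                coefs = pd.Series(est, index=names)
                coef_sd = pd.Series(sd, index=names)
                re_all = fit.random_effects[list(fit.random_effects)[0]]
                re_series = pd.Series(
                    {
                        k.split("[")[-1].rstrip("]"): float(v)
                        for k, v in re_all.items()
                        if k.startswith("province")
                    }
                )
                year_series = pd.Series(
                    {
                        int(k.split("[")[-1].rstrip("]")): float(v)
                        for k, v in re_all.items()
                        if k.startswith("year")
                    }
                )
                sigma_re = float(np.sqrt(max(fit.vcomp[0], 0.0)))
                sigma_resid = float(np.sqrt(max(fit.scale, 0.0)))
        except (np.linalg.LinAlgError, ValueError):
            coefs = None

    if coefs is None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, design, groups=np.asarray(provinces))
                fit = model.fit(reml=True, method="lbfgs")
            coefs = pd.Series(fit.fe_params, index=names)
            coef_sd = pd.Series(fit.bse_fe, index=names)
            re_series = pd.Series(
                {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
            )
            sigma_re = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
            sigma_resid = float(np.sqrt(max(fit.scale, 0.0)))
        except (np.linalg.LinAlgError, ValueError):
            # degenerate (e.g. noise-free) data: plain least squares
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            coefs = pd.Series(beta, index=names)
            resid = y - design @ beta
            dof = max(len(y) - design.shape[1], 1)
            sigma_resid = float(np.sqrt(resid @ resid / dof))
            cov = sigma_resid**2 * np.linalg.inv(design.T @ design)
            coef_sd = pd.Series(np.sqrt(np.diag(cov)), index=names)
            re_series = pd.Series(dtype=float)

    fitted = design @ coefs.to_numpy() + np.array(
        [re_series.get(p, 0.0) for p in provinces]
    )
    return GLMMResult(
        coefficients=coefs,
        coef_sd=coef_sd,
        random_effects=re_series,
        residuals=y - fitted,
        covariate_cols=list(covariate_cols),
        covariate_table=table,
        sigma_re=sigma_re,
        sigma_resid=sigma_resid,
        year_effects=year_series,
    )


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def matern_kernel(times: np.ndarray, nu: float, length_scale: float) -> np.ndarray:
    """Matérn correlation over a 1-D coordinate (unit variance)."""
    d = np.abs(times[:, None] - times[None, :]) / length_scale
    if abs(nu - 0.5) < 1e-12:
        return np.exp(-d)
    if abs(nu - 1.5) < 1e-12:
        s = np.sqrt(3.0) * d
        return (1.0 + s) * np.exp(-s)
    if abs(nu - 2.5) < 1e-12:
        s = np.sqrt(5.0) * d
        return (1.0 + s + s**2 / 3.0) * np.exp(-s)
    s = np.sqrt(2.0 * nu) * d
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.exp(
            (1.0 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(s)
        ) * kv(nu, s)
    k[d == 0] = 1.0
    return k


def diffusion_kernel(graph: AdjacencyGraph, rho: float) -> np.ndarray:
    """Graph-diffusion (heat-kernel) correlation: normalized expm(−ρL)."""
    k = expm(-rho * graph.laplacian())
    d = np.sqrt(np.diag(k))
    return k / np.outer(d, d)


def exchangeable_kernel(n: int, r: float) -> np.ndarray:
    return (1.0 - r) * np.eye(n) + r * np.ones((n, n))


# ---------------------------------------------------------------------------
# GP fitting
# ---------------------------------------------------------------------------

def _halfnormal_logpdf(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


def _lognormal_logpdf(logx: float, mu: float, sd: float) -> float:
    return -0.5 * ((logx - mu) / sd) ** 2


class _GPProblem:
    """Penalized marginal likelihood of the hyperparameters, latent field
    analytically integrated out."""

    def __init__(self, observations, mean_model, graph, spec, years):
        self.spec = spec
        self.graph = graph
        self.provinces = graph.provinces
        self.years = np.asarray(years, dtype=int)
        self.n_p, self.n_t = len(self.provinces), len(self.years)

        kept, cells, yv, dv, src, adj = [], [], [], [], [], []
        for o in observations:
            j = int(np.argmin(np.abs(self.years - o.reference_year)))
            if abs(self.years[j] - o.reference_year) > 1.0:
                logger.warning(
                    "dropping observation at %s outside grid years", o.reference_year
                )
                continue
            i = self.provinces.index(o.province)
            kept.append(o)
            cells.append(i * self.n_t + j)
            # count-based log rates carry a small-count Jensen bias;
            # restore the log-scale mean before the Gaussian likelihood
            yv.append(np.log(o.value) + log_rate_bias_correction(o.design_variance))
            dv.append(o.design_variance)
            src.append(o.source)
            adj.append(o.completeness_adjustable)
        if not kept:
            raise ValueError("no observations fall inside the model grid")
        self.observations = kept
        self.cells = np.asarray(cells)
        self.y = np.asarray(yv)
        self.design_var = np.asarray(dv)
        self.sources = np.asarray(src)
        self.adjustable = np.asarray(adj)

        if mean_model is None:
            self.mean_grid = np.zeros((self.n_p, self.n_t))
        else:
            self.mean_grid = mean_model.predict_grid(self.provinces, self.years)
        self.mean_obs = self.mean_grid.ravel()[self.cells]

        self.time_idx = (self.years - self.years[0]).astype(float)
        self.source_types = sorted(set(self.sources))
        fixed = spec.fixed_completeness or {}
        self.free_completeness = sorted(
            {s for s, a in zip(self.sources, self.adjustable) if a and s not in fixed}
        )
        self.fixed_completeness = fixed
        self.bias_sources = sorted(
            s for s in self.source_types if s in (spec.source_bias_prior_sd or {})
        )
        # parameter vector layout
        self.param_names = (
            ["log_amplitude", "log_timescale", "spatial_param"]
            + [f"logit_c_{s}" for s in self.free_completeness]
            + [f"bias_{s}" for s in self.bias_sources]
            + [f"log_ns_{s}" for s in self.source_types]
        )

    # -- parameter packing ---------------------------------------------------

    def bounds(self) -> list[tuple[float, float]]:
        """Box in transformed space keeping exp/expit finite."""
        out = [(-12.0, 4.0), (-12.0, 4.0)]
        out.append((-12.0, 4.0) if self.spec.spatial_kernel == "adjacency-diffusion" else (-8.0, 8.0))
        out.extend([(-8.0, 8.0)] * len(self.free_completeness))
        out.extend([(-2.0, 2.0)] * len(self.bias_sources))
        out.extend([(-12.0, 4.0)] * len(self.source_types))
        return out

    def initial_point(self) -> np.ndarray:
        spec = self.spec
        x = [np.log(spec.amplitude_sd), np.log(spec.length_scale_time)]
        if spec.spatial_kernel == "adjacency-diffusion":
            x.append(np.log(spec.spatial_range))
        else:
            x.append(0.0)  # logit r = 0 → r = 0.5
        for s in self.free_completeness:
            a, b = spec.completeness_prior.get(s, (9.0, 3.0))
            m = a / (a + b)
            x.append(np.log(m / (1.0 - m)))
        x.extend([0.0] * len(self.bias_sources))
        for s in self.source_types:
            x.append(np.log(max(spec.nonsampling_sd_prior.get(s, 0.1), 1e-3)))
        return np.asarray(x)

    def unpack(self, x: np.ndarray) -> dict:
        spec = self.spec
        bounds = self.bounds()
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        k = 3
        params = {
            "amplitude": float(np.exp(x[0])),
            "timescale": float(np.exp(x[1])),
        }
        if spec.spatial_kernel == "adjacency-diffusion":
            params["rho"] = float(np.exp(x[2]))
        else:
            params["r"] = float(1.0 / (1.0 + np.exp(-x[2])))
        comp = dict(self.fixed_completeness)
        for s in self.free_completeness:
            comp[s] = float(1.0 / (1.0 + np.exp(-x[k])))
            k += 1
        params["completeness"] = comp
        bias = {}
        for s in self.bias_sources:
            bias[s] = float(x[k])
            k += 1
        params["source_bias"] = bias
        ns = {}
        for s in self.source_types:
            ns[s] = float(np.exp(x[k]))
            k += 1
        params["nonsampling_sd"] = ns
        return params

    # -- model algebra -------------------------------------------------------

    def grid_cov(self, params: dict) -> np.ndarray:
        spec = self.spec
        kt = matern_kernel(self.time_idx, spec.matern_smoothness, params["timescale"])
        if spec.spatial_kernel == "adjacency-diffusion":
            ks = diffusion_kernel(self.graph, params["rho"])
        else:
            ks = exchangeable_kernel(self.n_p, params["r"])
        return params["amplitude"] ** 2 * np.kron(ks, kt)

    def obs_offset(self, params: dict) -> np.ndarray:
        off = np.zeros(len(self.y))
        for s, c in params["completeness"].items():
            off[(self.sources == s) & self.adjustable] = np.log(c)
        for s, b in params.get("source_bias", {}).items():
            off[self.sources == s] += b
        return off

    def obs_noise_var(self, params: dict) -> np.ndarray:
        var = self.design_var.copy()
        for s, sd in params["nonsampling_sd"].items():
            var[self.sources == s] += sd**2
        return var

    def log_prior(self, x: np.ndarray, params: dict) -> float:
        spec = self.spec
        # log-normal on the amplitude: a zero-amplitude GP is degenerate
        # (the posterior collapses onto the mean function with no spread),
        # so the prior keeps the field scale bounded away from zero
        lp = _lognormal_logpdf(x[0], np.log(spec.amplitude_sd / 2.0), 1.0)
        lp += _lognormal_logpdf(x[1], np.log(spec.length_scale_time), 0.75)
        if spec.spatial_kernel == "adjacency-diffusion":
            lp += _lognormal_logpdf(x[2], np.log(spec.spatial_range), 0.75)
        k = 3
        for s in self.free_completeness:
            a, b = spec.completeness_prior.get(s, (9.0, 3.0))
            c = params["completeness"][s]
            lp += beta_dist.logpdf(c, a, b) + np.log(c * (1.0 - c))  # + logit Jacobian
            k += 1
        for s in self.bias_sources:
            sd = spec.source_bias_prior_sd.get(s, 0.1)
            lp += -0.5 * (params["source_bias"][s] / sd) ** 2
        for s in self.source_types:
            lp += _halfnormal_logpdf(
                params["nonsampling_sd"][s], spec.nonsampling_sd_prior.get(s, 0.1)
            )
        return float(lp)

    def log_marginal(self, x: np.ndarray) -> float:
        params = self.unpack(x)
        sigma = self.grid_cov(params)
        v = sigma[np.ix_(self.cells, self.cells)] + np.diag(self.obs_noise_var(params))
        r = self.y - self.mean_obs - self.obs_offset(params)
        try:
            cf = cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        alpha = cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        loglik = -0.5 * (r @ alpha + logdet + len(r) * np.log(2.0 * np.pi))
        out = loglik + self.log_prior(x, params)
        return float(out) if np.isfinite(out) else -np.inf

    def conditional(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and covariance of the latent grid field given θ."""
        params = self.unpack(x)
        sigma = self.grid_cov(params)
        sig_oo = sigma[np.ix_(self.cells, self.cells)] + np.diag(self.obs_noise_var(params))
        sig_go = sigma[:, self.cells]
        r = self.y - self.mean_obs - self.obs_offset(params)
        cf = cho_factor(sig_oo, lower=True)
        mean = sig_go @ cho_solve(cf, r)
        cov = sigma - sig_go @ cho_solve(cf, sig_go.T)
        return mean, cov


def laplace_hyper_draws(
    logpost, x_hat: np.ndarray, n_draws: int, rng, step: float = 1e-3
) -> np.ndarray:
    """Gaussian (Laplace) draws of hyperparameters around their optimum.

    The Hessian of the negative log posterior is estimated by central finite
    differences; non-positive curvature directions are floored so the
    approximation never widens beyond the prior scale of the transformed
    parameters.
    """
    d = len(x_hat)
    h = step * (1.0 + np.abs(x_hat))
    hess = np.empty((d, d))
    f0 = logpost(x_hat)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                val = -(logpost(x_hat + ei) - 2 * f0 + logpost(x_hat - ei)) / h[i] ** 2
            else:
                val = -(
                    logpost(x_hat + ei + ej)
                    - logpost(x_hat + ei - ej)
                    - logpost(x_hat - ei + ej)
                    + logpost(x_hat - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    eigvals, eigvecs = np.linalg.eigh(hess)
    eigvals = np.maximum(eigvals, 1.0)  # floor: posterior sd ≤ 1 in transformed space
    cov = (eigvecs / eigvals) @ eigvecs.T
    return x_hat + rng.multivariate_normal(np.zeros(d), cov, size=n_draws)


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    jitter = 1e-10 * max(np.trace(cov) / len(cov), 1.0)
    for _ in range(8):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError("conditional covariance not positive definite")


def fit_gpr(
    observations: list[MortalityObservation],
    mean_model: GLMMResult | None,
    adjacency: AdjacencyGraph,
    spec: GPRSpec,
    years: np.ndarray | None = None,
    measure: str = "U5MR",
) -> RateSurface:
    """Posterior draws of the latent rate surface under the GP stage model.

    ``mean_model`` is the fitted GLMM mean (None for a zero mean, as in the
    neonatal residual route). ``years`` defaults to the integer span of the
    observation reference years.
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

    problem = _GPProblem(obs, mean_model, adjacency, spec, years)
    rng = np.random.default_rng(spec.seed)
    completeness_log_sd: dict[str, float] = {}

    if spec.inference == "map":
        res = minimize(
            lambda x: -problem.log_marginal(x),
            problem.initial_point(),
            method="L-BFGS-B",
            bounds=problem.bounds(),
            options={"maxiter": spec.max_opt_iter},
        )
        x_hat = res.x
        if spec.laplace_hyperparameters:
            theta_draws = laplace_hyper_draws(
                problem.log_marginal, x_hat, spec.draws, rng
            )
            cols = []
            for xk in theta_draws:
                mean, cov = problem.conditional(xk)
                cols.append(mean + _safe_cholesky(cov) @ rng.standard_normal(len(mean)))
            g = np.column_stack(cols)
            for s in problem.free_completeness:
                k = problem.param_names.index(f"logit_c_{s}")
                cs = 1.0 / (1.0 + np.exp(-theta_draws[:, k]))
                completeness_log_sd[s] = float(np.std(np.log(cs)))
        else:
            mean, cov = problem.conditional(x_hat)
            chol = _safe_cholesky(cov)
            z = rng.standard_normal((len(mean), spec.draws))
            g = mean[:, None] + chol @ z
        params = problem.unpack(x_hat)
        rhat = None
    elif spec.inference == "mcmc":
        import emcee

        ndim = len(problem.param_names)
        nwalkers = max(2 * ndim + 2, 2 * spec.chains)
        x0 = problem.initial_point()
        p0 = x0 + 0.05 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, problem.log_marginal)
        state = sampler.run_mcmc(p0, spec.warmup, progress=False)
        sampler.reset()
        steps = max(int(np.ceil(spec.draws / nwalkers)), 20)
        sampler.run_mcmc(state, steps, progress=False)
        chain = sampler.get_chain()  # (steps, walkers, ndim)
        rhat = _max_rhat(chain)
        if rhat > 1.05:
            logger.warning("MCMC not mixed: max R-hat %.3f > 1.05", rhat)
        flat = chain.reshape(-1, ndim)
        for s in problem.free_completeness:
            k = problem.param_names.index(f"logit_c_{s}")
            cs = 1.0 / (1.0 + np.exp(-flat[:, k]))
            completeness_log_sd[s] = float(np.std(np.log(cs)))
        idx = rng.choice(len(flat), size=spec.draws, replace=False)
        cols = []
        for xk in flat[idx]:
            mean, cov = problem.conditional(xk)
            cols.append(mean + _safe_cholesky(cov) @ rng.standard_normal(len(mean)))
        g = np.column_stack(cols)
        params = problem.unpack(np.median(flat, axis=0))
        x_hat = np.median(flat, axis=0)
    else:
        raise ValueError(f"unknown inference {spec.inference!r}")

    log_surface = problem.mean_grid.ravel()[:, None] + g
    draws = np.exp(log_surface).reshape(problem.n_p, problem.n_t, -1)
    draws = np.clip(draws, 1e-9, RATE_SCALE - 1e-6)
    metadata = {
        "model_tag": "gpr",
        "seed": spec.seed,
        "measure": measure,
        "inference": spec.inference,
        "hyperparameters": params,
        "completeness": params["completeness"],
        "completeness_log_sd": completeness_log_sd,
        "conditional_mean": (problem.mean_grid.ravel() + problem.conditional(x_hat)[0]).reshape(
            problem.n_p, problem.n_t
        ),
        "rhat": rhat,
    }
    return RateSurface(problem.provinces, problem.years, draws, metadata)


def _max_rhat(chain: np.ndarray) -> float:
    import arviz as az

    # emcee walkers act as chains: arviz expects (chain, draw, *shape)
    data = az.convert_to_dataset(np.moveaxis(chain, 1, 0))
    return float(az.rhat(data).to_array().max())
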