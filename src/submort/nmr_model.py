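"""Neonatal mortality from under-5 mortality via a quadratic log-log relation.

Pooled across province-years the association between log NMR and log U5MR is
quadratic; province-year effects δ_{p,t} let a province sit above or below
the curve. The effects are smoothed by both stage models (the GP route and
the spatiotemporal route) and combined by model averaging, exactly as for
the under-5 surface. The sampling of NMR is truncated above at U5MR draw by
draw — a neonatal death is an under-5 death, so the rate can never exceed it.

Registration incompleteness for neonatal deaths is proxied by the under-5
completeness estimated at the previous stage (no independent source exists
to estimate neonatal completeness), passed in as ``completeness``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    RATE_SCALE,
    AdjacencyGraph,
    MortalityObservation,
    RateSurface,
    log_rate_bias_correction,
)
from .ensemble import HoldoutPlan, combine, make_holdout, rank_weights, score_models
from .gpr_model import GPRSpec, fit_gpr
from .st_model import STSpec, fit_st

logger = logging.getLogger(__name__)


@dataclass
class NMRRelation:
    """Fitted quadratic relation and province-year effects."""

    beta0: float
    beta1: float
    beta2: float
    beta_cov: np.ndarray  # 3×3 sampling covariance of the coefficients
    effect_surface: np.ndarray  # posterior median δ_{p,t}
    residual_sd: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def coefficient_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": ["beta0", "beta1", "beta2"],
                "estimate": self.coefficients,
                "sd": self.coefficient_sd(),
            }
        )


def _fit_quadratic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, x**2])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = max(len(y) - 3, 1)
    sigma2 = float(resid @ resid / dof)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return beta, cov, resid


def assemble_nmr_draws(
    beta_draws: np.ndarray,
    delta_draws: np.ndarray,
    u5_draws: np.ndarray,
) -> np.ndarray:
    """Per-draw NMR from the relation, truncated at the paired U5MR draw.

    beta_draws: (D, 3); delta_draws, u5_draws: (P, T, D). Returns (P, T, D)
    NMR draws satisfying NMR ≤ U5MR in every draw.
    """
    x = np.log(u5_draws)
    log_nmr = (
        beta_draws[:, 0][None, None, :]
        + beta_draws[:, 1][None, None, :] * x
        + beta_draws[:, 2][None, None, :] * x**2
        + delta_draws
    )
    return np.minimum(np.exp(log_nmr), u5_draws)


def fit_nmr(
    nmr_observations: list[MortalityObservation],
    u5mr_surface: RateSurface,
    adjacency: AdjacencyGraph,
    gpr_spec: GPRSpec | None = None,
    st_spec: STSpec | None = None,
    holdout: HoldoutPlan | None = None,
    completeness: dict[str, float] | None = None,
    n_out_draws: int = 100,
    seed: int = 0,
) -> tuple[RateSurface, NMRRelation]:
    """Estimate the NMR surface from NMR observations and the U5MR posterior.

    Fits the pooled quadratic on (log U5MR median, corrected log NMR),
    smooths the residual province-year effects with both stage models,
    averages them with rank weights from a holdout, and assembles NMR draws
    over a thinned set of U5MR draws so both uncertainty sources propagate.
    """
    obs = [o for o in nmr_observations if o.measure == "NMR"]
    if not obs:
        raise ValueError("no NMR observations")
    gpr_spec = gpr_spec or GPRSpec(draws=n_out_draws, seed=seed)
    st_spec = st_spec or STSpec(draws=n_out_draws, seed=seed)
    holdout = holdout or HoldoutPlan(seed=seed)
    comp = completeness if completeness is not None else u5mr_surface.metadata.get(
        "completeness", {}
    )

    med = u5mr_surface.median()
    x_obs, y_obs = [], []
    for o in obs:
        i = u5mr_surface.province_index(o.province)
        j = u5mr_surface.year_index(int(round(o.reference_year - 0.001)))
        c = comp.get(o.source, 1.0) if o.completeness_adjustable else 1.0
        y = np.log(o.value / c) + log_rate_bias_correction(o.design_variance)
        if y > np.log(med[i, j]):
            logger.warning(
                "NMR observation %.1f at (%s, %s) exceeds paired U5MR median %.1f; "
                "the truncated likelihood will pull it below",
                o.value / c, o.province, o.reference_year, med[i, j],
            )
        x_obs.append(np.log(med[i, j]))
        y_obs.append(y)
    x_obs = np.asarray(x_obs)
    y_obs = np.asarray(y_obs)

    beta, beta_cov, resid = _fit_quadratic(x_obs, y_obs)

    # Residual effects as pseudo-observations: value chosen so the stage
    # models (which add the small-count log correction at ingestion) see
    # exactly the already-corrected residual.
    pseudo = [
        MortalityObservation(
            source=o.source,
            province=o.province,
            reference_year=o.reference_year,
            measure="NMR",
            value=float(np.exp(r - log_rate_bias_correction(o.design_variance))),
            design_variance=o.design_variance,
            completeness_adjustable=False,
        )
        for o, r in zip(obs, resid)
    ]

    years = u5mr_surface.years
    split = make_holdout(pseudo, holdout)
    gpr_fit_spec = GPRSpec(**{**gpr_spec.__dict__, "fixed_completeness": {}, "seed": seed})
    delta_gpr = fit_gpr(split["train"], None, adjacency, gpr_fit_spec,
                        years=years, measure="NMR")
    delta_st = fit_st(split["train"], adjacency, st_spec, years=years, measure="NMR")
    scores = score_models([delta_gpr, delta_st], split["test"], completeness={})
    weights = rank_weights(scores)
    delta_surface = combine([delta_gpr, delta_st], weights, n_out_draws, seed)
    delta_draws = np.log(delta_surface.draws)

    rng = np.random.default_rng(seed)
    n_u5 = u5mr_surface.n_draws
    pick = rng.choice(n_u5, size=n_out_draws, replace=n_out_draws > n_u5)
    u5_draws = u5mr_surface.draws[:, :, pick]
    beta_draws = rng.multivariate_normal(beta, beta_cov, size=n_out_draws)

    nmr_draws = assemble_nmr_draws(beta_draws, delta_draws, u5_draws)
    nmr_draws = np.clip(nmr_draws, 1e-9, RATE_SCALE - 1e-6)

    relation = NMRRelation(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        beta_cov=beta_cov,
        effect_surface=np.median(delta_draws, axis=2),
        residual_sd=float(np.std(resid, ddof=3)) if len(resid) > 3 else float(np.std(resid)),
    )
    surface = RateSurface(
        u5mr_surface.provinces,
        years,
        nmr_draws,
        {
            "model_tag": "nmr-bma",
            "seed": seed,
            "measure": "NMR",
            "weights": delta_surface.metadata["weights"],
            "completeness": dict(comp),
            "u5_draw_indices": pick,
        },
    )
    return surface, relation
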