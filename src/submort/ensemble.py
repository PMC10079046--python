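"""Bayesian model averaging of the stage models.

A fraction of the death-registration observations and a fraction of the
remaining sources are held out; each stage model's posterior surface is
scored on the held-out points by log-scale RMSE and 95% interval coverage;
models are ranked (RMSE first, coverage distance from 0.95 as tie-break, or
a rank-sum of both) and weighted by a monotonically declining function of
rank; the combined surface samples each output draw from one model with
probability equal to its weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MortalityObservation, RateSurface, log_rate_bias_correction


@dataclass
class HoldoutPlan:
    frac_drs: float = 0.20
    frac_other: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_drs < 1.0 and 0.0 < self.frac_other < 1.0):
            raise ValueError("holdout fractions must lie in (0, 1)")


@dataclass
class ModelScore:
    model_tag: str
    rmse: float
    coverage95: float
    rank: int = 0
    weight: float = 0.0


def make_holdout(
    observations: list[MortalityObservation], plan: HoldoutPlan
) -> dict[str, list[MortalityObservation]]:
    """Disjoint train/test split, stratified by registration vs survey sources.

    Within each stratum the held-out count is round(fraction × size); a
    present stratum too small to spare a test point raises.
    """
    rng = np.random.default_rng(plan.seed)
    drs = [o for o in observations if o.source == "DRS"]
    other = [o for o in observations if o.source != "DRS"]
    train: list[MortalityObservation] = []
    test: list[MortalityObservation] = []
    for stratum, frac in ((drs, plan.frac_drs), (other, plan.frac_other)):
        if not stratum:
            continue
        n_test = int(round(frac * len(stratum)))
        if n_test < 1 or n_test >= len(stratum):
            raise ValueError(
                f"stratum of size {len(stratum)} cannot hold out {n_test} points "
                f"at fraction {frac}"
            )
        idx = rng.permutation(len(stratum))
        test.extend(stratum[i] for i in idx[:n_test])
        train.extend(stratum[i] for i in idx[n_test:])
    return {"train": train, "test": test}


def _corrected_log_value(obs: MortalityObservation, completeness: dict[str, float]) -> float:
    c = completeness.get(obs.source, 1.0) if obs.completeness_adjustable else 1.0
    return float(
        np.log(obs.value / c) + log_rate_bias_correction(obs.design_variance)
    )


def score_models(
    surfaces: list[RateSurface],
    test: list[MortalityObservation],
    completeness: dict[str, float] | None = None,
    ranking: str = "rmse",
) -> list[ModelScore]:
    """Score each surface on held-out observations.

    RMSE is root-mean-square of (log corrected observation − log posterior
    median); coverage95 is the fraction of test points inside the model's
    central 95% predictive interval — the posterior of the latent log rate
    widened by the observation's own design variance, since a held-out data
    point carries sampling noise the latent surface does not. Registration
    test values are divided by the model's completeness estimate (surface
    metadata) unless an explicit ``completeness`` mapping is given.
    ``ranking`` is "rmse" (coverage breaks ties) or "rank-sum" (sum of the
    RMSE rank and the |coverage − 0.95| rank).
    """
    if not test:
        raise ValueError("empty test set")
    scores = []
    for surface in surfaces:
        comp = completeness
        if comp is None:
            comp = surface.metadata.get("completeness", {}) or {}
        med = surface.median()
        log_draws = np.log(surface.draws)
        mu = log_draws.mean(axis=2)
        var = log_draws.var(axis=2)
        sq, covered = [], []
        for o in test:
            i = surface.province_index(o.province)
            j = surface.year_index(int(round(o.reference_year - 0.001)))
            logv = _corrected_log_value(o, comp)
            sq.append((logv - np.log(med[i, j])) ** 2)
            s = np.sqrt(var[i, j] + o.design_variance)
            covered.append(abs(logv - mu[i, j]) <= 1.959964 * s)
        scores.append(
            ModelScore(
                model_tag=surface.metadata.get("model_tag", "model"),
                rmse=float(np.sqrt(np.mean(sq))),
                coverage95=float(np.mean(covered)),
            )
        )
    _assign_ranks(scores, ranking)
    return scores


def _assign_ranks(scores: list[ModelScore], ranking: str) -> None:
    if ranking == "rmse":
        order = sorted(
            range(len(scores)),
            key=lambda k: (scores[k].rmse, abs(scores[k].coverage95 - 0.95)),
        )
    elif ranking == "rank-sum":
        by_rmse = np.argsort([s.rmse for s in scores], kind="stable")
        by_cov = np.argsort([abs(s.coverage95 - 0.95) for s in scores], kind="stable")
        rank_sum = np.empty(len(scores))
        for pos, k in enumerate(by_rmse):
            rank_sum[k] = pos
        for pos, k in enumerate(by_cov):
            rank_sum[k] += pos
        order = sorted(range(len(scores)), key=lambda k: (rank_sum[k], scores[k].rmse))
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    for pos, k in enumerate(order):
        scores[k].rank = pos + 1


def rank_weights(
    scores: list[ModelScore], scheme: str = "linear", decay: float = 1.0
) -> np.ndarray:
    """Monotonically declining weights from model ranks, normalized to one.

    ``linear``: weight ∝ K − rank + 1 (K=2 gives 2/3, 1/3);
    ``exponential``: weight ∝ exp(−decay·rank).
    """
    k = len(scores)
    ranks = np.array([s.rank for s in scores], dtype=float)
    if sorted(ranks) != list(range(1, k + 1)):
        raise ValueError("ranks must be a permutation of 1..K")
    if scheme == "linear":
        raw = k - ranks + 1.0
    elif scheme == "exponential":
        raw = np.exp(-decay * ranks)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    weights = raw / raw.sum()
    for s, w in zip(scores, weights):
        s.weight = float(w)
    return weights


def combine(
    surfaces: list[RateSurface],
    weights: np.ndarray,
    n_out_draws: int,
    seed: int,
) -> RateSurface:
    """Mixture of model posteriors: each output draw comes from model k with
    probability weight_k (drawing one of that model's posterior draws)."""
    if len(surfaces) != len(weights):
        raise ValueError("one weight per surface required")
    base = surfaces[0]
    for s in surfaces[1:]:
        if s.provinces != base.provinces or not np.array_equal(s.years, base.years):
            raise ValueError("surfaces must share provinces and years")
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValueError("weights must be non-negative and sum to one")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(surfaces), size=n_out_draws, p=weights)
    draws = np.empty((len(base.provinces), len(base.years), n_out_draws))
    for d, k in enumerate(which):
        src = surfaces[k]
        draws[:, :, d] = src.draws[:, :, rng.integers(src.n_draws)]
    return RateSurface(
        base.provinces,
        base.years,
        draws,
        {
            "model_tag": "bma",
            "seed": seed,
            "weights": {s.metadata.get("model_tag", f"m{k}"): float(w)
                        for k, (s, w) in enumerate(zip(surfaces, weights))},
            "completeness": surfaces[int(np.argmax(weights))].metadata.get(
                "completeness", {}
            ),
        },
    )


def scores_to_frame(scores: list[ModelScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_tag": s.model_tag,
                "rmse": s.rmse,
                "coverage95": s.coverage95,
                "rank": s.rank,
                "weight": s.weight,
            }
            for s in scores
        ]
    )
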