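"""Synthetic province-year panels with the structure the analysis assumes.

One latent rate surface, observed by several biased and incomplete sources,
with spatial correlation (intrinsic CAR over a province adjacency graph),
smooth temporal correlation (second-order random walk) and province-year
interaction noise:

    log U5MR[p,t] = x[p,t]·β + φ_p + ψ_t + ε_{p,t}
    log NMR[p,t]  = β0 + β1·log U5MR + β2·(log U5MR)² + δ_{p,t},
                    truncated so NMR ≤ U5MR.

Sources emulated:

* a death-registration system (DRS) that registers only a fraction
  (the completeness) of true deaths,
* summary birth histories (children ever born / dead per maternal age group),
* complete birth histories (per-child birth dates and survival).

All generation is deterministic given the config seed. Rates are deaths per
1,000 live births throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .birth_history import (
    AGE_GROUPS,
    DEFAULT_PARITIES,
    BirthRecord,
    SBH_COLUMNS,
    _piecewise_q,
)
from .core import (
    RATE_SCALE,
    AdjacencyGraph,
    MortalityObservation,
    icar_basis,
    rw2_basis,
)

COVARIATE_NAMES = ("wealth_index", "schooling_years", "urbanization")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults are the desk-scale fixture)."""

    n_provinces: int = 8
    year_start: int = 2005
    year_end: int = 2017
    graph_model: str = "grid"  # grid | ring | random-planar
    #: intercept + 3 covariate slopes on the log-rate scale (rates per 1,000)
    mean_coefs: tuple[float, float, float, float] = (3.0, -0.30, -0.20, -0.15)
    spatial_sd: float = 0.15
    temporal_sd: float = 0.10
    interaction_sd: float = 0.05
    obs_sd: float = 0.05
    completeness_range: tuple[float, float] = (0.6, 0.95)
    completeness_constant_over_time: bool = False
    births_per_province_year: int = 20_000
    #: log-log quadratic linking NMR to U5MR (β0, β1, β2)
    nmr_quad_coefs: tuple[float, float, float] = (-0.40, 1.05, -0.005)
    nmr_effect_sd: float = 0.05
    n_regions: int = 2
    seed: int = 20170101

    def __post_init__(self) -> None:
        if self.n_provinces < 4:
            raise ValueError("need at least 4 provinces")
        if self.year_end - self.year_start + 1 < 3:
            raise ValueError("year span must cover at least 3 years")
        lo, hi = self.completeness_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("completeness_range must be a sub-interval of (0, 1]")
        for name in ("spatial_sd", "temporal_sd", "interaction_sd", "obs_sd", "nmr_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.births_per_province_year <= 0:
            raise ValueError("births_per_province_year must be positive")
        if self.graph_model not in ("grid", "ring", "random-planar"):
            raise ValueError(f"unknown graph_model {self.graph_model!r}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("mean_coefs", "completeness_range", "nmr_quad_coefs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth surfaces plus everything needed to generate sources."""

    config: SyntheticConfig
    provinces: list[str]
    years: np.ndarray
    true_u5mr: np.ndarray  # (P, T), per 1,000
    true_nmr: np.ndarray  # (P, T), per 1,000
    covariates: np.ndarray  # (P, T, 3)
    completeness: np.ndarray  # (P, T) in (0, 1]
    live_births: np.ndarray  # (P, T) positive integers
    adjacency: AdjacencyGraph
    region_of: dict[str, str]
    spatial_effect: np.ndarray = field(repr=False, default=None)
    temporal_effect: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.all((self.true_nmr > 0) & (self.true_nmr <= self.true_u5mr)):
            raise ValueError("truth must satisfy 0 < NMR ≤ U5MR")
        if not np.all(self.true_u5mr < RATE_SCALE):
            raise ValueError("true U5MR must stay below 1,000 per 1,000")

    def year_index(self, year: int) -> int:
        return int(np.flatnonzero(self.years == int(year))[0])

    def covariate_frame(self) -> pd.DataFrame:
        p, t, _ = self.covariates.shape
        frame = pd.DataFrame(
            {
                "province": np.repeat(self.provinces, t),
                "year": np.tile(self.years, p),
            }
        )
        for k, name in enumerate(COVARIATE_NAMES):
            frame[name] = self.covariates[:, :, k].ravel()
        return frame

    def truth_frame(self) -> pd.DataFrame:
        p, t = self.true_u5mr.shape
        return pd.DataFrame(
            {
                "province": np.repeat(self.provinces, t),
                "year": np.tile(self.years, p),
                "true_u5mr": self.true_u5mr.ravel(),
                "true_nmr": self.true_nmr.ravel(),
                "completeness": self.completeness.ravel(),
                "live_births": self.live_births.ravel(),
                "region": [self.region_of[q] for q in np.repeat(self.provinces, t)],
            }
        )

    def write_csv(self, path) -> None:
        self.truth_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Adjacency builders
# ---------------------------------------------------------------------------

def build_adjacency(n: int, model: str, seed: int = 0) -> AdjacencyGraph:
    provinces = [f"P{i:02d}" for i in range(n)]
    edges: list[tuple[str, str]] = []
    if model == "ring":
        edges = [(provinces[i], provinces[(i + 1) % n]) for i in range(n)]
    elif model == "grid":
        ncol = int(np.ceil(np.sqrt(n)))
        for i in range(n):
            r, c = divmod(i, ncol)
            if c + 1 < ncol and i + 1 < n:
                edges.append((provinces[i], provinces[i + 1]))
            if i + ncol < n:
                edges.append((provinces[i], provinces[i + ncol]))
    elif model == "random-planar":
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n, 2))
        tri = Delaunay(pts)
        seen = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    e = tuple(sorted((int(simplex[a]), int(simplex[b]))))
                    seen.add(e)
        edges = [(provinces[a], provinces[b]) for a, b in sorted(seen)]
    else:
        raise ValueError(f"unknown graph model {model!r}")
    graph = AdjacencyGraph(provinces, edges)
    if not graph.is_connected():
        raise ValueError("generated adjacency graph is disconnected")
    return graph


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw one ground-truth panel from the generative model."""
    rng = np.random.default_rng(config.seed)
    n, years = config.n_provinces, config.years
    t = len(years)
    graph = build_adjacency(n, config.graph_model, seed=config.seed)
    provinces = graph.provinces

    # standardized covariates: province baseline + gentle time trend + noise
    cov = np.empty((n, t, 3))
    tt = (years - years.mean()) / max(t - 1, 1)
    for k in range(3):
        base = rng.normal(size=n)
        slope = rng.normal(scale=0.5, size=n)
        noise = rng.normal(scale=0.15, size=(n, t))
        raw = base[:, None] + slope[:, None] * tt[None, :] + noise
        cov[:, :, k] = (raw - raw.mean()) / raw.std()

    b = np.asarray(config.mean_coefs, dtype=float)
    eta = b[0] + np.tensordot(cov, b[1:], axes=([2], [0]))

    spatial = (
        icar_basis(graph).sample(config.spatial_sd, rng)
        if config.spatial_sd > 0
        else np.zeros(n)
    )
    temporal = (
        rw2_basis(t).sample(config.temporal_sd, rng)
        if config.temporal_sd > 0
        else np.zeros(t)
    )
    interaction = rng.normal(scale=config.interaction_sd, size=(n, t)) if config.interaction_sd > 0 else np.zeros((n, t))

    log_u5 = eta + spatial[:, None] + temporal[None, :] + interaction
    true_u5mr = np.exp(log_u5)

    b0, b1, b2 = config.nmr_quad_coefs
    delta = rng.normal(scale=config.nmr_effect_sd, size=(n, t)) if config.nmr_effect_sd > 0 else np.zeros((n, t))
    log_nmr = b0 + b1 * log_u5 + b2 * log_u5**2 + delta
    true_nmr = np.minimum(np.exp(log_nmr), true_u5mr)

    if config.completeness_constant_over_time:
        comp = rng.uniform(*config.completeness_range, size=n)[:, None] * np.ones((1, t))
    else:
        comp = rng.uniform(*config.completeness_range, size=(n, t))

    births = np.full((n, t), config.births_per_province_year, dtype=int)

    per_region = int(np.ceil(n / config.n_regions))
    region_of = {
        p: f"R{min(i // per_region, config.n_regions - 1) + 1}" for i, p in enumerate(provinces)
    }

    return SyntheticTruth(
        config=config,
        provinces=provinces,
        years=years,
        true_u5mr=true_u5mr,
        true_nmr=true_nmr,
        covariates=cov,
        completeness=comp,
        live_births=births,
        adjacency=graph,
        region_of=region_of,
        spatial_effect=spatial,
        temporal_effect=temporal,
    )


# ---------------------------------------------------------------------------
# Source generation
# ---------------------------------------------------------------------------

def generate_drs(truth: SyntheticTruth, seed: int) -> list[MortalityObservation]:
    """Registered under-5 and neonatal death counts under incompleteness.

    Under-5 registrations are Binomial(live births, rate/1000 × completeness);
    neonatal registrations are drawn as the neonatal share of the registered
    under-5 deaths, so a province-year's neonatal count never exceeds its
    under-5 count and both have expectation completeness × true rate × births.
    Observed rates carry the generating completeness for oracle checks; the
    models never read it.
    """
    rng = np.random.default_rng(seed)
    out: list[MortalityObservation] = []
    p, t = truth.true_u5mr.shape
    for i in range(p):
        for j in range(t):
            births = int(truth.live_births[i, j])
            c = float(truth.completeness[i, j])
            pu5 = truth.true_u5mr[i, j] / RATE_SCALE * c
            u5_count = rng.binomial(births, min(pu5, 1.0))
            share = truth.true_nmr[i, j] / truth.true_u5mr[i, j]
            neo_count = rng.binomial(u5_count, share) if u5_count > 0 else 0
            for measure, count in (("U5MR", u5_count), ("NMR", neo_count)):
                eff = count if count > 0 else 0.5
                out.append(
                    MortalityObservation(
                        source="DRS",
                        province=truth.provinces[i],
                        reference_year=float(truth.years[j]),
                        measure=measure,
                        value=eff / births * RATE_SCALE,
                        design_variance=1.0 / eff,
                        completeness_adjustable=True,
                        completeness=c,
                    )
                )
    return out


def _hazard_params(truth: SyntheticTruth, province_idx: int, year_idx: int) -> tuple[float, float]:
    """Two-piece constant-hazard survival curve for one birth cohort."""
    q5 = truth.true_u5mr[province_idx, year_idx] / RATE_SCALE
    p_neo = truth.true_nmr[province_idx, year_idx] / RATE_SCALE
    p_month = 1.0 - ((1.0 - q5) / (1.0 - p_neo)) ** (1.0 / 59.0)
    return p_neo, p_month


def generate_summary_birth_history(
    truth: SyntheticTruth,
    province: str,
    survey_year: int,
    n_mothers_per_agegroup: int,
    seed: int,
    parities: tuple[float, ...] = DEFAULT_PARITIES,
) -> pd.DataFrame:
    """Children ever born / children dead per maternal age group.

    Each mother's children-ever-born count is Poisson with the age-group
    parity; each birth gets a uniform age-at-birth between 15 and the
    mother's (uniform within-band) age, and dies by the survey with the
    probability implied by the true mortality surface of its birth cohort at
    its current age.
    """
    if survey_year < truth.years[0]:
        raise ValueError("survey year precedes the truth horizon")
    rng = np.random.default_rng(seed)
    pi = truth.provinces.index(province)
    rows = []
    for gi, group in enumerate(AGE_GROUPS):
        lo = 15.0 + 5.0 * gi
        ceb_counts = rng.poisson(parities[gi], size=n_mothers_per_agegroup)
        total_ceb = int(ceb_counts.sum())
        if total_ceb == 0:
            rows.append(
                {"maternal_age_group": group, "ceb": 0, "cd": 0,
                 "n_mothers": n_mothers_per_agegroup, "missing_fraction": 0.0}
            )
            continue
        mother_age = np.repeat(rng.uniform(lo, lo + 5.0, n_mothers_per_agegroup), ceb_counts)
        birth_age = rng.uniform(15.0, np.maximum(mother_age, 15.0 + 1e-6))
        child_age_years = mother_age - birth_age
        birth_year = np.clip(
            np.floor(survey_year - child_age_years).astype(int),
            truth.years[0],
            truth.years[-1],
        )
        q = np.empty(total_ceb)
        for y in np.unique(birth_year):
            mask = birth_year == y
            p_neo, p_month = _hazard_params(truth, pi, truth.year_index(int(y)))
            q[mask] = _piecewise_q(child_age_years[mask] * 12.0, p_neo, p_month)
        cd = int(rng.binomial(1, q).sum())
        rows.append(
            {"maternal_age_group": group, "ceb": total_ceb, "cd": cd,
             "n_mothers": n_mothers_per_agegroup, "missing_fraction": 0.0}
        )
    return pd.DataFrame(rows, columns=SBH_COLUMNS)


def generate_complete_birth_history(
    truth: SyntheticTruth,
    province: str,
    survey_year: int,
    n_mothers: int,
    seed: int,
    mean_parity: float = 2.5,
    weight_sd: float = 0.2,
) -> list[BirthRecord]:
    """Per-child birth records with deaths from piecewise-constant hazards.

    Births are spread uniformly (at month resolution) over the 15 years
    before the survey; each child faces its birth cohort's neonatal-month
    hazard and a constant month-1–59 hazard consistent with the cohort's
    true 5q0. Children whose simulated death falls after the survey date are
    recorded as alive (right-censoring at interview).
    """
    if survey_year < truth.years[0]:
        raise ValueError("survey year precedes the truth horizon")
    rng = np.random.default_rng(seed)
    pi = truth.provinces.index(province)
    survey_time = survey_year + 0.5

    n_births = int(rng.poisson(mean_parity, size=n_mothers).sum())
    birth_month = rng.integers(0, 15 * 12, size=n_births)  # months before survey
    birth_time = survey_time - (birth_month + 0.5) / 12.0
    birth_year = np.clip(np.floor(birth_time).astype(int), truth.years[0], truth.years[-1])
    weights = rng.lognormal(mean=0.0, sigma=weight_sd, size=n_births) if weight_sd > 0 else np.ones(n_births)

    # per-cohort hazards, then a vectorized inverse-CDF draw of death month:
    # die in the neonatal month w.p. p_neo, else geometric over months 1..59
    p_neo = np.empty(n_births)
    p_month = np.empty(n_births)
    for y in np.unique(birth_year):
        mask = birth_year == y
        pn, pm = _hazard_params(truth, pi, truth.year_index(int(y)))
        p_neo[mask], p_month[mask] = pn, pm
    u = rng.uniform(size=n_births)
    death_month = np.full(n_births, -1)  # -1: survives to age 5
    neo = u < p_neo
    death_month[neo] = 0
    rem = np.clip((u - p_neo) / (1.0 - p_neo), 1e-15, 1.0 - 1e-15)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.floor(np.log1p(-rem) / np.log1p(-np.maximum(p_month, 1e-15))) + 1
    later = (~neo) & (p_month > 0) & (k < 60)
    death_month[later] = k[later].astype(int)

    age_at_survey_months = (survey_time - birth_time) * 12.0
    died = (death_month >= 0) & (death_month + 0.5 <= age_at_survey_months)
    return [
        BirthRecord(
            birth_time=float(birth_time[i]),
            alive=not died[i],
            age_at_death_months=int(death_month[i]) if died[i] else None,
            weight=float(weights[i]),
        )
        for i in range(n_births)
    ]
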