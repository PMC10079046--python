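"""Scenario projection of neonatal mortality to 2030 against SDG 3.2.

The annual rate of reduction (ARR) between two rates is
ARR = ln(rate_t1 / rate_t2) / (t2 − t1), positive when mortality declines.
Five scenarios set each province's 2018–2030 ARR:

* S1_constant       — rates stay at their base-year level (ARR 0);
* S2_own_trend      — each province keeps its own 2010–2017 ARR;
* S3_regional_best  — each province adopts the best (largest) ARR achieved
                      in its region;
* S4_sdg_target     — provinces above the SDG threshold decline exactly to
                      the threshold by 2030, the rest keep their own trend;
* S5_richest_trend  — every province adopts the mean ARR of a designated
                      set of highest-income provinces.

Projected rates are NMR_p(t) = NMR_p(base)·exp(−ARR_p·(t − base)); death
counts multiply by live births; a province meets SDG 3.2 if its 2030 NMR is
at or below 12 per 1,000 live births.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCENARIO_IDS = (
    "S1_constant",
    "S2_own_trend",
    "S3_regional_best",
    "S4_sdg_target",
    "S5_richest_trend",
)


def arr(rate_t1: float, rate_t2: float, t1: float, t2: float) -> float:
    """Annual rate of reduction between two rates (natural-log units/year)."""
    if rate_t1 <= 0 or rate_t2 <= 0:
        raise ValueError("rates must be positive")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return math.log(rate_t1 / rate_t2) / (t2 - t1)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ScenarioSpec:
    id: str
    base_year: int = 2017
    horizon: int = 2030
    sdg_threshold: float = 12.0
    region_of: dict[str, str] | None = None  # required for S3
    rich_provinces: list[str] | None = None  # required for S5

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario {self.id!r}; expected one of {SCENARIO_IDS}")
        if self.horizon <= self.base_year:
            raise ValueError("horizon must follow the base year")
        if self.sdg_threshold <= 0:
            raise ValueError("SDG threshold must be positive")


@dataclass
class ProjectionResult:
    scenario_id: str
    provinces: list[str]
    years: np.ndarray  # base_year+1 .. horizon
    nmr_path: pd.DataFrame  # province × year rates
    deaths_path: pd.DataFrame  # province × year expected deaths (full precision)
    national_path: pd.Series  # live-birth-weighted national NMR per year
    sdg_flags: dict[str, bool]
    sdg_threshold: float
    live_births: pd.DataFrame = field(repr=False, default=None)

    @property
    def cumulative_deaths(self) -> int:
        return round_half_up(float(self.deaths_path.to_numpy().sum()))

    @property
    def deaths_2030(self) -> int:
        return round_half_up(float(self.deaths_path[self.years[-1]].sum()))

    @property
    def national_nmr_2030(self) -> float:
        return float(self.national_path.iloc[-1])

    def summary(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "national_nmr_2030": self.national_nmr_2030,
            "deaths_2030": self.deaths_2030,
            "cumulative_deaths": self.cumulative_deaths,
            "provinces_meeting_sdg": sum(self.sdg_flags.values()),
            "provinces_above_sdg": sum(not v for v in self.sdg_flags.values()),
        }


def scenario_arrs(
    base_rates: pd.Series,
    aarr_table: pd.Series,
    spec: ScenarioSpec,
) -> pd.Series:
    """Per-province ARR for 2018–2030 under one scenario."""
    provinces = list(base_rates.index)
    missing = set(provinces) - set(aarr_table.index)
    if spec.id != "S1_constant" and missing:
        raise ValueError(f"aarr_table missing provinces: {sorted(missing)}")

    if spec.id == "S1_constant":
        return pd.Series(0.0, index=provinces)
    if spec.id == "S2_own_trend":
        return aarr_table.loc[provinces].astype(float)
    if spec.id == "S3_regional_best":
        if spec.region_of is None:
            raise ValueError("scenario S3_regional_best requires a province→region map")
        gap = set(provinces) - set(spec.region_of)
        if gap:
            raise ValueError(f"region map missing provinces: {sorted(gap)}")
        best: dict[str, float] = {}
        for p in provinces:
            r = spec.region_of[p]
            best[r] = max(best.get(r, -np.inf), float(aarr_table[p]))
        return pd.Series({p: best[spec.region_of[p]] for p in provinces})
    if spec.id == "S4_sdg_target":
        span = spec.horizon - spec.base_year
        out = {}
        for p in provinces:
            base = float(base_rates[p])
            if base > spec.sdg_threshold:
                out[p] = math.log(base / spec.sdg_threshold) / span
            else:
                out[p] = float(aarr_table[p])
        return pd.Series(out)
    # S5_richest_trend
    if spec.rich_provinces is None:
        raise ValueError(
            "scenario S5_richest_trend requires the designated high-income province set"
        )
    gap = set(spec.rich_provinces) - set(aarr_table.index)
    if gap:
        raise ValueError(f"aarr_table missing high-income provinces: {sorted(gap)}")
    target = float(aarr_table.loc[list(spec.rich_provinces)].mean())
    return pd.Series(target, index=provinces)


def _births_frame(
    live_births, provinces: list[str], years: np.ndarray
) -> pd.DataFrame:
    if isinstance(live_births, pd.DataFrame):
        frame = live_births.copy()
        frame.columns = [int(c) for c in frame.columns]
        missing_p = set(provinces) - set(frame.index)
        missing_y = set(int(y) for y in years) - set(frame.columns)
        if missing_p or missing_y:
            raise ValueError(
                f"live-birth table missing provinces {sorted(missing_p)} "
                f"or years {sorted(missing_y)}"
            )
        return frame.loc[provinces, list(years)]
    series = pd.Series(live_births).astype(float)
    missing_p = set(provinces) - set(series.index)
    if missing_p:
        raise ValueError(f"live-birth table missing provinces: {sorted(missing_p)}")
    return pd.DataFrame(
        np.tile(series.loc[provinces].to_numpy()[:, None], (1, len(years))),
        index=provinces,
        columns=list(years),
    )


def project_scenario(
    base_rates: pd.Series,
    aarr_table: pd.Series,
    spec: ScenarioSpec,
    live_births,
) -> ProjectionResult:
    """Project NMR from the base year to the horizon under one scenario.

    ``base_rates``: NMR per province at the base year (per 1,000);
    ``aarr_table``: each province's observed ARR over the reference window;
    ``live_births``: per-province annual live births (Series, constant over
    time) or a province × year DataFrame covering the projection years.
    Death counts stay at full precision internally and are rounded half-up
    only in the reported integers.
    """
    provinces = list(base_rates.index)
    years = np.arange(spec.base_year + 1, spec.horizon + 1)
    arrs = scenario_arrs(base_rates, aarr_table, spec)
    births = _births_frame(live_births, provinces, years)

    horizon_offsets = years - spec.base_year
    path = np.exp(
        -np.outer(arrs.loc[provinces].to_numpy(), horizon_offsets)
    ) * base_rates.to_numpy()[:, None]
    nmr_path = pd.DataFrame(path, index=provinces, columns=list(years))
    deaths_path = nmr_path / 1000.0 * births
    national = (nmr_path * births).sum(axis=0) / births.sum(axis=0)
    final = nmr_path[int(years[-1])]
    flags = {p: bool(final[p] <= spec.sdg_threshold) for p in provinces}
    return ProjectionResult(
        scenario_id=spec.id,
        provinces=provinces,
        years=years,
        nmr_path=nmr_path,
        deaths_path=deaths_path,
        national_path=national,
        sdg_flags=flags,
        sdg_threshold=spec.sdg_threshold,
        live_births=births,
    )


def lives_saved(result_a: ProjectionResult, result_b: ProjectionResult) -> int:
    """Cumulative deaths under a minus under b (positive when b saves lives)."""
    if not np.array_equal(result_a.years, result_b.years):
        raise ValueError("projection horizons differ")
    if result_a.live_births is not None and result_b.live_births is not None:
        if not result_a.live_births.equals(result_b.live_births):
            raise ValueError("projections use different live-birth inputs")
    return result_a.cumulative_deaths - result_b.cumulative_deaths
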