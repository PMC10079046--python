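"""Birth-history estimators of under-5 mortality and the data-quality gate.

Three estimation routes feed the stage models:

* ``cbh_u5mr`` — direct estimation from complete birth histories: weighted
  under-5 deaths over weighted person-years of exposure in a calendar year,
  converted to a 5q0-type probability via the constant-hazard identity
  5q0 = 1 − exp(−5m).
* ``mac_estimate`` / ``map_estimate`` — indirect (Brass-type) estimation from
  summary birth histories: children-dead over children-ever-born ratios per
  maternal age group, scaled by cohort multipliers and located in time by
  cohort offsets (MAC), or pooled into pre-survey period buckets (MAP).
* ``qc_gate`` — the missingness / sex-ratio plausibility screen applied to a
  candidate data source before it enters the pipeline.

The MAC/MAP multipliers and time offsets are a pluggable
:class:`CoefficientSet`: a classical fixed default is shipped, an identity
set supports algebraic tests, and :meth:`CoefficientSet.calibrated` derives
a set for a stated fertility schedule by direct exposure simulation (the
standard way such coefficients are produced from model schedules).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RATE_SCALE, MortalityObservation

logger = logging.getLogger(__name__)

AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")

#: average children ever born per mother by maternal age group — a fixed,
#: configurable schedule; only the CEB/CD → mortality mapping is under test.
DEFAULT_PARITIES = (0.25, 1.0, 1.9, 2.6, 3.1, 3.4, 3.5)

SBH_COLUMNS = ["maternal_age_group", "ceb", "cd", "n_mothers", "missing_fraction"]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class BirthRecord:
    """One child from a complete birth history.

    birth_time is a decimal calendar year at month resolution; alive refers
    to status at the survey date; age_at_death_months is present iff the
    child died (integer months in [0, 60) — under-5 deaths only).
    """

    birth_time: float
    alive: bool
    age_at_death_months: int | None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.alive != (self.age_at_death_months is None):
            raise ValueError("age_at_death_months must be present iff the child died")
        if self.age_at_death_months is not None and not (0 <= self.age_at_death_months < 60):
            raise ValueError("age_at_death_months must lie in [0, 60)")
        if self.weight <= 0:
            raise ValueError("survey weight must be positive")


def validate_sbh(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SBH_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"SBH table missing columns: {sorted(missing)}")
    if table["maternal_age_group"].duplicated().any():
        raise ValueError("duplicate maternal age groups in SBH table")
    bad = table[table["cd"] > table["ceb"]]
    if len(bad):
        raise ValueError(f"children dead exceed children ever born in rows {list(bad.index)}")
    if (table[["ceb", "cd"]] < 0).any().any():
        raise ValueError("negative counts in SBH table")
    return table


def read_sbh_csv(path) -> pd.DataFrame:
    return validate_sbh(pd.read_csv(path))


def records_to_frame(records: list[BirthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "birth_time": [r.birth_time for r in records],
            "alive": [r.alive for r in records],
            "age_at_death_months": [
                np.nan if r.age_at_death_months is None else r.age_at_death_months
                for r in records
            ],
            "weight": [r.weight for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[BirthRecord]:
    out = []
    for _, row in frame.iterrows():
        age = row["age_at_death_months"]
        out.append(
            BirthRecord(
                birth_time=float(row["birth_time"]),
                alive=bool(row["alive"]),
                age_at_death_months=None if pd.isna(age) else int(age),
                weight=float(row["weight"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Data-quality gate
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    accepted: bool
    reasons: list[str]

    def __bool__(self) -> bool:
        return self.accepted


SEX_RATIO_BOUNDS = (1.00, 1.06)  # inclusive plausibility band for boys-to-girls


def qc_gate(
    missing_fraction: float,
    sex_ratio: float,
    missing_cutoff: float = 0.10,
) -> QCResult:
    """Accept or reject a data source on missingness and sex-ratio plausibility.

    Rejects when the key-variable missing fraction exceeds the cutoff
    (default 0.10, configurable within [0.05, 0.10]) or the boys-to-girls
    ratio falls outside [1.00, 1.06]; both bounds are inclusive on the accept
    side. Missing inputs raise — a source is never silently accepted.
    """
    if missing_fraction is None or sex_ratio is None:
        raise ValueError("qc_gate requires both missing_fraction and sex_ratio")
    if not (0.05 <= missing_cutoff <= 0.10):
        raise ValueError("missing_cutoff must lie in [0.05, 0.10]")
    if math.isnan(missing_fraction) or math.isnan(sex_ratio):
        raise ValueError("qc_gate statistics must be computable (got NaN)")
    reasons = []
    if missing_fraction > missing_cutoff:
        reasons.append(
            f"missing fraction {missing_fraction:.3f} exceeds cutoff {missing_cutoff:.2f}"
        )
    lo, hi = SEX_RATIO_BOUNDS
    if not (lo <= sex_ratio <= hi):
        reasons.append(f"sex ratio {sex_ratio:.3f} outside plausible band [{lo:.2f}, {hi:.2f}]")
    return QCResult(accepted=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Complete birth history — direct estimation
# ---------------------------------------------------------------------------

def cbh_u5mr(
    records: list[BirthRecord],
    calendar_year: int,
    province: str = "unknown",
    survey_time: float | None = None,
) -> MortalityObservation:
    """Direct U5MR for one calendar year from complete birth histories.

    The mortality rate m is total weighted under-5 deaths in the year divided
    by total weighted person-years of under-5 exposure; the probability-type
    rate is 5q0 = 1000·(1 − exp(−5m)). When no deaths fall in the year a
    continuity correction of half a death stabilises the estimate and its
    variance. The weighted-Poisson approximation gives the design variance
    1/(weighted deaths) on the log scale.
    """
    y0, y1 = float(calendar_year), float(calendar_year) + 1.0
    if survey_time is not None:
        y1 = min(y1, survey_time)
    if y1 <= y0:
        raise ValueError("calendar year lies after the survey date")

    exposure = 0.0
    deaths = 0.0
    for r in records:
        entry = r.birth_time
        exit_time = entry + 5.0
        if not r.alive:
            exit_time = entry + (r.age_at_death_months + 0.5) / 12.0
        lo = max(entry, y0)
        hi = min(exit_time, y1)
        if hi > lo:
            exposure += r.weight * (hi - lo)
        if not r.alive and y0 <= entry + (r.age_at_death_months + 0.5) / 12.0 < y1:
            deaths += r.weight

    if exposure <= 0:
        raise ValueError(f"no under-5 exposure in year {calendar_year}")
    effective_deaths = deaths if deaths > 0 else 0.5
    m = effective_deaths / exposure
    value = RATE_SCALE * (1.0 - math.exp(-5.0 * m))
    return MortalityObservation(
        source="CBH",
        province=province,
        reference_year=calendar_year + 0.5,
        measure="U5MR",
        value=value,
        design_variance=1.0 / effective_deaths,
    )


def cbh_u5mr_series(
    records: list[BirthRecord],
    years: np.ndarray,
    province: str = "unknown",
    survey_time: float | None = None,
    min_expected_deaths: float = 1.0,
) -> list[MortalityObservation]:
    """Vectorized direct U5MR estimates for several calendar years.

    Same estimator as :func:`cbh_u5mr`, with two safeguards for multi-year
    use: calendar years whose under-5 cohorts are not fully observed (births
    before the survey's recall window would have contributed exposure) are
    skipped — including them keeps only the youngest, highest-hazard
    children and biases the rate upward — and the design variance uses a
    working death count from an exogenous reference rate rather than the
    year's own count, so weights are not correlated with the estimates.
    Years whose working expected deaths fall below ``min_expected_deaths``
    are skipped.
    """
    if not records:
        return []
    bt = np.array([r.birth_time for r in records])
    w = np.array([r.weight for r in records])
    dead = np.array([not r.alive for r in records])
    dtime = np.array(
        [
            r.birth_time + ((r.age_at_death_months or 0) + 0.5) / 12.0 if not r.alive else np.inf
            for r in records
        ]
    )
    exit_time = np.where(dead, dtime, bt + 5.0)
    first_full_year = bt.min() + 5.0  # cohorts fully observed from here on

    cells = []
    for year in np.asarray(years, dtype=int):
        y0, y1 = float(year), float(year) + 1.0
        if y0 < first_full_year:
            continue
        if survey_time is not None:
            y1 = min(y1, survey_time)
        if y1 <= y0:
            continue
        exposure = float(
            (w * np.clip(np.minimum(exit_time, y1) - np.maximum(bt, y0), 0.0, None)).sum()
        )
        deaths = float((w * (dead & (dtime >= y0) & (dtime < y1))).sum())
        if exposure <= 0:
            continue
        cells.append((year, exposure, deaths))
    if not cells:
        return []
    m_working = -math.log(1.0 - WORKING_Q5) / 5.0

    out = []
    for year, exposure, deaths in cells:
        lam_working = exposure * m_working
        if lam_working < min_expected_deaths:
            continue
        m = max(deaths, 0.5) / exposure
        out.append(
            MortalityObservation(
                source="CBH",
                province=province,
                reference_year=year + 0.5,
                measure="U5MR",
                value=RATE_SCALE * (1.0 - math.exp(-5.0 * m)),
                design_variance=1.0 / lam_working,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summary birth history — indirect estimation
# ---------------------------------------------------------------------------

@dataclass
class CoefficientSet:
    """Multipliers and time offsets turning CD/CEB ratios into located 5q0.

    One row per maternal age group: ``multiplier`` scales the raw proportion
    dead to a 5q0, ``time_offset`` (years before the survey) locates the
    estimate in time.
    """

    table: pd.DataFrame  # index: age group; columns: multiplier, time_offset

    def __post_init__(self) -> None:
        need = {"multiplier", "time_offset"}
        if not need <= set(self.table.columns):
            raise ValueError(f"CoefficientSet requires columns {sorted(need)}")

    @classmethod
    def identity(cls, offsets: tuple[float, ...] | None = None) -> "CoefficientSet":
        """All multipliers one, with standard Brass-type time offsets."""
        offs = offsets or (1.2, 2.6, 4.4, 6.5, 8.9, 11.2, 13.5)
        return cls(
            pd.DataFrame(
                {"multiplier": np.ones(len(AGE_GROUPS)), "time_offset": list(offs)},
                index=list(AGE_GROUPS),
            )
        )

    @classmethod
    def classical_default(cls) -> "CoefficientSet":
        """Fixed Brass/Trussell-style coefficients for general use.

        Multipliers correct the raw proportion dead for the incomplete
        exposure of young cohorts' children (largest for the 15–19 group,
        near one from 30–34 onward); offsets are the usual increasing
        location of each cohort's effective reference time before the survey.
        """
        return cls(
            pd.DataFrame(
                {
                    "multiplier": [1.30, 1.17, 1.05, 1.00, 0.99, 0.99, 0.99],
                    "time_offset": [1.2, 2.6, 4.4, 6.5, 8.9, 11.2, 13.5],
                },
                index=list(AGE_GROUPS),
            )
        )

    @classmethod
    def calibrated(
        cls,
        parities: tuple[float, ...] = DEFAULT_PARITIES,
        reference_q5: float = 0.02,
        neonatal_share: float = 0.74,
        n_sim: int = 200_000,
        seed: int = 0,
    ) -> "CoefficientSet":
        """Derive multipliers/offsets for a fertility schedule by simulation.

        For each maternal age group, simulate mothers' ages (uniform within
        the band), ages at birth (uniform from 15 to current age) and expose
        each child to a flat reference survival curve; the multiplier is
        reference 5q0 over the expected proportion dead, and the offset is
        the mean age of the group's children at the survey (deaths cluster
        near birth, so a cohort's ratio reflects mortality around its mean
        birth time).
        """
        rng = np.random.default_rng(seed)
        p_neo = reference_q5 * neonatal_share  # age pattern of the reference curve
        p_month = 1.0 - ((1.0 - reference_q5) / (1.0 - p_neo)) ** (1.0 / 59.0)
        mult, offs = [], []
        for gi, group in enumerate(AGE_GROUPS):
            lo = 15.0 + 5.0 * gi
            ages = rng.uniform(lo, lo + 5.0, n_sim)
            birth_age = rng.uniform(15.0, np.maximum(ages, 15.0 + 1e-6))
            child_age_months = np.clip((ages - birth_age) * 12.0, 0.0, None)
            q = _piecewise_q(child_age_months, p_neo, p_month)
            mult.append(reference_q5 / max(q.mean(), 1e-12))
            offs.append(float((ages - birth_age).mean()))
        return cls(
            pd.DataFrame(
                {"multiplier": mult, "time_offset": offs}, index=list(AGE_GROUPS)
            )
        )

    @classmethod
    def from_csv(cls, path) -> "CoefficientSet":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _piecewise_q(age_months: np.ndarray, p_neo: float, p_month: float) -> np.ndarray:
    """Probability of dying by a given age (months) under the two-piece
    constant-hazard survival curve (neonatal month, months 1–59)."""
    a = np.asarray(age_months, dtype=float)
    frac_neo = np.clip(a, 0.0, 1.0)
    frac_rest = np.clip(a - 1.0, 0.0, 59.0)
    surv = (1.0 - p_neo) ** frac_neo * (1.0 - p_month) ** frac_rest
    return 1.0 - surv


#: exogenous working 5q0 for design-variance calculations — variances built
#: from the survey's own death counts are correlated with its estimates and
#: bias any precision-weighted fit upward
WORKING_Q5 = 0.02


def _sbh_design_variance(q_working: float, ceb: float) -> float:
    """Binomial variance of log q under an exogenous working proportion dead."""
    q = min(max(q_working, 0.5 / max(ceb, 1.0)), 0.999)
    return (1.0 - q) / (q * ceb)


def mac_estimate(
    table: pd.DataFrame,
    survey_year: float,
    coefs: CoefficientSet,
    province: str = "unknown",
) -> pd.DataFrame:
    """Maternal-age-cohort estimates: one time-located 5q0 per age group.

    Returns a frame with columns (cohort, reference_year, q5_per_1000,
    design_variance); rows with zero children ever born are dropped with a
    warning. ``estimates_to_observations`` converts to the shared observation
    type (zero-death cohorts get a continuity floor there, since a log-scale
    observation cannot be exactly zero).
    """
    validate_sbh(table)
    usable = table[table["ceb"] > 0]
    dropped = set(table["maternal_age_group"]) - set(usable["maternal_age_group"])
    if dropped:
        logger.warning("dropping age groups with zero CEB: %s", sorted(dropped))
    if len(usable) < 3:
        raise ValueError("need at least 3 age-group rows with CEB > 0")
    rows = []
    for _, row in usable.iterrows():
        group = row["maternal_age_group"]
        if group not in coefs.table.index:
            raise ValueError(f"no coefficients for age group {group!r}")
        mult = float(coefs.table.loc[group, "multiplier"])
        offset = float(coefs.table.loc[group, "time_offset"])
        ratio = row["cd"] / row["ceb"]
        q5 = ratio * mult
        rows.append(
            {
                "cohort": group,
                "reference_year": survey_year - offset,
                "q5_per_1000": RATE_SCALE * q5,
                "design_variance": _sbh_design_variance(WORKING_Q5 / max(mult, 1e-9), row["ceb"]),
                "ceb": row["ceb"],
            }
        )
    return pd.DataFrame(rows)


#: pre-survey period buckets (years before survey) used by the period variant
MAP_PERIODS = ((0.0, 5.0, "0-4"), (5.0, 10.0, "5-9"), (10.0, 15.0, "10-14"))


def map_estimate(
    table: pd.DataFrame,
    survey_year: float,
    coefs: CoefficientSet,
    province: str = "unknown",
) -> pd.DataFrame:
    """Maternal-age-period estimates: one 5q0 per pre-survey period bucket.

    Age groups are assigned to period buckets by their time offsets; CEB and
    CD pool within a bucket and the bucket multiplier is the CEB-weighted
    mean of its member multipliers.
    """
    validate_sbh(table)
    usable = table[table["ceb"] > 0]
    if len(usable) < 3:
        raise ValueError("need at least 3 age-group rows with CEB > 0")
    dropped = set(table["maternal_age_group"]) - set(usable["maternal_age_group"])
    if dropped:
        logger.warning("dropping age groups with zero CEB: %s", sorted(dropped))

    rows = []
    for lo, hi, label in MAP_PERIODS:
        ceb_tot = cd_tot = mw = ow = 0.0
        for _, row in usable.iterrows():
            group = row["maternal_age_group"]
            offset = float(coefs.table.loc[group, "time_offset"])
            if lo <= offset < hi:
                ceb_tot += row["ceb"]
                cd_tot += row["cd"]
                mw += row["ceb"] * float(coefs.table.loc[group, "multiplier"])
                ow += row["ceb"] * offset
        if ceb_tot <= 0:
            continue
        ratio = cd_tot / ceb_tot
        mult = mw / ceb_tot
        q5 = ratio * mult
        rows.append(
            {
                "period": label,
                "reference_year": survey_year - ow / ceb_tot,
                "q5_per_1000": RATE_SCALE * q5,
                "design_variance": _sbh_design_variance(WORKING_Q5 / max(mult, 1e-9), ceb_tot),
                "ceb": ceb_tot,
            }
        )
    return pd.DataFrame(rows)


def estimates_to_observations(
    estimates: pd.DataFrame,
    province: str,
    source: str,
    horizon: tuple[float, float] | None = None,
) -> list[MortalityObservation]:
    """Convert a MAC/MAP estimate frame to MortalityObservations.

    Zero estimates get a continuity floor of half a death among the pooled
    CEB (the shared observation type carries log-scale rates, which cannot be
    exactly zero); estimates located outside the horizon are dropped, as are
    rows whose expected death count is below two (log-scale rates from such
    sparse cells are dominated by count artifacts rather than mortality).
    """
    out = []
    for _, row in estimates.iterrows():
        year = float(row["reference_year"])
        if horizon is not None and not (horizon[0] <= year <= horizon[1]):
            continue
        if float(row["design_variance"]) > 0.5:  # expected deaths < 2
            continue
        value = float(row["q5_per_1000"])
        if value <= 0:
            value = RATE_SCALE * 0.5 / max(float(row.get("ceb", 1.0)), 1.0)
        out.append(
            MortalityObservation(
                source=source,
                province=province,
                reference_year=year,
                measure="U5MR",
                value=min(value, RATE_SCALE - 1e-6),
                design_variance=float(row["design_variance"]),
            )
        )
    return out
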