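"""Shared containers for subnational mortality estimation.

Everything downstream operates on three objects:

* :class:`MortalityObservation` — one data point from one source (death
  registration, summary/complete birth history), carrying a rate per 1,000
  live births and a design variance on the log scale.
* :class:`AdjacencyGraph` — the province neighbourhood structure used by the
  CAR/BYM spatial terms and by the graph-diffusion space kernel.
* :class:`RateSurface` — posterior draws of a latent rate indexed by
  province × year × draw.

The module also houses the structured-precision linear algebra (ICAR and
second-order random walk) shared by the synthetic generator and the
spatiotemporal model: both improper Gaussian Markov random fields are
represented by the eigenbasis of their precision restricted to the proper
subspace, scaled so a unit variance parameter gives unit typical marginal
variance (the BYM2 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

RATE_SCALE = 1000.0  # rates are deaths per 1,000 live births

SOURCES = ("DRS", "SBH_MAC", "SBH_MAP", "CBH")
MEASURES = ("U5MR", "NMR")


@dataclass
class MortalityObservation:
    """A single rate measurement feeding the stage models.

    value is deaths per 1,000 live births; design_variance is the sampling
    variance of log(value). completeness_adjustable marks sources (DRS) whose
    observed rate is the true rate times an unknown registration completeness;
    completeness stores the generating value when known (synthetic data), the
    models never read it during fitting.
    """

    source: str
    province: str
    reference_year: float
    measure: str
    value: float
    design_variance: float
    completeness_adjustable: bool = False
    completeness: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not (0.0 < self.value < RATE_SCALE):
            raise ValueError(f"rate {self.value} outside (0, {RATE_SCALE})")
        if self.design_variance < 0:
            raise ValueError("design_variance must be non-negative")


_OBS_COLUMNS = [
    "source",
    "province",
    "reference_year",
    "measure",
    "value",
    "design_variance",
    "completeness_adjustable",
    "completeness",
]


def observations_to_frame(observations: Iterable[MortalityObservation]) -> pd.DataFrame:
    rows = [
        {
            "source": o.source,
            "province": o.province,
            "reference_year": o.reference_year,
            "measure": o.measure,
            "value": o.value,
            "design_variance": o.design_variance,
            "completeness_adjustable": o.completeness_adjustable,
            "completeness": np.nan if o.completeness is None else o.completeness,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=_OBS_COLUMNS)


def frame_to_observations(frame: pd.DataFrame) -> list[MortalityObservation]:
    missing = set(_OBS_COLUMNS[:6]) - set(frame.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    out = []
    for i, row in frame.iterrows():
        try:
            comp = row.get("completeness", np.nan)
            out.append(
                MortalityObservation(
                    source=str(row["source"]),
                    province=str(row["province"]),
                    reference_year=float(row["reference_year"]),
                    measure=str(row["measure"]),
                    value=float(row["value"]),
                    design_variance=float(row["design_variance"]),
                    completeness_adjustable=bool(row.get("completeness_adjustable", False)),
                    completeness=None if pd.isna(comp) else float(comp),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"invalid observation at row {i}: {exc}") from exc
    return out


def read_observations_csv(path) -> list[MortalityObservation]:
    return frame_to_observations(pd.read_csv(path))


def write_observations_csv(observations: Iterable[MortalityObservation], path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)


class AdjacencyGraph:
    """Province neighbourhood structure with a fixed node ordering."""

    def __init__(self, provinces: Sequence[str], edges: Iterable[tuple[str, str]]):
        self.provinces = list(provinces)
        if len(set(self.provinces)) != len(self.provinces):
            raise ValueError("duplicate province labels")
        self._index = {p: i for i, p in enumerate(self.provinces)}
        g = nx.Graph()
        g.add_nodes_from(self.provinces)
        for a, b in edges:
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge ({a}, {b}) references unknown province")
            if a == b:
                raise ValueError(f"self-loop at {a}")
            g.add_edge(a, b)
        self.graph = g

    def __len__(self) -> int:
        return len(self.provinces)

    def index(self, province: str) -> int:
        return self._index[province]

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.provinces)

    def laplacian(self) -> np.ndarray:
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a

    def neighbors(self, province: str) -> list[str]:
        return sorted(self.graph.neighbors(province))

    def relabel(self, mapping: dict[str, str]) -> "AdjacencyGraph":
        provinces = [mapping[p] for p in self.provinces]
        edges = [(mapping[a], mapping[b]) for a, b in self.graph.edges]
        return AdjacencyGraph(provinces, edges)

    def to_edge_list(self) -> pd.DataFrame:
        rows = sorted((min(a, b), max(a, b)) for a, b in self.graph.edges)
        return pd.DataFrame(rows, columns=["province_a", "province_b"])

    def write_edge_list_csv(self, path) -> None:
        self.to_edge_list().to_csv(path, index=False)

    @classmethod
    def from_edge_list_csv(cls, path, provinces: Sequence[str] | None = None) -> "AdjacencyGraph":
        frame = pd.read_csv(path)
        edges = list(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))
        if provinces is None:
            provinces = sorted({p for e in edges for p in e})
        return cls(provinces, edges)


@dataclass
class RateSurface:
    """Posterior draws of a latent rate, province × year × draw.

    draws holds rates per 1,000 live births; metadata records at least the
    model tag and the seed that produced the draws.
    """

    provinces: list[str]
    years: np.ndarray
    draws: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (province, year, draw)")
        if self.draws.shape[:2] != (len(self.provinces), len(self.years)):
            raise ValueError(
                f"draws shape {self.draws.shape} inconsistent with "
                f"{len(self.provinces)} provinces × {len(self.years)} years"
            )
        if not np.all((self.draws > 0) & (self.draws < RATE_SCALE)):
            raise ValueError(f"all draws must lie in (0, {RATE_SCALE})")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[2]

    def province_index(self, province: str) -> int:
        return self.provinces.index(province)

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == int(year))
        if idx.size == 0:
            raise KeyError(f"year {year} not covered by surface")
        return int(idx[0])

    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=2)

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.draws, q, axis=2)

    def interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        alpha = (1.0 - level) / 2.0
        return self.quantile(alpha), self.quantile(1.0 - alpha)

    def at(self, province: str, year: int) -> np.ndarray:
        """All draws for one province-year."""
        return self.draws[self.province_index(province), self.year_index(year), :]

    def to_long_frame(self) -> pd.DataFrame:
        p, t, d = self.draws.shape
        return pd.DataFrame(
            {
                "province": np.repeat(self.provinces, t * d),
                "year": np.tile(np.repeat(self.years, d), p),
                "draw": np.tile(np.arange(d), p * t),
                "value": self.draws.ravel(),
            }
        )

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = self.interval(level)
        med = self.median()
        p, t = med.shape
        return pd.DataFrame(
            {
                "province": np.repeat(self.provinces, t),
                "year": np.tile(self.years, p),
                "median": med.ravel(),
                "lower95": lo.ravel(),
                "upper95": hi.ravel(),
            }
        )

    def write_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def write_summary_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "RateSurface":
        provinces = list(pd.unique(frame["province"]))
        years = np.sort(frame["year"].unique())
        n_draws = int(frame["draw"].max()) + 1
        draws = np.empty((len(provinces), len(years), n_draws))
        pidx = {p: i for i, p in enumerate(provinces)}
        yidx = {y: i for i, y in enumerate(years)}
        for (p, y), grp in frame.groupby(["province", "year"], sort=False):
            draws[pidx[p], yidx[y], grp["draw"].to_numpy()] = grp["value"].to_numpy()
        return cls(provinces, years, draws, metadata or {})


# ---------------------------------------------------------------------------
# Log-scale bias correction for count-based rate observations
# ---------------------------------------------------------------------------

def poisson_log_mean(lam: float) -> float:
    """E[log(max(X, 0.5))] for X ~ Poisson(λ) (exact sum for small λ).

    Rate estimates built from death counts are unbiased in levels but biased
    on the log scale (Jensen); models with a Gaussian likelihood on log rates
    need the observed log value shifted by log λ − E[log max(X, ½)].
    """
    lam = float(lam)
    if lam <= 0:
        raise ValueError("λ must be positive")
    if lam > 30.0:  # asymptotic: E[log X] ≈ log λ − 1/(2λ) − 1/(12λ²)
        return np.log(lam) - 1.0 / (2.0 * lam) - 1.0 / (12.0 * lam**2)
    k = np.arange(0, max(int(lam + 12 * np.sqrt(lam + 1)), 20))
    logpmf = -lam + k * np.log(lam) - _log_factorial(k)
    y = np.log(np.maximum(k, 0.5))
    return float(np.exp(logpmf) @ y)


def _log_factorial(k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(k, dtype=float) + 1.0)


def log_rate_bias_correction(design_variance: float) -> float:
    """Additive correction restoring E[log rate] from a count-based estimate.

    The design variance of a count-based log rate is ≈ 1/(expected deaths),
    so λ̂ = 1/variance; the correction log λ̂ − E[log max(X, ½)] is added to
    the observed log value before it enters a Gaussian-on-log likelihood.
    """
    if design_variance <= 1e-8:
        return 0.0
    lam = 1.0 / design_variance
    return float(np.log(lam) - poisson_log_mean(lam))


# ---------------------------------------------------------------------------
# Structured improper GMRF bases (ICAR and RW2)
# ---------------------------------------------------------------------------

def icar_precision(graph: AdjacencyGraph) -> np.ndarray:
    """Intrinsic CAR precision = graph Laplacian (rank P−1 on a connected graph)."""
    return graph.laplacian()


def rw2_precision(n: int) -> np.ndarray:
    """Second-order random-walk precision D₂ᵀD₂ (null space: constants and
    linear trends, hence linear time trends are unpenalized)."""
    if n < 3:
        raise ValueError("RW2 needs at least 3 time points")
    d2 = np.zeros((n - 2, n))
    for i in range(n - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d2.T @ d2


@dataclass
class ProperBasis:
    """Proper subspace of an improper GMRF prior.

    basis columns span the complement of the precision's null space; under a
    unit variance parameter the component is ``basis @ z`` with
    z ~ N(0, diag(scale²/eigvals)). ``scale`` makes the geometric mean of the
    implied marginal variances equal 1 so variance parameters are comparable
    across structured components (scaled-BYM2 convention).
    """

    basis: np.ndarray
    eigvals: np.ndarray
    scale: float

    @property
    def dim(self) -> int:
        return self.basis.shape[1]

    def sd_weights(self) -> np.ndarray:
        """Per-coordinate prior standard deviations under unit variance."""
        return self.scale / np.sqrt(self.eigvals)

    def sample(self, sd: float, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim) * self.sd_weights() * sd
        return self.basis @ z

    def marginal_variances(self) -> np.ndarray:
        w = self.sd_weights() ** 2
        return np.einsum("ij,j,ij->i", self.basis, w, self.basis)


def proper_basis(precision: np.ndarray, null_tol: float = 1e-9) -> ProperBasis:
    """Eigen-decompose an improper precision and drop its null space.

    Raises if the precision is not positive semidefinite (e.g. a malformed
    graph), and scales so the geometric mean marginal variance is 1.
    """
    precision = np.asarray(precision, dtype=float)
    eigvals, eigvecs = np.linalg.eigh(precision)
    if eigvals[0] < -1e-8 * max(1.0, abs(eigvals[-1])):
        raise ValueError("precision matrix is not positive semidefinite")
    keep = eigvals > null_tol * max(1.0, eigvals[-1])
    if not np.any(keep):
        raise ValueError("precision has empty proper subspace")
    basis = eigvecs[:, keep]
    vals = eigvals[keep]
    # unscaled marginal variances of basis @ z with z_j ~ N(0, 1/vals_j)
    margvar = np.einsum("ij,j,ij->i", basis, 1.0 / vals, basis)
    scale = 1.0 / np.sqrt(np.exp(np.mean(np.log(margvar))))
    return ProperBasis(basis=basis, eigvals=vals, scale=scale)


def icar_basis(graph: AdjacencyGraph) -> ProperBasis:
    if not graph.is_connected():
        raise ValueError(
            "adjacency graph is disconnected: the ICAR precision is rank-deficient "
            "beyond the sum-to-zero constraint; connect the graph or model islands separately"
        )
    return proper_basis(icar_precision(graph))


def rw2_basis(n: int) -> ProperBasis:
    return proper_basis(rw2_precision(n))
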