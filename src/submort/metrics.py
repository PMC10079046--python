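"""Derived reporting statistics: AARR tables, neonatal share of under-5
mortality, provincial ranges and ranks, SDG counts, national aggregation.

All internal arithmetic runs at full precision; table-style output rounds
rates and percent AARRs to one decimal only when formatting. The published
national/provincial point-rate table (Iran, 2010 and 2017) ships as package
data for arithmetic that starts from printed rates.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core import RateSurface
from .projection import arr

PANEL_COLUMNS = ["province", "year", "measure", "value"]


def load_printed_panel() -> pd.DataFrame:
    """Published national/regional/provincial U5MR and NMR point rates."""
    with resources.files("submort.data").joinpath("iran_table1.csv").open() as fh:
        return pd.read_csv(fh)


def printed_panel_tidy(level: str = "province") -> pd.DataFrame:
    """Printed rates in tidy (province, year, measure, value) form."""
    wide = load_printed_panel()
    wide = wide[wide["level"] == level]
    rows = []
    for _, r in wide.iterrows():
        for measure, col2010, col2017 in (
            ("U5MR", "u5mr_2010", "u5mr_2017"),
            ("NMR", "nmr_2010", "nmr_2017"),
        ):
            rows.append({"province": r["name"], "year": 2010, "measure": measure, "value": r[col2010]})
            rows.append({"province": r["name"], "year": 2017, "measure": measure, "value": r[col2017]})
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def surfaces_to_panel(u5mr: RateSurface, nmr: RateSurface | None = None) -> pd.DataFrame:
    """Posterior-median point estimates in tidy panel form."""
    frames = []
    for measure, surface in (("U5MR", u5mr), ("NMR", nmr)):
        if surface is None:
            continue
        med = surface.median()
        p, t = med.shape
        frames.append(
            pd.DataFrame(
                {
                    "province": np.repeat(surface.provinces, t),
                    "year": np.tile(surface.years, p),
                    "measure": measure,
                    "value": med.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _panel_column(panel: pd.DataFrame, measure: str, year: int) -> pd.Series:
    sel = panel[(panel["measure"] == measure) & (panel["year"] == int(year))]
    if sel.empty:
        raise ValueError(f"panel has no {measure} values for {year}")
    return sel.set_index("province")["value"].astype(float)


def neonatal_share(nmr_surface: RateSurface, u5mr_surface: RateSurface) -> dict:
    """Neonatal share of under-5 mortality, 100·NMR/U5MR per draw.

    Returns median and central 95% interval arrays (province × year). The
    share never exceeds 100 because NMR draws are truncated at U5MR.
    """
    if (
        nmr_surface.provinces != u5mr_surface.provinces
        or not np.array_equal(nmr_surface.years, u5mr_surface.years)
        or nmr_surface.n_draws != u5mr_surface.n_draws
    ):
        raise ValueError("NMR and U5MR surfaces are misaligned")
    share = 100.0 * nmr_surface.draws / u5mr_surface.draws
    return {
        "provinces": nmr_surface.provinces,
        "years": nmr_surface.years,
        "median": np.median(share, axis=2),
        "lower95": np.quantile(share, 0.025, axis=2),
        "upper95": np.quantile(share, 0.975, axis=2),
    }


def point_share(nmr_value: float, u5mr_value: float) -> float:
    """Neonatal share from point rates (percent)."""
    return 100.0 * nmr_value / u5mr_value


def provincial_range(panel: pd.DataFrame, measure: str, year: int) -> dict:
    """Max − min of provincial point rates, with the provinces attaining them."""
    col = _panel_column(panel, measure, year)
    if len(col) < 2:
        raise ValueError("need at least 2 provinces")
    return {
        "max": float(col.max()),
        "min": float(col.min()),
        "diff": float(col.max() - col.min()),
        "argmax": str(col.idxmax()),
        "argmin": str(col.idxmin()),
    }


def sdg_count(
    panel: pd.DataFrame, year: int, threshold: float = 12.0, measure: str = "NMR"
) -> tuple[int, list[str]]:
    """Provinces with rates strictly above the SDG threshold."""
    col = _panel_column(panel, measure, year)
    above = sorted(col.index[col > threshold])
    return len(above), above


def national_aggregate(surface: RateSurface, live_births) -> RateSurface:
    """Live-birth-weighted national rate, draw by draw.

    ``live_births``: per-province Series (constant over time) or a
    province × year array aligned with the surface.
    """
    if isinstance(live_births, pd.Series):
        missing = set(surface.provinces) - set(live_births.index)
        if missing:
            raise ValueError(f"live births missing provinces: {sorted(missing)}")
        w = np.tile(
            live_births.loc[surface.provinces].to_numpy(dtype=float)[:, None],
            (1, len(surface.years)),
        )
    else:
        w = np.asarray(live_births, dtype=float)
        if w.shape != (len(surface.provinces), len(surface.years)):
            raise ValueError("live-birth array misaligned with surface")
    weighted = np.einsum("ptd,pt->td", surface.draws, w) / w.sum(axis=0)[:, None]
    return RateSurface(
        ["National"],
        surface.years,
        weighted[None, :, :],
        {**surface.metadata, "model_tag": surface.metadata.get("model_tag", "") + "-national"},
    )


def aarr_table(panel: pd.DataFrame, measure: str, year1: int = 2010, year2: int = 2017) -> pd.Series:
    """Per-province ARR between two panel years (natural units per year)."""
    r1 = _panel_column(panel, measure, year1)
    r2 = _panel_column(panel, measure, year2)
    common = r1.index.intersection(r2.index)
    return pd.Series(
        {p: arr(r1[p], r2[p], year1, year2) for p in common}, name=f"aarr_{measure.lower()}"
    )


def rank_table(panel: pd.DataFrame, measure: str, years: tuple[int, int] = (2010, 2017)) -> pd.DataFrame:
    """Provincial ranks by rate (rank 1 = lowest rate; ties broken by label)."""
    out = {}
    for year in years:
        col = _panel_column(panel, measure, year).sort_index()
        order = sorted(col.index, key=lambda p: (col[p], p))
        out[f"rank_{year}"] = pd.Series({p: i + 1 for i, p in enumerate(order)})
    return pd.DataFrame(out)


def panel_summary(
    u5mr_surface: RateSurface,
    nmr_surface: RateSurface,
    live_births,
    year1: int = 2010,
    year2: int = 2017,
) -> pd.DataFrame:
    """Table-style per-province (plus national) summary.

    Rates are posterior medians rounded to one decimal at output; AARRs are
    computed on full precision and reported as percentages to one decimal.
    """
    nat_u5 = national_aggregate(u5mr_surface, live_births)
    nat_nmr = national_aggregate(nmr_surface, live_births)
    share = neonatal_share(nmr_surface, u5mr_surface)
    rows = []
    u5_med, nmr_med = u5mr_surface.median(), nmr_surface.median()

    def _row(name, u5_1, u5_2, nm_1, nm_2, share_2):
        return {
            "name": name,
            f"u5mr_{year1}": round(u5_1, 1),
            f"u5mr_{year2}": round(u5_2, 1),
            "u5mr_aarr_pct": round(100.0 * arr(u5_1, u5_2, year1, year2), 1),
            f"nmr_{year1}": round(nm_1, 1),
            f"nmr_{year2}": round(nm_2, 1),
            "nmr_aarr_pct": round(100.0 * arr(nm_1, nm_2, year1, year2), 1),
            f"neonatal_share_{year2}_pct": round(share_2, 1),
        }

    j1, j2 = u5mr_surface.year_index(year1), u5mr_surface.year_index(year2)
    nat_share = 100.0 * float(np.median(nat_nmr.draws[0, j2] / nat_u5.draws[0, j2]))
    rows.append(
        _row(
            "National",
            float(nat_u5.median()[0, j1]),
            float(nat_u5.median()[0, j2]),
            float(nat_nmr.median()[0, j1]),
            float(nat_nmr.median()[0, j2]),
            nat_share,
        )
    )
    for i, p in enumerate(u5mr_surface.provinces):
        rows.append(
            _row(
                p,
                float(u5_med[i, j1]),
                float(u5_med[i, j2]),
                float(nmr_med[i, j1]),
                float(nmr_med[i, j2]),
                float(share["median"][i, j2]),
            )
        )
    return pd.DataFrame(rows)
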