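"""Phenological overlap among sites from weekly adult-count surveys.

Overlap between two sites' seasonal activity is Pianka's symmetric niche
overlap on weekly abundance proportions,

    O = sum_w p_jw p_kw / sqrt(sum_w p_jw^2 * sum_w p_kw^2),

an ecological ceiling on between-site mating and hence gene-flow potential.
Season timing per site is summarized by the day of year on which the 15th
and 85th percentile adult was surveyed (first-crossing convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SURVEY_COLUMNS",
    "OverlapRecord",
    "pianka_overlap",
    "percentile_dates",
    "overlap_pipeline",
]

SURVEY_COLUMNS = (
    "site",
    "elevation_m",
    "species",
    "year",
    "week",
    "day_of_year",
    "adult_count",
)


@dataclass
class OverlapRecord:
    species: str
    year: int
    site_a: str
    site_b: str
    overlap: float
    elevation_separation_m: float


def pianka_overlap(p_j: np.ndarray, p_k: np.ndarray) -> float:
    """Pianka's symmetric overlap of two proportion vectors on one week grid."""
    p_j = np.asarray(p_j, dtype=float)
    p_k = np.asarray(p_k, dtype=float)
    if p_j.shape != p_k.shape:
        raise ValueError("proportion vectors must share the week grid")
    for p in (p_j, p_k):
        if p.sum() <= 0:
            raise ValueError("all-zero season; overlap undefined")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("proportions must sum to 1")
    num = float(np.sum(p_j * p_k))
    den = float(np.sqrt(np.sum(p_j**2) * np.sum(p_k**2)))
    return num / den


def percentile_dates(
    counts: np.ndarray, days: np.ndarray, qs=(0.15, 0.85)
) -> list[float]:
    """Day of year at which the cumulative adult proportion first reaches q."""
    counts = np.asarray(counts, dtype=float)
    days = np.asarray(days, dtype=float)
    order = np.argsort(days)
    counts, days = counts[order], days[order]
    total = counts.sum()
    if total < 1:
        raise ValueError("needs at least one surveyed adult")
    cum = np.cumsum(counts) / total
    out = []
    for q in qs:
        idx = int(np.searchsorted(cum, q))
        out.append(float(days[min(idx, len(days) - 1)]))
    return out


def _validate_survey(st: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVEY_COLUMNS if c not in st.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    if (st["adult_count"] < 0).any():
        raise ValueError("adult counts must be non-negative")
    return st


def overlap_pipeline(
    st: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score all site pairs per species-year and the percentile dates per site.

    Returns (overlaps, percentiles).  Overlap rows are sorted by elevational
    separation; weekly proportion vectors are aligned on the union of surveyed
    weeks, with zeros where one site recorded no adults that week.  Sites with
    zero seasonal total are skipped with a warning.
    """
    st = _validate_survey(st)
    overlap_rows = []
    percentile_rows = []
    for (species, year), grp in st.groupby(["species", "year"], sort=False):
        sites = grp.groupby("site", sort=False).agg(
            elevation_m=("elevation_m", "first"), total=("adult_count", "sum")
        )
        usable = []
        for site, row in sites.iterrows():
            sub = grp[grp["site"] == site]
            if row["total"] < 1:
                warnings.warn(
                    f"site {site!r} has zero adults for {species} {year}; skipped",
                    stacklevel=2,
                )
                continue
            p15, p85 = percentile_dates(
                sub["adult_count"].to_numpy(), sub["day_of_year"].to_numpy()
            )
            percentile_rows.append(
                {
                    "species": species,
                    "year": year,
                    "site": site,
                    "elevation_m": row["elevation_m"],
                    "doy_15": p15,
                    "doy_85": p85,
                }
            )
            usable.append(site)
        for a_i in range(len(usable)):
            for b_i in range(a_i + 1, len(usable)):
                a, b = usable[a_i], usable[b_i]
                sub_a = grp[grp["site"] == a].set_index("week")["adult_count"]
                sub_b = grp[grp["site"] == b].set_index("week")["adult_count"]
                weeks = sorted(set(sub_a.index) | set(sub_b.index))
                ca = sub_a.reindex(weeks, fill_value=0).to_numpy(dtype=float)
                cb = sub_b.reindex(weeks, fill_value=0).to_numpy(dtype=float)
                o = pianka_overlap(ca / ca.sum(), cb / cb.sum())
                overlap_rows.append(
                    {
                        "species": species,
                        "year": year,
                        "site_a": a,
                        "site_b": b,
                        "overlap": o,
                        "elevation_separation_m": abs(
                            sites.loc[a, "elevation_m"] - sites.loc[b, "elevation_m"]
                        ),
                    }
                )
    overlaps = pd.DataFrame(
        overlap_rows,
        columns=[
            "species",
            "year",
            "site_a",
            "site_b",
            "overlap",
            "elevation_separation_m",
        ],
    )
    if len(overlaps):
        overlaps = overlaps.sort_values(
            ["species", "year", "elevation_separation_m"]
        ).reset_index(drop=True)
    percentiles = pd.DataFrame(
        percentile_rows,
        columns=["species", "year", "site", "elevation_m", "doy_15", "doy_85"],
    )
    return overlaps, percentiles
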