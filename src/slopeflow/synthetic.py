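"""Synthetic inputs shaped like the elevational grasshopper study.

Provides the four species sampling layouts (deme elevations, diploid sample
sizes, SNP counts, candidate gene-flow model sets), the five-site environment
table (elevation, coordinates, mean annual temperature, growing-season
length), and generators for weekly adult-count surveys with an
elevation-shifted Gaussian season and for linear trait clines, so the whole
pipeline is exercisable without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesConfig",
    "SPECIES",
    "species_config",
    "site_table",
    "gen_survey_data",
    "gen_trait_clines",
]


@dataclass
class SpeciesConfig:
    name: str
    elevations: np.ndarray  # m a.s.l., increasing
    samples: np.ndarray  # diploids per deme
    n_snps: int
    models: tuple[str, ...]

    @property
    def n_demes(self) -> int:
        return len(self.elevations)


_SITES = pd.DataFrame(
    {
        "elevation_m": [1577.0, 2195.0, 2591.0, 3048.0, 3515.0],
        "lat": [40.061, 40.015, 40.023, 40.036, 40.059],
        "lon": [-105.193, -105.377, -105.430, -105.547, -105.617],
        "mean_annual_temp_c": [10.67, 7.93, 5.98, 1.79, -3.50],
        "season_length_d": [199.8, 164.5, 148.0, 100.5, 84.4],
    }
)

_SPECIES = {
    "A. clavatus": SpeciesConfig(
        name="A. clavatus",
        elevations=np.array([1577.0, 2195.0, 2591.0, 3515.0]),
        samples=np.array([22, 21, 22, 22]),
        n_snps=9454,
        models=("dn", "up", "ss", "am"),
    ),
    "M. boulderensis": SpeciesConfig(
        name="M. boulderensis",
        elevations=np.array([2195.0, 2591.0, 3048.0, 3515.0]),
        samples=np.array([21, 18, 8, 19]),
        n_snps=5501,
        models=("dn", "up", "ss", "am"),
    ),
    "M. sanguinipes": SpeciesConfig(
        name="M. sanguinipes",
        elevations=np.array([1577.0, 2195.0, 2591.0, 3048.0, 3515.0]),
        samples=np.array([22, 20, 21, 21, 12]),
        n_snps=4087,
        models=("dn", "up", "ss", "am", "sk"),
    ),
    "C. pellucida": SpeciesConfig(
        name="C. pellucida",
        elevations=np.array([2195.0, 2591.0, 3048.0]),
        samples=np.array([23, 21, 21]),
        n_snps=6815,
        models=("dn", "up", "ss", "am"),
    ),
}

SPECIES = tuple(_SPECIES)


def species_config(name: str) -> SpeciesConfig:
    """Sampling layout and candidate model set for one of the four species."""
    if name not in _SPECIES:
        raise ValueError(f"unknown species {name!r}; valid names: {list(_SPECIES)}")
    cfg = _SPECIES[name]
    return SpeciesConfig(
        name=cfg.name,
        elevations=cfg.elevations.copy(),
        samples=cfg.samples.copy(),
        n_snps=cfg.n_snps,
        models=cfg.models,
    )


def site_table() -> pd.DataFrame:
    """The five-site environment table (m a.s.l., dec. degrees, deg C, days)."""
    return _SITES.copy()


def gen_survey_data(
    site_elevations: np.ndarray,
    years=(2016,),
    delay_per_100m: float = 3.0,
    season_sd: float = 21.0,
    peak_abundance: float = 60.0,
    rng: np.random.Generator | None = None,
    species: str = "synthetic",
    base_peak_doy: float = 170.0,
    week_start_doy: int = 120,
    n_weeks: int = 26,
) -> pd.DataFrame:
    """Weekly adult counts with an elevation-shifted Gaussian season.

    Counts are Poisson draws around a Gaussian curve whose peak occurs
    ``delay_per_100m`` days later per 100 m of elevation above the lowest
    site.  Defaults emulate a montane mid-summer adult season (~3 d/100 m
    delay, 3-week spread) surveyed weekly from late April.
    """
    if season_sd <= 0:
        raise ValueError("season_sd must be positive")
    rng = rng or np.random.default_rng(0)
    site_elevations = np.asarray(site_elevations, dtype=float)
    e0 = site_elevations.min()
    rows = []
    for year in years:
        for elev in site_elevations:
            peak = base_peak_doy + delay_per_100m * (elev - e0) / 100.0
            for w in range(n_weeks):
                doy = week_start_doy + 7 * w
                lam = peak_abundance * np.exp(-0.5 * ((doy - peak) / season_sd) ** 2)
                rows.append(
                    {
                        "site": f"S{int(elev)}",
                        "elevation_m": elev,
                        "species": species,
                        "year": int(year),
                        "week": w,
                        "day_of_year": doy,
                        "adult_count": int(rng.poisson(lam)),
                    }
                )
    return pd.DataFrame(rows)


def gen_trait_clines(
    populations: pd.DataFrame,
    slopes: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    intercepts: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Population trait means linear in elevation plus Gaussian noise.

    ``populations`` needs columns population and elevation_m; ``slopes`` maps
    trait name -> change per km of elevation.  Defaults emulate the study's
    trait set: body size and thermal limits declining with elevation,
    reproductive investment per egg increasing.
    """
    rng = rng or np.random.default_rng(0)
    if slopes is None:
        slopes = {
            "body_mass": -0.08,
            "femur_length": -0.9,
            "clutch_size": -1.2,
            "ovariole_number": -0.8,
            "egg_mass": 0.4,
            "clutch_weight": -0.5,
            "preferred_body_temp": -1.0,
            "ct_min": -0.8,
            "ct_max": -0.6,
        }
    base = {
        "body_mass": 0.5,
        "femur_length": 11.0,
        "clutch_size": 14.0,
        "ovariole_number": 20.0,
        "egg_mass": 3.0,
        "clutch_weight": 40.0,
        "preferred_body_temp": 38.0,
        "ct_min": 6.0,
        "ct_max": 47.0,
    }
    if intercepts:
        base.update(intercepts)
    out = {}
    elev_km = populations["elevation_m"].to_numpy(dtype=float) / 1000.0
    for trait, slope in slopes.items():
        mu = base.get(trait, 0.0) + slope * elev_km
        out[trait] = mu + rng.normal(0.0, noise_sd, size=len(elev_km))
    return pd.DataFrame(out, index=populations["population"].tolist())
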