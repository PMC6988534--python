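"""Distance matrices over populations and Mantel permutation tests.

Predictor matrices: geographic (Euclidean km on locally projected
coordinates), elevational (absolute difference in metres), environmental
(Euclidean on z-scored mean annual temperature and growing-season length) and
genetic (linearized pairwise F_ST).  Response matrices are Euclidean
distances on z-scored trait-category means.  Association is tested with the
Mantel permutation test: Pearson correlation of the lower-triangle vectors,
one-sided upper p-value over joint row+column permutations of the second
matrix, with the +1 correction so p is never 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import PopulationMap

__all__ = [
    "DISTANCE_KINDS",
    "MantelResult",
    "build_distances",
    "mantel_test",
    "trait_association_suite",
]

DISTANCE_KINDS = ("geography", "elevation", "environment", "genetic")

TRAIT_CATEGORIES = {
    "growth": ("body_mass", "femur_length"),
    "reproductive": ("clutch_size", "ovariole_number", "egg_mass", "clutch_weight"),
    "physiological": ("preferred_body_temp", "ct_min", "ct_max"),
}


from dataclasses import dataclass


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _euclidean(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def build_distances(
    pm: PopulationMap,
    kind: str,
    env: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    trait_category: str | None = None,
    genetic: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Square distance matrix over populations (ordered low -> high elevation).

    ``env`` is a site table with elevation_m, mean_annual_temp_c and
    season_length_d; ``traits`` a population x trait table; ``genetic`` a
    linearized pairwise F_ST matrix passed through unchanged.
    """
    pops = pm.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    if kind == "geography":
        coords = pm.coordinates().loc[pops]
        lat = coords["lat"].to_numpy()
        lon = coords["lon"].to_numpy()
        # local equirectangular projection, km
        lat0 = np.deg2rad(lat.mean())
        x = np.deg2rad(lon) * 6371.0 * np.cos(lat0)
        y = np.deg2rad(lat) * 6371.0
        mat = _euclidean(np.column_stack([x, y]))
    elif kind == "elevation":
        elev = pm.elevations().loc[pops].to_numpy(dtype=float)
        mat = np.abs(elev[:, None] - elev[None, :])
    elif kind == "environment":
        if env is None:
            raise ValueError("environment distance needs the site table")
        elev = pm.elevations().loc[pops]
        site = env.set_index("elevation_m")
        vals = site.loc[elev, ["mean_annual_temp_c", "season_length_d"]].to_numpy(
            dtype=float
        )
        mat = _euclidean(_zscore(vals))
    elif kind == "genetic":
        if genetic is None:
            raise ValueError("genetic distance needs a linearized F_ST matrix")
        return genetic.loc[pops, pops].copy()
    elif kind and kind.startswith("phenotype"):
        if traits is None or trait_category is None:
            raise ValueError("phenotype distance needs traits and a category")
        cols = [
            c for c in TRAIT_CATEGORIES[trait_category] if c in traits.columns
        ]
        sub = traits.loc[pops, cols].astype(float)
        if sub.isna().any().any():
            raise ValueError(f"missing trait values for category {trait_category!r}")
        mat = _euclidean(_zscore(sub.to_numpy()))
    else:
        raise ValueError(f"unknown distance kind {kind!r}")
    return pd.DataFrame(mat, index=pops, columns=pops)


def _tri(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices."""
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs >=3 populations")
    va, vb = _tri(a), _tri(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = rng or np.random.default_rng(0)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    i, j = np.tril_indices(n, k=-1)
    vp = b[perms[:, i], perms[:, j]]  # (n_perm, n_pairs)
    va_c = (va - va.mean()) / va.std()
    vp_c = (vp - vp.mean(axis=1, keepdims=True)) / vp.std(axis=1, keepdims=True)
    r_perm = (vp_c * va_c).mean(axis=1)
    p = (1.0 + int(np.sum(r_perm >= r_obs))) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm)


def trait_association_suite(
    traits: pd.DataFrame,
    predictors: dict[str, pd.DataFrame],
    pm: PopulationMap,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mantel (r, p) per trait category x predictor.

    Categories with complete data for fewer than 3 populations are emitted as
    N/A rows (NaN r and p).
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for category, variables in TRAIT_CATEGORIES.items():
        cols = [c for c in variables if c in traits.columns]
        complete = traits[cols].dropna() if cols else traits.iloc[0:0]
        testable = len(cols) > 0 and len(complete) >= 3
        for pred_name, pred in predictors.items():
            if not testable:
                rows.append(
                    {
                        "category": category,
                        "predictor": pred_name,
                        "r": np.nan,
                        "p_value": np.nan,
                        "n_populations": len(complete),
                    }
                )
                continue
            pops = [p for p in pred.index if p in complete.index]
            sub_pm = PopulationMap(
                pm.table[pm.table["population"].isin(pops)].reset_index(drop=True)
            )
            pheno = build_distances(
                sub_pm, f"phenotype:{category}", traits=complete,
                trait_category=category,
            )
            res = mantel_test(
                pheno, pred.loc[pheno.index, pheno.index], n_perm=n_perm, rng=rng
            )
            rows.append(
                {
                    "category": category,
                    "predictor": pred_name,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n_populations": len(pheno),
                }
            )
    return pd.DataFrame(rows)
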