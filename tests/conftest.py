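import numpy as np
import pandas as pd
import pytest

from slopeflow.genotype_io import MISSING, GenotypeMatrix, PopulationMap


def make_popmap(pop_sizes: dict[str, int], elevations=None) -> PopulationMap:
    """Population map for synthetic sample ids pop_i; elevations increasing."""
    rows = []
    elev = 1000.0
    for pop, n in pop_sizes.items():
        e = elevations[pop] if elevations else elev
        for i in range(n):
            rows.append(
                {
                    "sample": f"{pop}_{i}",
                    "population": pop,
                    "elevation_m": e,
                    "lat": 40.0 + e / 1e5,
                    "lon": -105.0 - e / 1e5,
                }
            )
        elev += 500.0
    return PopulationMap(pd.DataFrame(rows))


def make_matrix(pop_sizes: dict[str, int], calls: np.ndarray) -> tuple[GenotypeMatrix, PopulationMap]:
    pm = make_popmap(pop_sizes)
    n_samples, n_loci = calls.shape
    g = GenotypeMatrix(
        sample_ids=list(pm.table["sample"]),
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=np.asarray(calls, dtype=np.int8),
    )
    return g, pm


def random_matrix(
    rng: np.random.Generator,
    pop_sizes: dict[str, int],
    n_loci: int,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, PopulationMap]:
    n = sum(pop_sizes.values())
    p = rng.uniform(0.05, 0.95, size=n_loci)
    calls = rng.binomial(2, p[None, :], size=(n, n_loci)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, n_loci)) < missing_rate
        calls[mask] = MISSING
    return make_matrix(pop_sizes, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
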