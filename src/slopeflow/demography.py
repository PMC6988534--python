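"""Spatial gene-flow models and the structured-coalescent SNP simulator.

Five migration topologies over demes ordered low -> high elevation:

``dn``
    unidirectional gene flow downslope (each deme sends migrants to its
    adjacent lower neighbour),
``up``
    unidirectional gene flow upslope,
``ss``
    bidirectional stepping stone (both adjacent neighbours),
``am``
    island model (equal gene flow among all demes),
``sk``
    source-sink: the island model plus an extra unidirectional rate from
    every other deme into the top deme, emulating an "accidental" summit
    population maintained by lowland sources.

The scalar gene-flow rate ``m`` is a per donor->recipient edge proportion of
individuals per generation.  Forward-time topologies are converted to
backward-time lineage movement by edge reversal: a lineage sampled in the
recipient deme jumps to the donor deme at the forward rate.

Datasets are sets of SNPs collected from a constant-intensity Poisson
mutation process streamed across independent genealogies, so each site is
polymorphic in the pooled sample and site frequencies follow the neutral
ascertained-SNP distribution (class probability proportional to expected
subtending branch length); sites that share a genealogy are mildly linked,
like SNPs on one short simulated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._coalescent import simulate_counts
from .genotype_io import GenotypeMatrix, PopulationMap
from .popgen_stats import nei_chesser_components

MODEL_LABELS = ("dn", "up", "ss", "am", "sk")

__all__ = [
    "MODEL_LABELS",
    "DemographicModel",
    "PriorSpec",
    "build_migration_matrix",
    "sample_prior",
    "simulate_counts_dataset",
    "simulate_dataset",
    "sumstat_names",
    "sumstats_from_counts",
    "dataset_sumstats",
    "popmap_for",
]


def _forward_topology(label: str, d: int) -> np.ndarray:
    """0/1 forward gene-flow adjacency (row donor, column recipient); the sk
    extra inflow edges carry weight so one matrix entry may be 2."""
    F = np.zeros((d, d))
    if label == "dn":
        for i in range(1, d):
            F[i, i - 1] = 1.0
    elif label == "up":
        for i in range(d - 1):
            F[i, i + 1] = 1.0
    elif label == "ss":
        for i in range(d - 1):
            F[i, i + 1] = 1.0
            F[i + 1, i] = 1.0
    elif label == "am":
        F[:] = 1.0
        np.fill_diagonal(F, 0.0)
    elif label == "sk":
        if d < 3:
            raise ValueError("source-sink model needs >=3 demes")
        F[:] = 1.0
        np.fill_diagonal(F, 0.0)
        F[:-1, -1] += 1.0  # extra unidirectional inflow to the top deme
    else:
        raise ValueError(f"unknown model label {label!r}; valid: {MODEL_LABELS}")
    return F


def build_migration_matrix(label: str, d: int, m: float) -> np.ndarray:
    """Backward-time per-lineage migration rate matrix for a model label.

    Entry [i, j] is the rate at which a lineage currently in deme i jumps to
    deme j, obtained by reversing the forward gene-flow edges.
    """
    if d < 2:
        raise ValueError("need at least 2 demes")
    if m <= 0:
        raise ValueError("migration rate must be positive")
    F = _forward_topology(label, d) * m
    return F.T.copy()


def _has_common_ancestral_deme(M: np.ndarray) -> bool:
    """True when some deme is reachable (backward) from every deme, so all
    lineages can meet."""
    d = M.shape[0]
    reach = (M > 0) | np.eye(d, dtype=bool)
    for _ in range(d):
        reach = reach | (reach @ reach)
    return bool(np.any(reach.all(axis=0)))


@dataclass
class DemographicModel:
    """A migration topology with per-deme effective sizes.

    demes are ordered low -> high elevation; ``elevations`` (m a.s.l.) are
    optional labels used when exporting population maps.
    """

    label: str
    Ne: np.ndarray
    m: float
    elevations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Ne = np.asarray(self.Ne, dtype=float)
        if self.label not in MODEL_LABELS:
            raise ValueError(f"unknown model label {self.label!r}")
        if np.any(self.Ne <= 0):
            raise ValueError("effective sizes must be positive")
        if self.elevations is not None:
            self.elevations = np.asarray(self.elevations, dtype=float)
            if len(self.elevations) != self.n_demes:
                raise ValueError("one elevation per deme required")
            if np.any(np.diff(self.elevations) <= 0):
                raise ValueError("deme elevations must be strictly increasing")

    @property
    def n_demes(self) -> int:
        return len(self.Ne)

    @property
    def migration_matrix(self) -> np.ndarray:
        M = build_migration_matrix(self.label, self.n_demes, self.m)
        if not _has_common_ancestral_deme(M):
            raise ValueError("deme structure admits no common ancestral deme")
        return M


@dataclass
class PriorSpec:
    """Uniform prior on m; independent log-uniform priors on per-deme N_e."""

    m_bounds: tuple[float, float] = (0.001, 0.05)
    ne_bounds: tuple[float, float] = (200.0, 10_000.0)

    def __post_init__(self) -> None:
        if not (0 < self.m_bounds[0] < self.m_bounds[1]):
            raise ValueError("m bounds must be positive and ordered")
        if not (0 < self.ne_bounds[0] < self.ne_bounds[1]):
            raise ValueError("N_e bounds must be positive and ordered")


def sample_prior(
    prior: PriorSpec, d: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Draw (m, N_e vector): m ~ U(m_bounds); N_e[i] iid log-uniform(ne_bounds)."""
    m = rng.uniform(*prior.m_bounds)
    lo, hi = np.log(prior.ne_bounds[0]), np.log(prior.ne_bounds[1])
    Ne = np.exp(rng.uniform(lo, hi, size=d))
    return float(m), Ne


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_counts_dataset(
    model: DemographicModel,
    samples: np.ndarray,
    n_snps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: per-locus derived-allele and heterozygote counts per deme.

    ``samples`` are per-deme diploid counts.  Returns (counts, het), each of
    shape (n_snps, d); counts are out of 2*samples haploid genomes.
    """
    samples = np.asarray(samples, dtype=np.int64)
    if len(samples) != model.n_demes:
        raise ValueError("one diploid sample size per deme required")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    M = model.migration_matrix
    return simulate_counts(_kernel_seed(rng), n_snps, 2 * samples, model.Ne, M)


def popmap_for(
    model: DemographicModel, samples: np.ndarray, site_table=None
) -> PopulationMap:
    """Population map for simulated samples (labels pop1..popd, low -> high)."""
    import pandas as pd

    d = model.n_demes
    elev = (
        model.elevations
        if model.elevations is not None
        else 1000.0 + 500.0 * np.arange(d)
    )
    coords = {}
    if site_table is not None:
        for _, row in site_table.iterrows():
            coords[float(row["elevation_m"])] = (row["lat"], row["lon"])
    rows = []
    for k in range(d):
        lat, lon = coords.get(float(elev[k]), (40.0 + 0.01 * k, -105.0 - 0.05 * k))
        for i in range(int(samples[k])):
            rows.append(
                {
                    "sample": f"pop{k + 1}_{i + 1}",
                    "population": f"pop{k + 1}",
                    "elevation_m": float(elev[k]),
                    "lat": lat,
                    "lon": lon,
                }
            )
    return PopulationMap(pd.DataFrame(rows))


def simulate_dataset(
    model: DemographicModel,
    samples: np.ndarray,
    n_snps: int,
    rng: np.random.Generator,
    site_table=None,
) -> tuple[GenotypeMatrix, np.ndarray, PopulationMap]:
    """Simulate a genotype dataset; returns (genotypes, haplotypes, popmap).

    Haplotypes (2*sum(samples), n_snps) hold 0/1 alleles; consecutive pairs
    within a deme form the diploid samples (random pairing).
    """
    samples = np.asarray(samples, dtype=np.int64)
    counts, _ = simulate_counts_dataset(model, samples, n_snps, rng)
    nhap = 2 * samples
    total_hap = int(nhap.sum())
    hap = np.zeros((total_hap, n_snps), dtype=np.int8)
    offsets = np.concatenate([[0], np.cumsum(nhap)])
    for k in range(model.n_demes):
        o = offsets[k]
        for j in range(n_snps):
            c = counts[j, k]
            if c:
                idx = rng.choice(nhap[k], size=c, replace=False)
                hap[o + idx, j] = 1
    calls = (hap[0::2, :] + hap[1::2, :]).astype(np.int8)
    pm = popmap_for(model, samples, site_table=site_table)
    g = GenotypeMatrix(
        sample_ids=list(pm.table["sample"]),
        locus_ids=[f"snp{j + 1}" for j in range(n_snps)],
        calls=calls,
        chrom=["1"] * n_snps,
        pos=np.arange(1, n_snps + 1, dtype=np.int64) * 1000,
    )
    return g, hap, pm


def sumstat_names(d: int) -> list[str]:
    """Fixed ordering of the summary-statistic vector for d demes."""
    names = ["H_total", "S_total"]
    names += [f"S_pop{k + 1}" for k in range(d)]
    pairs = [(a, b) for a in range(d) for b in range(a + 1, d)]
    names += [f"pi_{a + 1}_{b + 1}" for a, b in pairs]
    names += [f"fst_{a + 1}_{b + 1}" for a, b in pairs]
    return names


def sumstats_from_counts(
    counts: np.ndarray, het: np.ndarray, samples: np.ndarray
) -> np.ndarray:
    """Summary-statistic vector from per-deme derived/het counts.

    Components: mean total gene diversity H_T over loci; segregating sites
    overall and per deme; mean pairwise sequence differences between each deme
    pair (summed over loci); pairwise Nei F_ST per deme pair.
    """
    samples = np.asarray(samples, dtype=float)
    nhap = 2.0 * samples
    d = len(samples)
    p = counts / nhap
    ho = het / samples
    total = counts.sum(axis=1)
    tot_hap = nhap.sum()

    _, _, Ht = nei_chesser_components(p, ho, samples)
    stats = [float(Ht.mean()), float(np.sum((total > 0) & (total < tot_hap)))]
    stats += [float(np.sum((counts[:, k] > 0) & (counts[:, k] < nhap[k]))) for k in range(d)]
    pairs = [(a, b) for a in range(d) for b in range(a + 1, d)]
    for a, b in pairs:
        ca, cb = counts[:, a], counts[:, b]
        diff = (ca * (nhap[b] - cb) + cb * (nhap[a] - ca)) / (nhap[a] * nhap[b])
        stats.append(float(diff.sum()))
    for a, b in pairs:
        cols = [a, b]
        _, Hs, Ht2 = nei_chesser_components(p[:, cols], ho[:, cols], samples[cols])
        hs, ht = Hs.mean(), Ht2.mean()
        stats.append(float((ht - hs) / ht) if ht > 0 else 0.0)
    return np.asarray(stats)


def dataset_sumstats(g: GenotypeMatrix, pm: PopulationMap) -> np.ndarray:
    """Summary-statistic vector for a genotype dataset (fixed deme ordering by
    elevation); equals :func:`sumstats_from_counts` on the dataset's counts."""
    groups = pm.indices_by_population(g.sample_ids)
    d = len(groups)
    counts = np.zeros((g.n_loci, d), dtype=np.int64)
    het = np.zeros((g.n_loci, d), dtype=np.int64)
    samples = np.zeros(d, dtype=np.int64)
    for k, pop in enumerate(groups):
        block = g.calls[groups[pop], :]
        if (block < 0).any():
            raise ValueError("summary statistics require a complete matrix")
        counts[:, k] = block.sum(axis=0)
        het[:, k] = (block == 1).sum(axis=0)
        samples[k] = block.shape[0]
    return sumstats_from_counts(counts, het, samples)
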