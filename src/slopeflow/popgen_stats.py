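"""Diversity and differentiation statistics for biallelic SNPs.

Implements the Nei & Chesser (1983) unbiased estimators of within-population
gene diversity (H_S) and total gene diversity (H_T) for r populations of
diploids, and the derived fixation indices F_IS, F_ST, and Jost's D_est.
Multi-locus values follow the ratio-of-averages convention: per-locus
components are averaged across loci first and the ratios formed afterwards.

Per locus, with r populations, per-population alternate-allele frequencies
p_k, observed heterozygosities h_k, and harmonic-mean sample size n~ of the
per-population diploid counts n_k:

    H_O = (1/r) sum_k h_k
    H_S = (n~/(n~-1)) * [1 - (1/r) sum_k (p_k^2 + q_k^2) - H_O/(2 n~)]
    H_T = 1 - (pbar^2 + qbar^2) + H_S/(r n~) - H_O/(2 r n~)

with pbar the unweighted mean of the p_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "LocusStats",
    "OverallStats",
    "PairwiseFst",
    "nei_chesser_components",
    "locus_stats",
    "overall_stats",
    "pairwise_fst",
    "pairwise_fst_from_freqs",
    "linearize_fst",
]


def nei_chesser_components(
    p: np.ndarray, ho: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (H_O, H_S, H_T) from frequency/heterozygosity/sample arrays.

    Parameters
    ----------
    p : (L, r) alternate-allele frequency per locus and population.
    ho : (L, r) observed heterozygote proportion per locus and population.
    n : (L, r) or (r,) genotyped diploid count per locus and population.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    ho = np.atleast_2d(np.asarray(ho, dtype=float))
    n = np.asarray(n, dtype=float)
    if n.ndim == 1:
        n = np.broadcast_to(n, p.shape)
    if np.any(n < 1):
        raise ValueError("every population needs >=1 genotyped diploid per locus")
    r = p.shape[1]
    ntilde = r / np.sum(1.0 / n, axis=1)  # harmonic mean sample size
    Ho = ho.mean(axis=1)
    msp2 = np.mean(p * p + (1.0 - p) * (1.0 - p), axis=1)
    Hs = (ntilde / (ntilde - 1.0)) * (1.0 - msp2 - Ho / (2.0 * ntilde))
    pbar = p.mean(axis=1)
    Ht = (
        1.0
        - (pbar * pbar + (1.0 - pbar) * (1.0 - pbar))
        + Hs / (r * ntilde)
        - Ho / (2.0 * r * ntilde)
    )
    return Ho, Hs, Ht


@dataclass
class LocusStats:
    """Per-locus components and per-population quantities."""

    locus_ids: list[str]
    populations: list[str]
    n: np.ndarray  # (L, r) genotyped diploids
    p: np.ndarray  # (L, r) alternate-allele frequency
    h_o: np.ndarray  # (L, r) observed heterozygosity
    h_e: np.ndarray  # (L, r) plain expected heterozygosity 2 p q
    maf: np.ndarray  # (L,) pooled minor-allele frequency
    H_O: np.ndarray  # (L,) mean observed heterozygosity over populations
    H_S: np.ndarray  # (L,) Nei-Chesser within-population gene diversity
    H_T: np.ndarray  # (L,) Nei-Chesser total gene diversity


@dataclass
class OverallStats:
    """Loci-averaged components and the derived multilocus indices."""

    populations: list[str]
    H_O: float
    H_S: float
    H_T: float
    F_IS: float
    F_ST: float | None
    D_est: float | None
    per_population: pd.DataFrame  # rows: population; columns H_O, H_E, H_S, F_IS

    def to_frame(self) -> pd.DataFrame:
        """Species-level + per-population rows, one table."""
        species = pd.DataFrame(
            {
                "H_O": [self.H_O],
                "H_E": [np.nan],
                "H_S": [self.H_S],
                "F_IS": [self.F_IS],
                "F_ST": [self.F_ST],
                "H_T": [self.H_T],
                "D_est": [self.D_est],
            },
            index=["overall"],
        )
        return pd.concat([species, self.per_population], axis=0)


@dataclass
class PairwiseFst:
    populations: list[str]
    fst: pd.DataFrame

    def linearized(self) -> pd.DataFrame:
        values = linearize_fst(self.fst.to_numpy())
        return pd.DataFrame(values, index=self.fst.index, columns=self.fst.columns)


def _per_population_arrays(
    g: GenotypeMatrix, pm: PopulationMap
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    groups = pm.indices_by_population(g.sample_ids)
    pops = list(groups)
    L = g.n_loci
    r = len(pops)
    n = np.zeros((L, r))
    p = np.zeros((L, r))
    ho = np.zeros((L, r))
    for k, pop in enumerate(pops):
        block = g.calls[groups[pop], :]
        obs = block != MISSING
        nk = obs.sum(axis=0)
        if np.any(nk == 0):
            j = int(np.flatnonzero(nk == 0)[0])
            raise ValueError(
                f"population {pop!r} has no genotyped sample at locus "
                f"{g.locus_ids[j]!r}"
            )
        alt = np.where(obs, block, 0).sum(axis=0)
        het = ((block == 1) & obs).sum(axis=0)
        n[:, k] = nk
        p[:, k] = alt / (2.0 * nk)
        ho[:, k] = het / nk
    return pops, n, p, ho


def locus_stats(g: GenotypeMatrix, pm: PopulationMap) -> LocusStats:
    """Per-SNP MAF, per-population frequencies/heterozygosities and the
    Nei-Chesser H_O / H_S / H_T components."""
    pops, n, p, ho = _per_population_arrays(g, pm)
    Ho, Hs, Ht = nei_chesser_components(p, ho, n)
    # MAF is pooled over all genotyped samples, not averaged per population
    alt = (p * 2.0 * n).sum(axis=1)
    tot = (2.0 * n).sum(axis=1)
    pooled = alt / tot
    maf = np.minimum(pooled, 1.0 - pooled)
    return LocusStats(
        locus_ids=list(g.locus_ids),
        populations=pops,
        n=n,
        p=p,
        h_o=ho,
        h_e=2.0 * p * (1.0 - p),
        maf=maf,
        H_O=Ho,
        H_S=Hs,
        H_T=Ht,
    )


def overall_stats(ls: LocusStats) -> OverallStats:
    """Average per-locus components across loci, then form the ratios."""
    r = len(ls.populations)
    Ho = float(ls.H_O.mean())
    Hs = float(ls.H_S.mean())
    Ht = float(ls.H_T.mean())
    Fis = 1.0 - Ho / Hs if Hs > 0 else float("nan")
    if r >= 2:
        Fst = (Ht - Hs) / Ht if Ht > 0 else float("nan")
        Dest = (r / (r - 1.0)) * (Ht - Hs) / (1.0 - Hs) if Hs < 1 else float("nan")
    else:
        Fst = None
        Dest = None
    # per-population means: plain 2pq, observed het, and the single-population
    # unbiased gene diversity n/(n-1) (2pq - ho/(2n))
    hs_k = (ls.n / (ls.n - 1.0)) * (ls.h_e - ls.h_o / (2.0 * ls.n)) if np.all(
        ls.n > 1
    ) else np.full_like(ls.h_e, np.nan)
    per_pop = pd.DataFrame(
        {
            "H_O": ls.h_o.mean(axis=0),
            "H_E": ls.h_e.mean(axis=0),
            "H_S": hs_k.mean(axis=0),
        },
        index=ls.populations,
    )
    per_pop["F_IS"] = 1.0 - per_pop["H_O"] / per_pop["H_S"]
    return OverallStats(
        populations=list(ls.populations),
        H_O=Ho,
        H_S=Hs,
        H_T=Ht,
        F_IS=Fis,
        F_ST=Fst,
        D_est=Dest,
        per_population=per_pop,
    )


def pairwise_fst_from_freqs(
    p: np.ndarray, ho: np.ndarray, n: np.ndarray, populations: list[str]
) -> pd.DataFrame:
    """Pairwise Nei F_ST (ratio-of-averages, r=2) from per-population arrays."""
    r = len(populations)
    n = np.broadcast_to(np.asarray(n, dtype=float), p.shape)
    out = np.zeros((r, r))
    for a in range(r):
        for b in range(a + 1, r):
            cols = [a, b]
            Ho, Hs, Ht = nei_chesser_components(p[:, cols], ho[:, cols], n[:, cols])
            hs, ht = Hs.mean(), Ht.mean()
            out[a, b] = out[b, a] = (ht - hs) / ht if ht > 0 else 0.0
    return pd.DataFrame(out, index=populations, columns=populations)


def pairwise_fst(g: GenotypeMatrix, pm: PopulationMap) -> PairwiseFst:
    """Population-pair F_ST matrix; each pair's components are recomputed on
    the two-population restriction."""
    pops, n, p, ho = _per_population_arrays(g, pm)
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs >=2 populations")
    return PairwiseFst(populations=pops, fst=pairwise_fst_from_freqs(p, ho, n, pops))


def linearize_fst(f):
    """Latter's linearization f / (1 - f), elementwise; rejects f >= 1."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr >= 1.0):
        raise ValueError("linearized F_ST undefined for F_ST >= 1")
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(f) or arr.ndim == 0 else out
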