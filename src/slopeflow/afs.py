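"""Minor-allele site-frequency spectra and composite-likelihood fitting.

Per population of n_k diploids, each locus contributes to the folded class
equal to its minor-allele copy number in that population (0 .. n_k, folding
2 n_k haploid copies at n_k); class 0 holds loci monomorphic within the
population.  The expected spectrum under a demographic model is estimated by
Monte Carlo from the coalescent simulator with add-one smoothing, and the
composite log-likelihood treats loci and populations as independent:

    ll = sum_pops sum_classes  obs_count * log(expected_proportion)

Maximization is a cyclic coordinate search on (log m, log N_e) with common
random numbers (a fixed simulation seed per restart), which makes the
Monte-Carlo likelihood surface deterministic for the optimizer.

A structural caveat: the conditioned-SNP spectrum is exactly invariant under
(N_e, m) -> (c N_e, m / c) — only time units change — so the composite
likelihood has a ridge along N_e * m = const and absolute N_e is only
identified jointly with m (or with m known).  Tools that fit the AFS of
sequence data anchor absolute N_e through the mutation rate; this module's
ascertained-SNP likelihood deliberately has no mutation-rate parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel, simulate_counts_dataset
from .genotype_io import GenotypeMatrix, PopulationMap

__all__ = [
    "JointAFS",
    "AfsFit",
    "minor_afs",
    "afs_from_counts",
    "expected_afs",
    "composite_ll",
    "fit_afs",
    "parametric_bootstrap",
]


@dataclass
class JointAFS:
    """Folded per-population spectra (optionally joint pairwise)."""

    populations: list[str]
    sfs: dict[str, np.ndarray]  # pop -> counts over classes 0..n_k
    n_loci: int
    joint: dict[tuple[str, str], np.ndarray] | None = None

    def polymorphic_total(self, pop: str) -> int:
        return int(self.sfs[pop][1:].sum())


def afs_from_counts(
    counts: np.ndarray,
    samples: np.ndarray,
    populations: list[str] | None = None,
    joint: bool = False,
) -> JointAFS:
    """Folded spectra from per-deme derived-allele counts (loci x demes)."""
    samples = np.asarray(samples, dtype=int)
    d = len(samples)
    populations = populations or [f"pop{k + 1}" for k in range(d)]
    sfs = {}
    folded_all = {}
    for k, pop in enumerate(populations):
        nh = 2 * samples[k]
        folded = np.minimum(counts[:, k], nh - counts[:, k])
        folded_all[k] = folded
        sfs[pop] = np.bincount(folded, minlength=samples[k] + 1).astype(np.int64)
    out = JointAFS(populations=populations, sfs=sfs, n_loci=counts.shape[0])
    if joint:
        out.joint = {}
        for a in range(d):
            for b in range(a + 1, d):
                grid = np.zeros((samples[a] + 1, samples[b] + 1), dtype=np.int64)
                np.add.at(grid, (folded_all[a], folded_all[b]), 1)
                out.joint[(populations[a], populations[b])] = grid
    return out


def minor_afs(g: GenotypeMatrix, pm: PopulationMap, joint: bool = False) -> JointAFS:
    """Folded minor-allele SFS per population (and per pair when ``joint``)."""
    if g.has_missing():
        raise ValueError("minor_afs requires a complete (missing-free) matrix")
    groups = pm.indices_by_population(g.sample_ids)
    pops = list(groups)
    samples = np.array([len(groups[p]) for p in pops])
    counts = np.zeros((g.n_loci, len(pops)), dtype=np.int64)
    for k, pop in enumerate(pops):
        counts[:, k] = g.calls[groups[pop], :].sum(axis=0)
    return afs_from_counts(counts, samples, pops, joint=joint)


def expected_afs(
    model: DemographicModel,
    samples: np.ndarray,
    n_sim_loci: int,
    rng: np.random.Generator,
    populations: list[str] | None = None,
    joint: bool = False,
) -> dict:
    """Monte-Carlo expected folded class proportions with add-one smoothing.

    With ``joint=True`` the dictionary is keyed by population pairs and holds
    normalized 2-D joint folded grids, which retain the between-population
    allele-frequency covariance that the marginal spectra integrate out.
    """
    counts, _ = simulate_counts_dataset(model, samples, n_sim_loci, rng)
    sim = afs_from_counts(counts, samples, populations, joint=joint)
    out = {}
    if joint:
        for pair, grid in sim.joint.items():
            smoothed = grid.astype(float) + 1.0
            out[pair] = smoothed / smoothed.sum()
        return out
    for pop, c in sim.sfs.items():
        smoothed = c.astype(float) + 1.0
        out[pop] = smoothed / smoothed.sum()
    return out


def composite_ll(obs: JointAFS, expected: dict) -> float:
    """Sum over classes of obs_count * log(expected_prop).

    ``expected`` keyed by population names uses the per-population marginal
    spectra; keyed by population pairs it uses the 2-D joint folded grids
    (``obs.joint`` must be present).
    """
    keys = list(expected)
    pairwise = bool(keys) and isinstance(keys[0], tuple)
    if pairwise and obs.joint is None:
        raise ValueError("pairwise expected spectra require obs.joint grids")
    ll = 0.0
    for key in (keys if pairwise else obs.populations):
        o = (obs.joint[key] if pairwise else obs.sfs[key]).astype(float)
        e = expected[key]
        if o.shape != e.shape:
            raise ValueError(f"class support mismatch for {key!r}")
        if np.any((e <= 0) & (o > 0)):
            raise ValueError("zero expected proportion with positive observed count")
        mask = o > 0
        ll += float(np.sum(o[mask] * np.log(e[mask])))
    return ll


@dataclass
class AfsFit:
    m: float
    Ne: np.ndarray
    log_likelihood: float
    restarts: int
    converged: bool
    shared_ne: bool
    bootstrap: dict[str, tuple[float, float]] | None = None


def _fit_params_to_model(
    label: str, theta: np.ndarray, d: int, shared_ne: bool
) -> DemographicModel:
    m = theta[0]
    Ne = np.full(d, theta[1]) if shared_ne else theta[1:].copy()
    return DemographicModel(label, Ne=Ne, m=m)


def fit_afs(
    obs: JointAFS,
    label: str,
    samples: np.ndarray,
    m_bounds: tuple[float, float] = (0.001, 0.05),
    ne_bounds: tuple[float, float] = (200.0, 10_000.0),
    restarts: int = 5,
    n_sim_loci: int = 2000,
    shared_ne: bool = True,
    joint: bool = False,
    rel_tol: float = 0.001,
    max_cycles: int = 10,
    rng: np.random.Generator | None = None,
) -> AfsFit:
    """Maximize the composite likelihood by cyclic coordinate search.

    All parameters are searched on the log scale within the prior bounds;
    passing equal lower and upper bounds freezes that coordinate (e.g.
    ``m_bounds=(m0, m0)`` fits N_e conditional on a known migration rate —
    see the module caveat on the N_e * m ridge).  Each restart draws a random
    start and fixes the simulation seed for every likelihood evaluation
    (common random numbers), and the cycle stops once the relative parameter
    change falls below ``rel_tol``.
    """
    rng = rng or np.random.default_rng(0)
    samples = np.asarray(samples, dtype=np.int64)
    d = len(samples)
    n_par = 2 if shared_ne else 1 + d
    lo = np.log(np.array([m_bounds[0]] + [ne_bounds[0]] * (n_par - 1)))
    hi = np.log(np.array([m_bounds[1]] + [ne_bounds[1]] * (n_par - 1)))
    free = hi > lo

    best_theta, best_ll = None, -np.inf
    improved = False
    for _ in range(max(1, restarts)):
        eval_seed = int(rng.integers(1, 2**31 - 1))

        def ll_at(log_theta):
            model = _fit_params_to_model(label, np.exp(log_theta), d, shared_ne)
            exp = expected_afs(
                model, samples, n_sim_loci, np.random.default_rng(eval_seed),
                populations=obs.populations, joint=joint,
            )
            return composite_ll(obs, exp)

        theta = rng.uniform(lo, hi)
        cur = ll_at(theta)
        start_ll = cur
        for _cycle in range(max_cycles):
            prev = theta.copy()
            for j in range(n_par):
                if not free[j]:
                    continue
                span = (hi[j] - lo[j]) / (2.0 ** (_cycle + 1))
                grid = np.clip(
                    theta[j] + span * np.linspace(-1, 1, 7), lo[j], hi[j]
                )
                vals = []
                for gval in grid:
                    cand = theta.copy()
                    cand[j] = gval
                    vals.append(ll_at(cand))
                kbest = int(np.argmax(vals))
                if vals[kbest] > cur:
                    cur = vals[kbest]
                    theta[j] = grid[kbest]
            if np.max(np.abs(theta - prev) / np.maximum(np.abs(prev), 1e-12)) < rel_tol:
                break
        if cur > start_ll:
            improved = True
        if cur > best_ll:
            best_ll, best_theta = cur, theta.copy()

    est = np.exp(best_theta)
    Ne = np.full(d, est[1]) if shared_ne else est[1:]
    return AfsFit(
        m=float(est[0]),
        Ne=Ne,
        log_likelihood=float(best_ll),
        restarts=restarts,
        converged=improved,
        shared_ne=shared_ne,
    )


def parametric_bootstrap(
    fit: AfsFit,
    label: str,
    samples: np.ndarray,
    n_loci: int,
    n_boot: int = 100,
    restarts: int = 2,
    n_sim_loci: int = 2000,
    joint: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[float, float]]:
    """Percentile (2.5-97.5%) intervals from refits of datasets simulated at
    the point estimates."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = rng or np.random.default_rng(0)
    samples = np.asarray(samples, dtype=np.int64)
    d = len(samples)
    model = DemographicModel(label, Ne=fit.Ne, m=fit.m)
    reps_m, reps_ne = [], []
    for _ in range(n_boot):
        counts, _h = simulate_counts_dataset(model, samples, n_loci, rng)
        boot_obs = afs_from_counts(counts, samples)
        refit = fit_afs(
            boot_obs,
            label,
            samples,
            restarts=restarts,
            n_sim_loci=n_sim_loci,
            shared_ne=fit.shared_ne,
            rng=rng,
        )
        reps_m.append(refit.m)
        reps_ne.append(refit.Ne.copy())
    reps_ne = np.asarray(reps_ne)
    out = {"m": tuple(np.percentile(reps_m, [2.5, 97.5]))}
    if fit.shared_ne:
        out["Ne"] = tuple(np.percentile(reps_ne[:, 0], [2.5, 97.5]))
    else:
        for k in range(d):
            out[f"Ne{k + 1}"] = tuple(np.percentile(reps_ne[:, k], [2.5, 97.5]))
    fit.bootstrap = out
    return out
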