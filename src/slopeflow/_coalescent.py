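"""Structured-coalescent kernel producing conditioned SNPs.

Independent genealogies are simulated backward in time: lineages coalesce
within demes at pairwise rate 1/(2 N_e[i]) per generation and migrate between
demes at the backward per-lineage rates of a migration matrix.  SNPs arise as
a Poisson process of constant intensity on total branch length, streamed
across successive genealogies until the requested number of polymorphic sites
is collected.  This reproduces the sampling distribution of neutral SNPs
ascertained from simulated sequences — each site's frequency class is
proportional to the expected branch length subtending it — including the mild
linkage of sites that happen to share a genealogy.  The SNP intensity only
trades genealogy count against linkage; the ensemble distribution of site
frequencies does not depend on it.

Haplotypes are paired at random within demes per site, and the kernel reports
per-deme derived-allele counts and heterozygote counts per SNP.

The event loop is RNG-bound, so it uses an inline xoshiro256** generator
(seeded through splitmix64) instead of numba's Mersenne Twister, and recycles
the fractional remainder of the event-selection uniform to pick lineages
within the selected category (the remainder of a uniform within a chosen
subinterval is itself uniform).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: per-genealogy event guard against non-communicating deme structures
MAX_EVENTS_PER_TREE = 50_000_000

_U53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always")
def _next_u64(s):  # pragma: no cover
    """xoshiro256** step; s is a uint64[4] state array."""
    x = s[1] * np.uint64(5)
    r = ((x << np.uint64(7)) | (x >> np.uint64(57))) * np.uint64(9)
    t = s[1] << np.uint64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = (s[3] << np.uint64(45)) | (s[3] >> np.uint64(19))
    return r


@njit(inline="always")
def _next_double(s):  # pragma: no cover
    return float(_next_u64(s) >> np.uint64(11)) * _U53


@njit(cache=True)
def _seed_state(seed):  # pragma: no cover
    """splitmix64 expansion of a seed into the xoshiro state."""
    s = np.zeros(4, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(4):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        s[i] = w ^ (w >> np.uint64(31))
    return s


@njit(cache=True, fastmath=True)
def _simulate_counts_kernel(seed, n_snps, snps_per_tree, n_pilot, max_trees, nhap, Ne, M):  # pragma: no cover
    """Collect ``n_snps`` SNPs from Poisson-marked genealogies.

    snps_per_tree : target mean SNPs per genealogy; the SNP intensity is set
        from the mean branch length of ``n_pilot`` unmarked pilot genealogies
        (independent of the marked ones, so the ensemble SNP distribution is
        untouched — the intensity only trades genealogy count vs. linkage)
    nhap  : int64[d] haploid sample sizes per deme (2 x diploids)
    Ne    : float64[d] diploid effective sizes
    M     : float64[d, d] backward per-lineage migration rates (row = deme)

    Returns (counts[n_snps, d], het[n_snps, d], n_trees, err); err = 1 when a
    genealogy exceeded the event guard (deme structure without common
    ancestry), err = 2 when max_trees genealogies did not yield enough SNPs.
    """
    rs = _seed_state(seed)
    d = nhap.shape[0]
    ntot = 0
    for i in range(d):
        ntot += nhap[i]

    counts = np.zeros((n_snps, d), dtype=np.int32)
    het = np.zeros((n_snps, d), dtype=np.int32)

    inv4Ne = np.zeros(d)
    Mrow = np.zeros(d)
    for i in range(d):
        inv4Ne[i] = 1.0 / (4.0 * Ne[i])
        s = 0.0
        for j in range(d):
            if j != i:
                s += M[i, j]
        Mrow[i] = s

    desc = np.zeros((ntot, d), dtype=np.int32)
    members = np.zeros((d, ntot), dtype=np.int32)
    kcount = np.zeros(d, dtype=np.int64)
    coal_rate = np.zeros(d)
    mig_rate = np.zeros(d)
    alleles = np.zeros(ntot, dtype=np.int8)

    n_found = 0
    n_trees = 0
    pilot_done = False
    pilot_length = 0.0
    theta = 1.0
    gap = 0.0

    for _tree in range(max_trees):
        n_trees += 1
        # reset state: one lineage per sampled haploid genome
        lid = 0
        for i in range(d):
            ki = nhap[i]
            kcount[i] = ki
            coal_rate[i] = ki * (ki - 1) * inv4Ne[i]
            mig_rate[i] = ki * Mrow[i]
            for s_ in range(ki):
                members[i, s_] = lid
                for j in range(d):
                    desc[lid, j] = 0
                desc[lid, i] = 1
                lid += 1
        k_total = ntot
        events = 0
        tot = 0.0
        for i in range(d):
            tot += coal_rate[i] + mig_rate[i]

        while k_total > 1:
            if (events & 0xFFFF) == 0xFFFF:  # resync against float drift
                tot = 0.0
                for i in range(d):
                    tot += coal_rate[i] + mig_rate[i]
            if tot <= 0.0:
                return counts, het, n_trees, 1
            dt = -np.log(1.0 - _next_double(rs)) / tot
            dL = k_total * dt
            if not pilot_done:
                pilot_length += dL
            else:
                # SNPs falling in this interval (usually none)
                while gap < dL and n_found < n_snps:
                    w = int(gap / dt)  # lineage hosting the SNP
                    if w >= k_total:
                        w = k_total - 1
                    for i in range(d):
                        if w < kcount[i]:
                            lw = members[i, w]
                            for j in range(d):
                                counts[n_found, j] = desc[lw, j]
                            break
                        w -= kcount[i]
                    n_found += 1
                    gap += -np.log(1.0 - _next_double(rs)) / theta
                gap -= dL
            # pick the event category; remainders pick the actors
            z = _next_double(rs) * tot
            applied = False
            for i in range(d):
                rc = coal_rate[i]
                if z < rc:
                    ki = kcount[i]
                    pair = int(z / rc * (ki * (ki - 1)))
                    if pair >= ki * (ki - 1):
                        pair = ki * (ki - 1) - 1
                    a = pair // (ki - 1)
                    b = pair % (ki - 1)
                    if b >= a:
                        b += 1
                    la = members[i, a]
                    lb = members[i, b]
                    for j in range(d):
                        desc[la, j] += desc[lb, j]
                    members[i, b] = members[i, ki - 1]
                    ki -= 1
                    kcount[i] = ki
                    tot -= coal_rate[i] + mig_rate[i]
                    coal_rate[i] = ki * (ki - 1) * inv4Ne[i]
                    mig_rate[i] = ki * Mrow[i]
                    tot += coal_rate[i] + mig_rate[i]
                    k_total -= 1
                    applied = True
                    break
                z -= rc
                rm = mig_rate[i]
                if z < rm:
                    ki = kcount[i]
                    zz = z / ki
                    mig_to = -1
                    for j in range(d):
                        if j == i:
                            continue
                        if zz < M[i, j]:
                            mig_to = j
                            break
                        zz -= M[i, j]
                    if mig_to < 0:
                        for j in range(d - 1, -1, -1):
                            if j != i and M[i, j] > 0.0:
                                mig_to = j
                                break
                    a = int(zz / M[i, mig_to] * ki)
                    if a >= ki or a < 0:
                        a = ki - 1
                    lw = members[i, a]
                    members[i, a] = members[i, ki - 1]
                    ki -= 1
                    kcount[i] = ki
                    kj = kcount[mig_to]
                    members[mig_to, kj] = lw
                    kj += 1
                    kcount[mig_to] = kj
                    tot -= coal_rate[i] + mig_rate[i] + coal_rate[mig_to] + mig_rate[mig_to]
                    coal_rate[i] = ki * (ki - 1) * inv4Ne[i]
                    mig_rate[i] = ki * Mrow[i]
                    coal_rate[mig_to] = kj * (kj - 1) * inv4Ne[mig_to]
                    mig_rate[mig_to] = kj * Mrow[mig_to]
                    tot += coal_rate[i] + mig_rate[i] + coal_rate[mig_to] + mig_rate[mig_to]
                    applied = True
                    break
                z -= rm
            if not applied:
                continue  # float rounding left z past all categories: redraw
            events += 1
            if events > MAX_EVENTS_PER_TREE:
                return counts, het, n_trees, 1

        if not pilot_done:
            if _tree == n_pilot - 1:
                pilot_done = True
                theta = n_pilot * snps_per_tree / pilot_length
                gap = -np.log(1.0 - _next_double(rs)) / theta
        elif n_found >= n_snps:
            break

    if n_found < n_snps:
        return counts, het, n_trees, 2

    # random pairing of haploids into diploids within each deme, per SNP
    for snp in range(n_snps):
        for i in range(d):
            nh = nhap[i]
            c = counts[snp, i]
            for s_ in range(nh):
                alleles[s_] = 1 if s_ < c else 0
            for s_ in range(nh - 1, 0, -1):  # Fisher-Yates shuffle
                t = int(_next_double(rs) * (s_ + 1))
                tmp = alleles[s_]
                alleles[s_] = alleles[t]
                alleles[t] = tmp
            h = 0
            for s_ in range(0, nh, 2):
                if alleles[s_] != alleles[s_ + 1]:
                    h += 1
            het[snp, i] = h

    return counts, het, n_trees, 0


def simulate_counts(
    seed: int,
    n_snps: int,
    nhap: np.ndarray,
    Ne: np.ndarray,
    M: np.ndarray,
    snps_per_tree: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Python entry point for the kernel; raises on simulation failure."""
    nhap = np.ascontiguousarray(nhap, dtype=np.int64)
    Ne = np.ascontiguousarray(Ne, dtype=np.float64)
    M = np.ascontiguousarray(M, dtype=np.float64)
    if np.any(nhap % 2 != 0):
        raise ValueError("haploid sample sizes must be even (diploid samples)")
    if int(np.sum(nhap)) < 2:
        raise ValueError("need at least two haploid genomes")
    n_pilot = 4
    max_trees = n_pilot + 40 + 20 * int(n_snps)
    counts, het, _n_trees, err = _simulate_counts_kernel(
        int(seed), int(n_snps), float(snps_per_tree), n_pilot, max_trees, nhap, Ne, M
    )
    if err == 1:
        raise RuntimeError(
            "coalescent did not reach a common ancestor (non-communicating "
            "deme structure or event guard exceeded)"
        )
    if err == 2:
        raise RuntimeError("SNP intensity too low: genealogy budget exhausted")
    return counts, het
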