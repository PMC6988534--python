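"""Genotype and metadata IO plus the post-calling filters.

Genotypes are held as alternate-allele dosage codes (0, 1, 2) in a dense
matrix; ``MISSING`` (-1) marks uncalled genotypes.  The filter pipeline
(per-population Hardy-Weinberg imputation followed by a pooled minor-allele
frequency cut) guarantees downstream modules a complete, missing-free matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "load_genotypes",
    "load_popmap",
    "write_genotypes",
    "write_popmap",
    "filter_maf",
    "impute_missing",
]


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes per (sample, locus).

    ``calls[i, j]`` counts copies of locus ``j``'s alternate allele carried by
    sample ``i`` (0, 1, 2) or is :data:`MISSING`.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray  # (n_samples, n_loci) int8
    chrom: list[str] | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(f"invalid genotype code at (sample {bad[0]}, locus {bad[1]})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            chrom=[self.chrom[i] for i in idx] if self.chrom is not None else None,
            pos=self.pos[idx].copy() if self.pos is not None else None,
        )


@dataclass
class PopulationMap:
    """sample -> (population, elevation m a.s.l., latitude, longitude)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample", "population", "elevation_m", "lat", "lon")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"population map missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample in population map: {dup!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        """Population labels ordered by increasing elevation."""
        pops = (
            self.table.groupby("population", sort=False)["elevation_m"]
            .first()
            .sort_values()
        )
        return list(pops.index)

    def population_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"sample {sample!r} absent from population map")
        return str(row["population"].iloc[0])

    def indices_by_population(self, sample_ids: list[str]) -> dict[str, np.ndarray]:
        """Column indices of ``sample_ids`` grouped by population (low -> high)."""
        lookup = dict(zip(self.table["sample"], self.table["population"]))
        for s in sample_ids:
            if s not in lookup:
                raise KeyError(f"sample {s!r} absent from population map")
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, s in enumerate(sample_ids):
            out[lookup[s]].append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items() if ix}

    def elevations(self) -> pd.Series:
        return self.table.groupby("population")["elevation_m"].first()

    def coordinates(self) -> pd.DataFrame:
        return self.table.groupby("population")[["lat", "lon"]].first()


def load_popmap(path) -> PopulationMap:
    """Read the 5-column TSV population map (sample, population, elevation_m, lat, lon)."""
    df = pd.read_csv(path, sep="\t")
    return PopulationMap(df)


def write_popmap(pm: PopulationMap, path) -> None:
    pm.table.to_csv(path, sep="\t", index=False)


def load_genotypes(vcf_path, popmap_path) -> tuple[GenotypeMatrix, PopulationMap]:
    """Read a biallelic-SNP VCF and its population map.

    Sample order follows the VCF header.  Multi-allelic records are rejected
    with their coordinates; samples absent from the population map are a hard
    error.
    """
    from cyvcf2 import VCF

    pm = load_popmap(popmap_path)
    known = set(pm.table["sample"])

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in known:
            raise ValueError(f"sample {s!r} present in VCF but absent from population map")

    loci: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {var.CHROM}:{var.POS} (ALT={var.ALT})"
            )
        gts = np.asarray(var.genotypes, dtype=object)
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        columns.append(col)
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
    vcf.close()

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    g = GenotypeMatrix(
        sample_ids=samples,
        locus_ids=loci,
        calls=calls,
        chrom=chroms,
        pos=np.asarray(positions, dtype=np.int64),
    )
    return g, pm


_GT_STR = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT field only, unphased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = g.chrom if g.chrom is not None else ["1"]
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j in range(g.n_loci):
            chrom = g.chrom[j] if g.chrom is not None else "1"
            pos = int(g.pos[j]) if g.pos is not None else j + 1
            fields = [chrom, str(pos), g.locus_ids[j], "A", "T", ".", "PASS", ".", "GT"]
            fields += [_GT_STR[int(c)] for c in g.calls[:, j]]
            fh.write("\t".join(fields) + "\n")


def pooled_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor-allele frequency pooled over all samples.

    MISSING calls are excluded from the denominators.  Loci with no genotyped
    sample get MAF 0.
    """
    calls = g.calls
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
    n_chrom = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.02) -> GenotypeMatrix:
    """Drop loci whose pooled minor-allele frequency is strictly below ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    keep = np.flatnonzero(pooled_maf(g) >= threshold)
    return g.take_loci(keep)


def _hw_probs(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def impute_missing(
    g: GenotypeMatrix, pm: PopulationMap, confidence: float = 0.70
) -> GenotypeMatrix:
    """Hardy-Weinberg posterior imputation within populations.

    Each MISSING call is replaced by the genotype with maximal Hardy-Weinberg
    probability under its population's allele frequency at that locus, provided
    that probability reaches ``confidence``.  Loci that still contain MISSING
    afterwards (low-confidence calls, or populations with no data at the locus)
    are dropped, so the result is complete.
    """
    if not 0.0 < confidence <= 1.0:
        raise ValueError(f"confidence must be in (0, 1], got {confidence}")
    calls = g.calls.copy()
    groups = pm.indices_by_population(g.sample_ids)
    drop = np.zeros(g.n_loci, dtype=bool)
    for idx in groups.values():
        block = calls[idx, :]
        miss = block == MISSING
        cols = np.flatnonzero(miss.any(axis=0))
        for j in cols:
            col = block[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:  # unresolvable within this population
                drop[j] = True
                continue
            p = obs.sum() / (2.0 * obs.size)
            probs = _hw_probs(p)
            best = int(np.argmax(probs))
            if probs[best] >= confidence:
                col = col.copy()
                col[col == MISSING] = best
                block[:, j] = col
            else:
                drop[j] = True
        calls[idx, :] = block
    out = GenotypeMatrix(
        sample_ids=list(g.sample_ids),
        locus_ids=list(g.locus_ids),
        calls=calls,
        chrom=list(g.chrom) if g.chrom is not None else None,
        pos=g.pos.copy() if g.pos is not None else None,
    )
    keep = np.flatnonzero(~drop)
    if len(keep) < g.n_loci:
        warnings.warn(
            f"dropped {g.n_loci - len(keep)} loci that could not be imputed at "
            f"confidence {confidence:g}",
            stacklevel=2,
        )
    out = out.take_loci(keep)
    assert not out.has_missing()
    return out
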