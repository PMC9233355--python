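"""Simulation of segregating populations from a true genetic map.

The simulator produces F2 (and recombinant inbred line) populations derived
from two fully homozygous inbred parents. Meiosis follows a no-interference
(Poisson crossover) model: the number of crossovers per chromosome and gamete
is Poisson with mean equal to the chromosome's genetic length in Morgans, and
crossover locations are uniform on the genetic (cM) scale. This reproduces
Haldane's mapping function exactly: the recombinant fraction between two loci
d Morgans apart is (1 - exp(-2d)) / 2.

Genotypes are dosages of the parent-2 allele in {0, 1, 2}; pooling the
population yields one allele frequency per marker, the sole genetic input of
the pool-genetic-map estimator downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

MISSING = -1  # missing-dosage code in genotype matrices

MAP_COLUMNS = ["chrom", "pos_bp", "cM"]


class MapError(ValueError):
    """Raised for structurally invalid genetic maps."""


def validate_map(tmap: pd.DataFrame) -> pd.DataFrame:
    """Validate a genetic map (columns chrom, pos_bp, cM) and return it.

    Within each chromosome, physical positions must be strictly increasing
    and genetic positions non-decreasing; no duplicated (chrom, pos_bp).
    """
    missing = [c for c in MAP_COLUMNS if c not in tmap.columns]
    if missing:
        raise MapError(f"map is missing columns {missing}")
    if len(tmap) == 0:
        raise MapError("map is empty")
    if tmap[["pos_bp", "cM"]].isna().any().any():
        raise MapError("map contains missing positions")
    if (tmap["cM"] < 0).any():
        raise MapError("negative genetic positions")
    for chrom, grp in tmap.groupby("chrom", sort=False):
        bp = grp["pos_bp"].to_numpy()
        cm = grp["cM"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise MapError(f"physical positions not strictly increasing on {chrom}")
        if np.any(np.diff(cm) < 0):
            raise MapError(f"genetic positions decreasing on {chrom}")
    return tmap


@dataclass
class SimConfig:
    """Parameters of one simulated pooled sample.

    n_genotypes: population size (number of individuals pooled).
    depth: genotyping depth, i.e. number of markers assayed (<= markers in map).
    pop_type: 'F2' or 'RIL'.
    selfing_generations: for RIL; None means fully inbred (infinite selfing).
    replicates: number of independent populations per configuration.
    seed: top-level RNG seed; per-replicate streams derive deterministically.
    """

    n_genotypes: int
    depth: int
    pop_type: Literal["F2", "RIL"] = "F2"
    selfing_generations: int | None = None
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValueError("population size must be >= 1")
        if self.depth < 2:
            raise ValueError("genotyping depth must be >= 2")
        if self.pop_type not in ("F2", "RIL"):
            raise ValueError(f"unknown population type {self.pop_type!r}")

    def rng_for_replicate(self, replicate: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, replicate])


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage of the parent-2 allele.

    dosage values are in {0, 1, 2} with MISSING (-1) for no-calls; marker
    metadata (chrom, pos_bp, cM) is carried alongside in physical order.
    """

    markers: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be individuals x markers")
        if self.dosage.shape[1] != len(self.markers):
            raise ValueError("marker count mismatch between dosage and metadata")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]


def make_synthetic_map(
    n_chrom: int,
    markers_per_chrom: int,
    chrom_len_bp: int,
    total_cM: float,
    profile: str = "uniform",
) -> pd.DataFrame:
    """Construct a synthetic true genetic map.

    Markers are equally spaced physically; the genetic (Marey) profile is
    either 'uniform' (constant cM/bp) or 'barley_like', which emulates the
    pericentromeric recombination suppression of large cereal genomes: the
    middle third of each chromosome is a near-plateau carrying only ~2% of
    the genetic length, so the outer thirds hold ~98% of the centiMorgans
    (well above the 70% such genomes show at minimum). Each chromosome
    carries total_cM / n_chrom centiMorgans.
    """
    if n_chrom < 1 or markers_per_chrom < 2 or chrom_len_bp < markers_per_chrom:
        raise MapError("non-positive or inconsistent synthetic map sizes")
    if total_cM <= 0:
        raise MapError("total genetic length must be positive")
    if profile not in ("uniform", "barley_like"):
        raise MapError(f"unknown profile {profile!r}")

    per_chrom_cM = total_cM / n_chrom
    frames = []
    for c in range(1, n_chrom + 1):
        bp = np.linspace(1, chrom_len_bp, markers_per_chrom).round().astype(np.int64)
        bp = np.unique(bp)  # guards against rounding collisions
        x = (bp - bp[0]) / (bp[-1] - bp[0])  # relative position in [0, 1]
        if profile == "uniform":
            cm = x * per_chrom_cM
        else:
            # Piecewise-uniform crossover density: outer thirds at weight 1,
            # pericentromeric middle third at weight w_mid, giving the
            # middle a w_mid/(2 + w_mid) share (~2%) of the genetic length.
            w_mid = 0.04
            cum = np.where(
                x < 1 / 3,
                x,
                np.where(
                    x < 2 / 3,
                    1 / 3 + (x - 1 / 3) * w_mid,
                    (1 + w_mid) / 3 + (x - 2 / 3),
                ),
            )
            cm = cum / ((2 + w_mid) / 3) * per_chrom_cM
        frames.append(pd.DataFrame({"chrom": f"chr{c}", "pos_bp": bp, "cM": cm}))
    tmap = pd.concat(frames, ignore_index=True)
    return validate_map(tmap)


def _chromosome_blocks(tmap: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    """Index slices and cM arrays per chromosome, in file order."""
    blocks = []
    start = 0
    for _, grp in tmap.groupby("chrom", sort=False):
        n = len(grp)
        blocks.append((slice(start, start + n), grp["cM"].to_numpy(float)))
        start += n
    return blocks


def _meiosis_origins(cm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Parent-of-origin (0/1) for each marker of one chromosome in one gamete."""
    length_cM = cm[-1] - cm[0]
    n_cross = rng.poisson(length_cM / 100.0)
    start = int(rng.integers(2))
    if n_cross == 0:
        return np.full(cm.shape, start, dtype=np.int8)
    xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_cross))
    switches = np.searchsorted(xpos, cm, side="right")
    return ((start + switches) % 2).astype(np.int8)


def simulate_gamete(tmap: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """One F1 gamete: per-marker parent of origin in {0, 1}.

    Crossover counts are Poisson in the chromosome's Morgan length and
    crossover positions uniform on the genetic scale (no interference); the
    chromosome-start parent is a fair coin per gamete and chromosome.
    """
    validate_map(tmap)
    out = np.empty(len(tmap), dtype=np.int8)
    for sl, cm in _chromosome_blocks(tmap):
        out[sl] = _meiosis_origins(cm, rng)
    return out


def _origin_matrix(
    blocks: list[tuple[slice, np.ndarray]],
    n_markers: int,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parent-of-origin matrix (n_gametes x n_markers) for many meioses.

    Uses the interval representation of the Poisson crossover process:
    crossover counts in disjoint genetic intervals are independent, so the
    origin switch between adjacent markers d Morgans apart is an
    independent Bernoulli with the Haldane probability (1 - exp(-2d)) / 2,
    and the chromosome-start parent is a fair coin. At the assayed markers
    this is distributionally identical to drawing explicit crossover
    positions (as simulate_gamete does), but vectorizes over gametes.
    """
    out = np.empty((n_gametes, n_markers), dtype=np.int8)
    for sl, cm in blocks:
        d_morgan = np.diff(cm) / 100.0
        p_switch = (1.0 - np.exp(-2.0 * d_morgan)) / 2.0
        start = rng.integers(2, size=(n_gametes, 1), dtype=np.int8)
        if p_switch.size:
            switches = (rng.random((n_gametes, p_switch.size)) < p_switch).astype(
                np.int8
            )
            parity = np.cumsum(switches, axis=1, dtype=np.int32) % 2
            out[:, sl] = np.concatenate([start, (start + parity) % 2], axis=1)
        else:
            out[:, sl] = start
    return out


#: individuals simulated per vectorized batch (bounds transient memory)
_BATCH_CELLS = 20_000_000


def simulate_f2_population(
    tmap: pd.DataFrame, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """An F2 population: each individual is the sum of two independent F1 gametes."""
    validate_map(tmap)
    if n < 1:
        raise ValueError("population size must be >= 1")
    blocks = _chromosome_blocks(tmap)
    m = len(tmap)
    dosage = np.empty((n, m), dtype=np.int8)
    batch = max(1, _BATCH_CELLS // max(m, 1))
    for lo in range(0, n, batch):
        k = min(batch, n - lo)
        dosage[lo : lo + k] = _origin_matrix(blocks, m, k, rng) + _origin_matrix(
            blocks, m, k, rng
        )
    return GenotypeMatrix(markers=tmap.reset_index(drop=True), dosage=dosage)


def simulate_ril(
    tmap: pd.DataFrame,
    n: int,
    selfing_generations: int | None,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Recombinant inbred lines by repeated selfing from the F1.

    selfing_generations counts selfing meioses after the F1, so one
    generation reproduces an F2. None means a fully inbred line: selfing is
    iterated until residual heterozygosity is negligible (24 rounds,
    expected residual < 2^-23 per locus) and any leftover heterozygous
    dosage is resolved to 0 or 2 by a fair coin per locus and individual.
    Under full inbreeding the recombinant fraction between two loci at
    single-meiosis distance r expands to 2r / (1 + 2r) (Haldane-Waddington).
    """
    validate_map(tmap)
    infinite = selfing_generations is None
    gens = 24 if infinite else int(selfing_generations)
    if gens < 1:
        raise ValueError("selfing_generations must be >= 1")
    if n < 1:
        raise ValueError("population size must be >= 1")
    blocks = _chromosome_blocks(tmap)
    m = len(tmap)
    hap_a = _origin_matrix(blocks, m, n, rng)  # F2: two F1 gametes each
    hap_b = _origin_matrix(blocks, m, n, rng)
    for _ in range(gens - 1):
        origin_a = _origin_matrix(blocks, m, n, rng)
        origin_b = _origin_matrix(blocks, m, n, rng)
        new_a = np.where(origin_a == 0, hap_a, hap_b)
        new_b = np.where(origin_b == 0, hap_a, hap_b)
        hap_a, hap_b = new_a.astype(np.int8), new_b.astype(np.int8)
    dosage = (hap_a + hap_b).astype(np.int8)
    if infinite:
        het = dosage == 1
        if het.any():
            dosage[het] = 2 * rng.integers(2, size=int(het.sum())).astype(np.int8)
    return GenotypeMatrix(markers=tmap.reset_index(drop=True), dosage=dosage)


def subsample_markers(
    tmap: pd.DataFrame, depth: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Uniform random marker subset of the given size, physical order kept.

    When depth equals the number of available markers the full set is
    returned without consuming randomness, so full-depth replicates share
    the identical marker panel.
    """
    n = len(tmap)
    if depth > n:
        raise ValueError(f"requested depth {depth} exceeds {n} available markers")
    if depth == n:
        return tmap.reset_index(drop=True).copy()
    idx = np.sort(rng.choice(n, size=depth, replace=False))
    return tmap.iloc[idx].reset_index(drop=True)


def pool_allele_frequency(g: GenotypeMatrix) -> pd.DataFrame:
    """Pool a population into per-marker allele frequencies.

    AF is the parent-2 allele count over non-missing calls divided by twice
    the non-missing individual count; the per-marker missing fraction is
    recorded. Markers with no calls at all are dropped with a warning.
    """
    d = g.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    all_missing = n_called == 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} marker(s) with no non-missing calls dropped",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called, d, 0).sum(axis=0) / (2.0 * n_called)
    track = g.markers[["chrom", "pos_bp"]].copy()
    track["af"] = af
    track["missing_frac"] = 1.0 - n_called / g.n_individuals
    return track.loc[~all_missing].reset_index(drop=True)
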