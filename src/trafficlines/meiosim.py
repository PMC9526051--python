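"""Stochastic meiosis: synthetic seed data and a brute-force oracle.

Crossovers along a bivalent are modelled as a stationary gamma renewal process
with shape ``nu`` and rate ``2 * nu`` events per Morgan; each event resolves
into the sampled chromatid with probability 1/2 (chromatid thinning), so the
retained crossover density on a gamete is 1 per Morgan regardless of ``nu``.
``nu = 1`` gives Poisson crossovers (no interference, Haldane's map function);
larger ``nu`` spaces crossovers more regularly, suppressing nearby doubles the
way the coefficient of coincidence does in the exact engine.

The simulator is deliberately independent of :mod:`trafficlines.crosscalc`:
the two agree on overlapping ground only because the biology does, which is
what the cross-validation tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .crosscalc import (
    INTENSITIES,
    CrossDesign,
    GeneticMap,
    Haplotype,
    LethalSpec,
    SeedClassModel,
)
from .linkage import CountTable, Phase

__all__ = [
    "InterferenceModel",
    "SimulatedSeedPopulation",
    "morgans_from_r",
    "segment_morgans_for_map",
    "simulate_strand_matrix",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_cross",
    "simulate_testcross_counts",
]


@dataclass(frozen=True)
class InterferenceModel:
    """Gamma-renewal crossover interference; nu = 1 means none (Poisson)."""

    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.nu < 0.25:
            raise ValueError(f"gamma shape nu must be >= 0.25, got {self.nu}")


def morgans_from_r(r: float) -> float:
    """Invert Haldane's map function: genetic length whose Poisson-crossover
    recombination fraction is exactly r (used to place loci for simulation)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"need 0 <= r < 0.5 to invert Haldane, got {r}")
    return -0.5 * np.log(1.0 - 2.0 * r)


def segment_morgans_for_map(gmap: GeneticMap) -> dict[int, list[float]]:
    """Per-chromosome segment lengths in Morgans matching the map's fractions
    under the nu = 1 simulator."""
    return {
        chrom: [morgans_from_r(r) for r in rs] for chrom, rs in gmap.segment_r.items()
    }


def _equilibrium_first_arrival(n: int, nu: float, scale: float, rng: np.random.Generator):
    # stationary renewal: residual life = U * length-biased interval, and the
    # length-biased gamma(nu) interval is gamma(nu + 1)
    return rng.uniform(size=n) * rng.gamma(nu + 1.0, scale, size=n)


def simulate_strand_matrix(
    n: int,
    locus_positions: Sequence[float],
    interference: InterferenceModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Strand-of-origin matrix for n gametes over loci at given Morgan positions.

    Returns an (n, n_loci) uint8 array of 0/1 strand indicators: entry (i, j)
    says which parental strand gamete i copies at locus j.  The first locus
    sits at position 0; crossover points come from the stationary gamma
    renewal process thinned by 1/2.
    """
    pos = np.asarray(locus_positions, dtype=float)
    if pos.ndim != 1 or pos.size < 1 or np.any(np.diff(pos) < 0):
        raise ValueError("locus_positions must be a non-decreasing 1-D sequence")
    k = pos.size
    start = rng.integers(0, 2, size=n).astype(np.uint8)
    if k == 1 or pos[-1] == 0.0:
        return np.repeat(start[:, None], k, axis=1)
    nu = interference.nu
    scale = 1.0 / (2.0 * nu)
    length = float(pos[-1])
    seg_flips = np.zeros((n, k - 1), dtype=bool)
    x = _equilibrium_first_arrival(n, nu, scale, rng)
    active = x < length
    while active.any():
        idx = np.nonzero(active)[0]
        kept = idx[rng.random(idx.size) < 0.5]
        if kept.size:
            seg = np.searchsorted(pos, x[kept], side="right") - 1
            np.logical_xor.at(seg_flips, (kept, seg), True)
        x[idx] += rng.gamma(nu, scale, size=idx.size)
        active[idx] = x[idx] < length
    parity = np.cumsum(seg_flips, axis=1) & 1
    strands = np.empty((n, k), dtype=np.uint8)
    strands[:, 0] = start
    strands[:, 1:] = start[:, None] ^ parity.astype(np.uint8)
    return strands


def _parent_allele_matrix(parent: tuple[Haplotype, Haplotype]) -> np.ndarray:
    return np.array([list(parent[0]), list(parent[1])], dtype=object)


def simulate_gametes(
    parent: tuple[Haplotype, Haplotype],
    gmap: GeneticMap,
    n: int,
    interference: InterferenceModel | None = None,
    rng: np.random.Generator | None = None,
    segment_morgans: Mapping[int, Sequence[float]] | None = None,
) -> list[Haplotype]:
    """Draw n gametes from a parent; chromosomes assort independently.

    Segment lengths default to the Haldane inversion of the map's fractions,
    so at nu = 1 the simulated two-point fractions equal the map's r exactly.
    """
    interference = interference or InterferenceModel()
    rng = rng if rng is not None else np.random.default_rng()
    seg_m = dict(segment_morgans) if segment_morgans is not None else segment_morgans_for_map(gmap)
    alleles = _parent_allele_matrix(parent)
    n_loci = len(gmap.loci)
    out = np.empty((n, n_loci), dtype=object)
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_indices(chrom)
        positions = np.concatenate([[0.0], np.cumsum(seg_m[chrom])])
        strands = simulate_strand_matrix(n, positions, interference, rng)
        for j, locus_i in enumerate(idx):
            out[:, locus_i] = alleles[strands[:, j], locus_i]
    return [tuple(row) for row in out]


def simulate_gamete(
    parent: tuple[Haplotype, Haplotype],
    gmap: GeneticMap,
    interference: InterferenceModel | None = None,
    rng: np.random.Generator | None = None,
) -> Haplotype:
    """Draw a single gamete (convenience wrapper over simulate_gametes)."""
    return simulate_gametes(parent, gmap, 1, interference, rng)[0]


@dataclass
class SimulatedSeedPopulation:
    """A simulated seed lot: genotypes, true and observed classes, viability.

    ``seeds`` has one row per seed with columns ``<locus>_a``/``<locus>_b``
    (unordered haplotype alleles), ``green_true``/``red_true`` (dosage-coded
    intensity), ``green_obs``/``red_obs`` (after misclassification) and
    ``viable``.  ``seed`` records the RNG seed used so runs are reproducible
    bit for bit.
    """

    seeds: pd.DataFrame
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# trafficlines simulate seed={self.seed} params={self.params}\n")
            self.seeds.to_csv(fh, sep="\t", index=False)


def _observed_intensity(
    true_idx: np.ndarray, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    """Adjacent-intensity confusion on intensity indices 0/1/2."""
    obs = true_idx.copy()
    if epsilon == 0.0:
        return obs
    u = rng.random(true_idx.size)
    lower = u < epsilon / 2.0
    upper = (u >= epsilon / 2.0) & (u < epsilon)
    # end classes put all epsilon mass on their single neighbour
    obs[(true_idx == 0) & (lower | upper)] = 1
    obs[(true_idx == 2) & (lower | upper)] = 1
    obs[(true_idx == 1) & lower] = 0
    obs[(true_idx == 1) & upper] = 2
    return obs


def simulate_cross(
    cross: CrossDesign,
    n_seeds: int,
    model: SeedClassModel | None = None,
    interference: InterferenceModel | None = None,
    rng: np.random.Generator | int | None = None,
    lethal: Iterable[LethalSpec] = (),
    segment_morgans: Mapping[int, Sequence[float]] | None = None,
) -> SimulatedSeedPopulation:
    """Simulate a seed population from a cross (selfing if father is None)."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    model = model or SeedClassModel()
    interference = interference or InterferenceModel()
    seed_used = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gmap = cross.map
    mom = simulate_gametes(cross.mother, gmap, n_seeds, interference, gen, segment_morgans)
    dad = simulate_gametes(cross.father_or_self, gmap, n_seeds, interference, gen, segment_morgans)
    mom_arr = np.array(mom, dtype=object)
    dad_arr = np.array(dad, dtype=object)
    i_green = gmap.marker_index("green") if any(l.channel == "green" for l in gmap.loci) else None
    i_red = gmap.marker_index("red") if any(l.channel == "red" for l in gmap.loci) else None

    def dosage(i: int | None) -> np.ndarray:
        if i is None:
            return np.zeros(n_seeds, dtype=np.int64)
        return (mom_arr[:, i] != "+").astype(np.int64) + (dad_arr[:, i] != "+").astype(np.int64)

    g_true = dosage(i_green)
    r_true = dosage(i_red)
    g_obs = _observed_intensity(g_true, model.epsilon, gen)
    r_obs = _observed_intensity(r_true, model.epsilon, gen)
    viable = np.ones(n_seeds, dtype=bool)
    for spec in tuple(lethal):
        hit = np.ones(n_seeds, dtype=bool)
        for name, allele in spec.items():
            i = gmap.locus_index(name)
            hit &= (mom_arr[:, i] == allele) & (dad_arr[:, i] == allele)
        viable &= ~hit
    data: dict[str, object] = {}
    for i, loc in enumerate(gmap.loci):
        pair = np.sort(np.stack([mom_arr[:, i], dad_arr[:, i]], axis=1), axis=1)
        data[f"{loc.name}_a"] = pair[:, 0]
        data[f"{loc.name}_b"] = pair[:, 1]
    names = np.array(INTENSITIES)
    data["green_true"] = names[g_true]
    data["red_true"] = names[r_true]
    data["green_obs"] = names[g_obs]
    data["red_obs"] = names[r_obs]
    data["viable"] = viable
    return SimulatedSeedPopulation(
        seeds=pd.DataFrame(data),
        seed=seed_used,
        params={"n_seeds": n_seeds, "nu": interference.nu, "epsilon": model.epsilon},
    )


def simulate_testcross_counts(
    r: float,
    n: int,
    phase: Phase = "repulsion",
    rng: np.random.Generator | int | None = None,
) -> CountTable:
    """Multinomial testcross seed classes at a true recombination fraction.

    Gamete classes of the doubly heterozygous parent appear directly in the
    offspring of a cross to the unmarked tester: parental classes (1-r)/2
    each, recombinant classes r/2 each, arranged by phase (in repulsion the
    single-colour classes are parental).
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    par, rec = (1.0 - r) / 2.0, r / 2.0
    draw = gen.multinomial(n, [par, par, rec, rec])
    if phase == "repulsion":
        return CountTable(int(draw[0]), int(draw[1]), int(draw[2]), int(draw[3]), "repulsion")
    return CountTable(int(draw[2]), int(draw[3]), int(draw[0]), int(draw[1]), "coupling")
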