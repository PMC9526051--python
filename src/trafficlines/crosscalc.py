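"""Exact probabilities for crossing schemes built on traffic lines.

A traffic line (TL) is a chromosome carrying linked green and red seed-
fluorescence markers in cis.  Schemes that use a TL as a balancer or as a
recombination screen all reduce to the same calculus: enumerate the gametes of
each parent with their probabilities, convolve parents into offspring
diplotypes, map diplotypes to seed fluorescence classes through marker dosage
(0/1/2 reporter copies per channel -> none/moderate/strong intensity), and
condition.  Crossover interference enters through a single coefficient of
coincidence ``c`` applied to double crossovers in adjacent segments.

Alleles are plain strings; ``"+"`` always denotes the absent/wild-type allele,
and at a marker locus any other allele means the reporter is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Locus",
    "GeneticMap",
    "CrossDesign",
    "SeedClassModel",
    "INTENSITIES",
    "diplotype_key",
    "gamete_distribution",
    "offspring_distribution",
    "double_recombinant_freq",
    "balancer_purity",
    "seed_class_distribution",
    "genotype_posterior",
    "marker_dosage",
    "rescue_scheme",
    "separation_scheme",
    "sample_size",
]

Haplotype = tuple[str, ...]
DiplotypeKey = tuple[Haplotype, Haplotype]

INTENSITIES = ("none", "moderate", "strong")  # dosage 0 / 1 / 2

_PUBLIC_MAX_LINKED = 3  # beyond this, interference algebra is delegated to meiosim


@dataclass(frozen=True)
class Locus:
    """A named biallelic locus; markers carry a fluorescence channel."""

    name: str
    chromosome: int = 1
    alleles: tuple[str, str] = ("+", "m")
    position_bp: int | None = None
    channel: str | None = None  # "green" | "red" | None

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != 2:
            raise ValueError(f"locus {self.name}: needs two distinct allele labels")
        if self.channel not in (None, "green", "red"):
            raise ValueError(f"locus {self.name}: channel must be green, red or None")


class GeneticMap:
    """Ordered loci with per-adjacent-segment recombination fractions.

    ``segment_r`` maps chromosome -> recombination fractions between
    consecutive loci on that chromosome (one fewer than the locus count).
    ``c`` is the coefficient of coincidence for adjacent-segment double
    crossovers (1 = no interference, 0 = complete interference).
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        segment_r: Mapping[int, Sequence[float]] | Sequence[float],
        c: float = 1.0,
    ) -> None:
        self.loci = tuple(loci)
        if not self.loci:
            raise ValueError("map needs at least one locus")
        chroms: list[int] = []
        for loc in self.loci:
            if not chroms or loc.chromosome != chroms[-1]:
                if loc.chromosome in chroms:
                    raise ValueError("loci of each chromosome must be contiguous in the list")
                chroms.append(loc.chromosome)
        self.chromosomes = tuple(chroms)
        if not isinstance(segment_r, Mapping):
            if len(chroms) != 1:
                raise ValueError("flat segment list only allowed for a single-chromosome map")
            segment_r = {chroms[0]: segment_r}
        self.segment_r: dict[int, tuple[float, ...]] = {}
        for chrom in chroms:
            k = sum(1 for loc in self.loci if loc.chromosome == chrom)
            rs = tuple(float(r) for r in segment_r.get(chrom, ()))
            if len(rs) != k - 1:
                raise ValueError(
                    f"chromosome {chrom}: {k} loci need {k - 1} segment fractions, got {len(rs)}"
                )
            for r in rs:
                if not 0.0 <= r <= 0.5:
                    raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
            self.segment_r[chrom] = rs
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"coefficient of coincidence must be in [0, 1], got {c}")
        self.c = float(c)

    def chrom_indices(self, chrom: int) -> list[int]:
        return [i for i, loc in enumerate(self.loci) if loc.chromosome == chrom]

    def locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise KeyError(f"no locus named {name!r}")

    def marker_index(self, channel: str) -> int:
        hits = [i for i, loc in enumerate(self.loci) if loc.channel == channel]
        if len(hits) != 1:
            raise ValueError(f"map must carry exactly one {channel} marker locus, found {len(hits)}")
        return hits[0]


@dataclass(frozen=True)
class CrossDesign:
    """Two parental diplotypes over one shared map; father None means selfing."""

    map: GeneticMap
    mother: tuple[Haplotype, Haplotype]
    father: tuple[Haplotype, Haplotype] | None = None

    def __post_init__(self) -> None:
        n = len(self.map.loci)
        for hap in (*self.mother, *(self.father or ())):
            if len(hap) != n:
                raise ValueError(f"haplotype {hap} does not cover the map's {n} loci")
            for allele, loc in zip(hap, self.map.loci):
                if allele not in loc.alleles:
                    raise ValueError(f"allele {allele!r} not valid at locus {loc.name}")

    @property
    def father_or_self(self) -> tuple[Haplotype, Haplotype]:
        return self.father if self.father is not None else self.mother


def diplotype_key(h1: Haplotype, h2: Haplotype) -> DiplotypeKey:
    """Order-free diplotype key (maternal/paternal origin is not tracked)."""
    return tuple(sorted((h1, h2)))  # type: ignore[return-value]


def _pattern_probs(rs: Sequence[float], c: float) -> dict[tuple[bool, ...], float]:
    """Joint law of per-segment exchange indicators for up to three segments.

    Marginals are the segment fractions r_i; adjacent pairs co-occur with
    probability c*r_i*r_j, non-adjacent pairs independently, and the triple
    with c^2*r1*r2*r3 (coincidence applied once per adjacency).  Probabilities
    of all 2^k patterns follow by inclusion-exclusion.
    """
    k = len(rs)
    if k > 3:
        raise ValueError("pattern engine supports at most three segments")
    pair = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair[(i, j)] = (c if j == i + 1 else 1.0) * rs[i] * rs[j]
    triple = c * c * rs[0] * rs[1] * rs[2] if k == 3 else 0.0
    out: dict[tuple[bool, ...], float] = {}
    for pattern in product((False, True), repeat=k):
        ones = [i for i, b in enumerate(pattern) if b]
        zeros = [i for i, b in enumerate(pattern) if not b]
        # inclusion-exclusion over which of the "zero" segments actually fire
        p = 0.0
        for extra in product((False, True), repeat=len(zeros)):
            s = ones + [z for z, e in zip(zeros, extra) if e]
            sign = -1.0 if sum(extra) % 2 else 1.0
            if len(s) == 0:
                term = 1.0
            elif len(s) == 1:
                term = rs[s[0]]
            elif len(s) == 2:
                term = pair[(min(s), max(s))]
            else:
                term = triple
            p += sign * term
        if p < -1e-12:
            raise ValueError(
                f"inconsistent interference parameters: pattern {pattern} has probability {p}"
            )
        out[pattern] = max(p, 0.0)
    return out


def _chromosome_gametes(
    hap_a: Haplotype, hap_b: Haplotype, rs: Sequence[float], c: float
) -> dict[Haplotype, float]:
    """Gamete law for one chromosome: exchange pattern x random start strand."""
    dist: dict[Haplotype, float] = {}
    for pattern, p in _pattern_probs(rs, c).items():
        if p == 0.0:
            continue
        for start in (0, 1):
            strand = start
            alleles = []
            for i in range(len(hap_a)):
                alleles.append(hap_a[i] if strand == 0 else hap_b[i])
                if i < len(pattern) and pattern[i]:
                    strand ^= 1
            hap = tuple(alleles)
            dist[hap] = dist.get(hap, 0.0) + 0.5 * p
    return dist


def _gamete_distribution(
    parent: tuple[Haplotype, Haplotype], gmap: GeneticMap, max_linked: int
) -> dict[Haplotype, float]:
    hap_a, hap_b = parent
    per_chrom: list[tuple[list[int], dict[Haplotype, float]]] = []
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_indices(chrom)
        if len(idx) > max_linked:
            raise ValueError(
                f"chromosome {chrom} carries {len(idx)} linked loci; exact interference "
                "algebra is limited to short maps - use trafficlines.meiosim for longer ones"
            )
        sub_a = tuple(hap_a[i] for i in idx)
        sub_b = tuple(hap_b[i] for i in idx)
        per_chrom.append((idx, _chromosome_gametes(sub_a, sub_b, gmap.segment_r[chrom], gmap.c)))
    n = len(gmap.loci)
    dist: dict[Haplotype, float] = {}
    for combo in product(*(d.items() for _, d in per_chrom)):
        alleles: list[str | None] = [None] * n
        p = 1.0
        for (idx, _), (sub_hap, sub_p) in zip(per_chrom, combo):
            p *= sub_p
            for i, a in zip(idx, sub_hap):
                alleles[i] = a
        hap = tuple(alleles)  # type: ignore[arg-type]
        dist[hap] = dist.get(hap, 0.0) + p
    return dist


def gamete_distribution(
    parent: tuple[Haplotype, Haplotype], gmap: GeneticMap
) -> dict[Haplotype, float]:
    """Exact gamete law of a parent over a map with <= 3 linked loci each.

    Two linked loci: parental haplotypes (1-r)/2 each, recombinants r/2 each.
    Three linked loci with segments r1, r2: double recombinants c*r1*r2/2 each,
    single-segment recombinants (r_i - c*r1*r2)/2, parentals
    (1 - r1 - r2 + c*r1*r2)/2.  Unlinked chromosomes segregate independently.
    """
    return _gamete_distribution(parent, gmap, _PUBLIC_MAX_LINKED)


def offspring_distribution(cross: CrossDesign) -> dict[DiplotypeKey, float]:
    """Convolve the two parental gamete laws into an offspring diplotype law."""
    mom = gamete_distribution(cross.mother, cross.map)
    dad = gamete_distribution(cross.father_or_self, cross.map)
    out: dict[DiplotypeKey, float] = {}
    for (h1, p1), (h2, p2) in product(mom.items(), dad.items()):
        key = diplotype_key(h1, h2)
        out[key] = out.get(key, 0.0) + p1 * p2
    return out


def double_recombinant_freq(r1: float, r2: float, c: float = 1.0) -> float:
    """Frequency of gametes with an exchange in both segments flanking a locus.

    For the catalog's average 6.9 cM interval split at the midpoint this is
    0.035 * 0.035 ~ 1/1000 chromosomes without interference, and lower with it.
    """
    for r in (r1, r2):
        if not 0.0 <= r <= 0.5:
            raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"coefficient of coincidence must be in [0, 1], got {c}")
    return c * r1 * r2


def balancer_purity(r1: float, r2: float, c: float = 1.0) -> float:
    """Double-recombination leakage of a TL used as a balancer.

    Returns P(a gamete carries the TL-derived allele at an interior locus |
    the gamete carries neither marker) = c*r1*r2 / (1 - r1 - r2 + 2*c*r1*r2),
    where r1, r2 are the fractions from each marker to the locus.  The
    complement is the purity of the unmarked chromosome class: it grows as the
    locus moves away from the interval midpoint, because the product r1*r2 is
    maximal at the midpoint for fixed r1 + r2.
    """
    double = double_recombinant_freq(r1, r2, c)
    if r1 + r2 > 1.0:
        raise ValueError("r1 + r2 must be <= 1")
    denom = 1.0 - r1 - r2 + 2.0 * double
    if denom <= 0.0:
        raise ValueError("no unmarked gametes under these parameters (denominator <= 0)")
    return double / denom


# ---------------------------------------------------------------------------
# seed fluorescence classes


@dataclass(frozen=True)
class SeedClassModel:
    """Dosage-coded fluorescence with optional adjacent-intensity confusion.

    Reporter dosage on the diploid embryo maps 0/1/2 copies to
    none/moderate/strong intensity per channel.  With probability ``epsilon`` a
    seed's intensity is misread as an adjacent class (the middle class splits
    the error evenly between its two neighbours); channels err independently.
    """

    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5], got {self.epsilon}")

    def intensity(self, dosage: int) -> str:
        return INTENSITIES[dosage]

    @property
    def confusion(self) -> dict[str, dict[str, float]]:
        """P(observed intensity | true intensity), per channel."""
        e = self.epsilon
        return {
            "none": {"none": 1 - e, "moderate": e, "strong": 0.0},
            "moderate": {"none": e / 2, "moderate": 1 - e, "strong": e / 2},
            "strong": {"none": 0.0, "moderate": e, "strong": 1 - e},
        }


SeedClass = tuple[str, str, bool, str]  # (green intensity, red intensity, viable, phenotype)

LethalSpec = Mapping[str, str]  # locus name -> allele that is lethal when homozygous


def marker_dosage(dip: DiplotypeKey, gmap: GeneticMap, channel: str) -> int:
    """Reporter copy number (0/1/2) of a channel's marker in a diplotype."""
    i = gmap.marker_index(channel)
    return sum(1 for hap in dip if hap[i] != "+")


def _is_lethal(dip: DiplotypeKey, gmap: GeneticMap, lethal: Iterable[LethalSpec]) -> bool:
    for spec in lethal:
        if all(
            dip[0][gmap.locus_index(name)] == allele and dip[1][gmap.locus_index(name)] == allele
            for name, allele in spec.items()
        ):
            return True
    return False


def seed_class_distribution(
    offspring: Mapping[DiplotypeKey, float],
    gmap: GeneticMap,
    model: SeedClassModel | None = None,
    lethal: Iterable[LethalSpec] = (),
    phenotype: Callable[[DiplotypeKey], str] | None = None,
) -> dict[SeedClass, float]:
    """Joint law of (green intensity, red intensity, viability, phenotype).

    Lethality acts on the true genotype after fertilisation but dead seeds
    remain observable (shriveled seeds are scored); misclassification acts on
    the observed intensities only.
    """
    model = model or SeedClassModel()
    lethal = tuple(lethal)
    conf = model.confusion
    out: dict[SeedClass, float] = {}
    for dip, p in offspring.items():
        g_true = model.intensity(marker_dosage(dip, gmap, "green"))
        r_true = model.intensity(marker_dosage(dip, gmap, "red"))
        viable = not _is_lethal(dip, gmap, lethal)
        phen = phenotype(dip) if phenotype is not None else ""
        for g_obs, pg in conf[g_true].items():
            if pg == 0.0:
                continue
            for r_obs, pr in conf[r_true].items():
                if pr == 0.0:
                    continue
                key = (g_obs, r_obs, viable, phen)
                out[key] = out.get(key, 0.0) + p * pg * pr
    return out


def _class_predicate(seed_class) -> Callable[[str, str], bool]:
    """Accept a (green, red) intensity pair or a named intensity group."""
    named: dict[str, Callable[[str, str], bool]] = {
        "fluorescent": lambda g, r: g != "none" or r != "none",
        "nonfluorescent": lambda g, r: g == "none" and r == "none",
        "moderate_both": lambda g, r: g == "moderate" and r == "moderate",
        "strong_both": lambda g, r: g == "strong" and r == "strong",
        "strong_red_moderate_green": lambda g, r: g == "moderate" and r == "strong",
        "strong_green_moderate_red": lambda g, r: g == "strong" and r == "moderate",
    }
    if isinstance(seed_class, str):
        if seed_class not in named:
            raise ValueError(f"unknown seed class {seed_class!r}; known: {sorted(named)}")
        return named[seed_class]
    g_want, r_want = seed_class
    return lambda g, r: g == g_want and r == r_want


def genotype_posterior(
    cross: CrossDesign,
    seed_class,
    model: SeedClassModel | None = None,
    lethal: Iterable[LethalSpec] = (),
) -> dict[DiplotypeKey, float]:
    """Bayes-invert the seed-class law: P(genotype | observed seed class).

    ``seed_class`` is either a named group ("fluorescent", "nonfluorescent",
    "moderate_both", "strong_both", ...) or an explicit (green, red) intensity
    pair.  Raises if the class has zero marginal probability.
    """
    model = model or SeedClassModel()
    pred = _class_predicate(seed_class)
    conf = model.confusion
    offspring = offspring_distribution(cross)
    joint: dict[DiplotypeKey, float] = {}
    total = 0.0
    for dip, p in offspring.items():
        g_true = model.intensity(marker_dosage(dip, cross.map, "green"))
        r_true = model.intensity(marker_dosage(dip, cross.map, "red"))
        p_class = sum(
            pg * pr
            for g_obs, pg in conf[g_true].items()
            for r_obs, pr in conf[r_true].items()
            if pred(g_obs, r_obs)
        )
        if p_class > 0.0:
            joint[dip] = joint.get(dip, 0.0) + p * p_class
            total += p * p_class
    if total <= 0.0:
        raise ValueError(f"seed class {seed_class!r} has zero probability under this cross")
    return {dip: p / total for dip, p in joint.items()}


# ---------------------------------------------------------------------------
# named schemes


def rescue_scheme(
    r1: float, r2: float, c: float = 1.0, tau: float = 0.0
) -> dict[str, float]:
    """T1 seed categories when selfing a lethal-mutation/TL heterozygote.

    The lethal allele sits in trans to the TL inside the marked interval
    (fractions ``r1``/``r2`` from each marker).  Floral-dip transformation
    hits each T1 seed independently at rate ``tau`` and rescues homozygous
    lethality.  Without recombination and without transformation the expected
    pattern is 3/4 fluorescent viable : 1/4 nonfluorescent dead; the only
    nonfluorescent viable seeds are then double-recombination heterozygotes
    (or, with transformation, rescued mutant homozygotes).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"transformation rate tau must be in [0, 1], got {tau}")
    loci = [
        Locus("G", alleles=("+", "G"), channel="green"),
        Locus("M", alleles=("+", "m")),
        Locus("R", alleles=("+", "R"), channel="red"),
    ]
    gmap = GeneticMap(loci, [r1, r2], c=c)
    cross = CrossDesign(gmap, (("G", "+", "R"), ("+", "m", "+")))
    offspring = offspring_distribution(cross)
    cats = {
        "fluorescent_viable": 0.0,
        "fluorescent_dead": 0.0,
        "nonfluorescent_dead": 0.0,
        "nonfluorescent_rescued_homozygote": 0.0,
        "nonfluorescent_double_recombinant_het": 0.0,
        "nonfluorescent_wildtype_homozygote": 0.0,
    }
    i_m = gmap.locus_index("M")
    for dip, p in offspring.items():
        fluor = marker_dosage(dip, gmap, "green") > 0 or marker_dosage(dip, gmap, "red") > 0
        mm = dip[0][i_m] == "m" and dip[1][i_m] == "m"
        if fluor:
            if mm:
                cats["fluorescent_viable"] += tau * p
                cats["fluorescent_dead"] += (1.0 - tau) * p
            else:
                cats["fluorescent_viable"] += p
        else:
            if mm:
                cats["nonfluorescent_rescued_homozygote"] += tau * p
                cats["nonfluorescent_dead"] += (1.0 - tau) * p
            elif "m" in (dip[0][i_m], dip[1][i_m]):
                cats["nonfluorescent_double_recombinant_het"] += p
            else:
                cats["nonfluorescent_wildtype_homozygote"] += p
    return cats


def separation_scheme(
    r_g1: float,
    r_12: float,
    r_2r: float,
    c: float = 1.0,
    selected: str = "strong_red_moderate_green",
    epsilon: float = 0.0,
    allele_labels: tuple[str, str] = ("m1", "m2"),
) -> dict[str, float]:
    """Recombinant-chromosome classes behind a dosage-selected F2 seed class.

    Two mutations m1, m2 sit between the markers in trans to the TL, with
    segment fractions marker-m1, m1-m2, m2-marker.  F2 seeds showing one
    marker at dosage 2 and the other at dosage 1 carry one intact TL
    chromosome and one single-marker recombinant chromosome; the returned
    distribution gives the alleles that recombinant chromosome carries at
    (m1, m2), conditional on the selected class.  For a short middle segment
    the mixed single-mutant classes are rare in proportion to its length.
    With ``epsilon`` > 0 misclassified non-single-recombinant seeds leak in
    and are reported under "other".
    """
    if selected not in ("strong_red_moderate_green", "strong_green_moderate_red"):
        raise ValueError(f"unknown selected class {selected!r}")
    m1, m2 = allele_labels
    loci = [
        Locus("G", alleles=("+", "G"), channel="green"),
        Locus("M1", alleles=("+", m1)),
        Locus("M2", alleles=("+", m2)),
        Locus("R", alleles=("+", "R"), channel="red"),
    ]
    gmap = GeneticMap(loci, [r_g1, r_12, r_2r], c=c)
    tl = ("G", "+", "+", "R")
    mut = ("+", m1, m2, "+")
    model = SeedClassModel(epsilon=epsilon)
    pred = _class_predicate(selected)
    conf = model.confusion
    gametes = _gamete_distribution((tl, mut), gmap, max_linked=4)
    joint: dict[str, float] = {}
    total = 0.0
    for (h1, p1), (h2, p2) in product(gametes.items(), gametes.items()):
        dip = diplotype_key(h1, h2)
        p = p1 * p2
        g_true = model.intensity(marker_dosage(dip, gmap, "green"))
        r_true = model.intensity(marker_dosage(dip, gmap, "red"))
        p_sel = sum(
            pg * pr
            for g_obs, pg in conf[g_true].items()
            for r_obs, pr in conf[r_true].items()
            if pred(g_obs, r_obs)
        )
        if p_sel == 0.0:
            continue
        # classify by the single-marker (recombinant) chromosome, if there is one
        marks = [(hap[0] != "+") + (hap[3] != "+") for hap in dip]
        if sorted(marks) == [1, 2]:
            rec = dip[marks.index(1)]
            label = f"{rec[1]} {rec[2]}"
        else:
            label = "other"
        joint[label] = joint.get(label, 0.0) + p * p_sel
        total += p * p_sel
    if total <= 0.0:
        raise ValueError(f"selected class {selected!r} has zero probability")
    return {k: v / total for k, v in joint.items()}


def sample_size(p_class: float, confidence: float = 0.95) -> int:
    """Smallest n with P(at least one seed of the class) >= confidence.

    Solves 1 - (1 - p)^n >= confidence, the planning rule for how many seeds
    to screen when the target class (e.g. a rare recombinant) has frequency p.
    """
    if not 0.0 < p_class <= 1.0:
        raise ValueError(f"p_class must be in (0, 1], got {p_class}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if p_class >= 1.0 - 1e-15:
        return 1
    n = math.log(1.0 - confidence) / math.log(1.0 - p_class)
    n_int = math.ceil(n - 1e-9)
    return max(n_int, 1)
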