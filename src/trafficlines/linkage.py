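"""Recombination-fraction estimation from fluorescence-classed testcross counts.

A traffic line is built by crossing a plant that carries linked ``pNAP::eGFP``
and ``pNAP::DsRed`` insertions to an unmarked tester.  When the two markers sit
on opposite homologs of the testcross parent (repulsion phase) the single-colour
seed classes are parental and the double-fluorescent and nonfluorescent classes
are recombinant; in coupling phase the roles swap.  The recombination fraction
is the pooled recombinant proportion, and map distance follows the direct rule
cM = 100 r used throughout the catalog (Haldane and Kosambi conversions are
provided for simulator calibration only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

from scipy import stats

Phase = Literal["repulsion", "coupling"]

__all__ = [
    "CountTable",
    "RecombinationEstimate",
    "RateEstimate",
    "estimate_r",
    "rate",
    "map_function",
    "compare_lines",
    "distortion_tests",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching the catalog's printed values.

    Python's builtin ``round`` is banker's rounding; the printed tables round
    half up (e.g. 5.65 -> 5.7), so comparisons against printed numbers use this.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountTable:
    """Four fluorescence-classed seed counts from a testcross.

    Classes are dsRed-only, GFP-only, double-fluorescent, and nonfluorescent.
    ``phase`` records whether the markers were in trans (repulsion, the catalog
    design) or in cis (coupling) in the heterozygous parent.
    """

    n_red: int
    n_green: int
    n_both: int
    n_none: int
    phase: Phase = "repulsion"

    def __post_init__(self) -> None:
        for name in ("n_red", "n_green", "n_both", "n_none"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.phase not in ("repulsion", "coupling"):
            raise ValueError(f"phase must be 'repulsion' or 'coupling', got {self.phase!r}")

    @property
    def total(self) -> int:
        """Class-sum sample size N (never the printed total column)."""
        return self.n_red + self.n_green + self.n_both + self.n_none

    @property
    def recombinant(self) -> int:
        if self.phase == "repulsion":
            return self.n_both + self.n_none
        return self.n_red + self.n_green

    @property
    def parental(self) -> int:
        return self.total - self.recombinant

    @property
    def parental_pair(self) -> tuple[int, int]:
        if self.phase == "repulsion":
            return (self.n_red, self.n_green)
        return (self.n_both, self.n_none)

    @property
    def recombinant_pair(self) -> tuple[int, int]:
        if self.phase == "repulsion":
            return (self.n_both, self.n_none)
        return (self.n_red, self.n_green)


@dataclass(frozen=True)
class RecombinationEstimate:
    """Point estimate of the recombination fraction with a Wilson interval.

    ``r_hat`` is the raw recombinant proportion and may exceed 0.5 (a strong
    hint of mis-specified phase; ``phase_suspect`` is then set rather than
    truncating).  ``cM`` is 100*r_hat rounded half-up to one decimal, the
    catalog's printing convention.
    """

    r_hat: float
    cM: float
    se: float
    ci: tuple[float, float]
    n: int
    level: float = 0.95
    ci_method: str = "wilson"
    phase_suspect: bool = field(default=False)


@dataclass(frozen=True)
class RateEstimate:
    """Recombination rate over a physical interval, in cM/Mb at one decimal."""

    cM_per_Mb: float
    interval_Mb: float


def estimate_r(counts: CountTable, level: float = 0.95) -> RecombinationEstimate:
    """Estimate the recombination fraction from a testcross count table.

    Recombinant classes are pooled by phase; the confidence interval is the
    Wilson score interval, which behaves well at the small recombinant counts
    typical of short intervals.
    """
    n = counts.total
    if n < 1:
        raise ValueError("count table is empty (N = 0)")
    r_count = counts.recombinant
    r_hat = r_count / n
    se = math.sqrt(r_hat * (1.0 - r_hat) / n)
    ci = stats.binomtest(r_count, n).proportion_ci(confidence_level=level, method="wilson")
    return RecombinationEstimate(
        r_hat=r_hat,
        cM=round_half_up(100.0 * r_hat, 1),
        se=se,
        ci=(float(ci.low), float(ci.high)),
        n=n,
        level=level,
        phase_suspect=r_hat > 0.5,
    )


def rate(estimate: RecombinationEstimate, interval_nt: int) -> RateEstimate:
    """Convert a map distance to cM/Mb over a physical interval.

    The rate is computed from the cM value already rounded to one decimal (the
    catalog's convention: line 3.49 prints 16.5 = 2.0/0.121308 Mb, not the
    16.8 that the unrounded distance would give).
    """
    if interval_nt <= 0:
        raise ValueError(f"interval_nt must be positive, got {interval_nt}")
    mb = interval_nt / 1e6
    return RateEstimate(cM_per_Mb=round_half_up(estimate.cM / mb, 1), interval_Mb=mb)


def map_function(r: float, rule: str = "direct") -> float:
    """Map a recombination fraction to centimorgans.

    ``direct`` (cM = 100 r) is the catalog convention; ``haldane`` and
    ``kosambi`` exist for converting fractions to Morgans when calibrating the
    meiosis simulator.
    """
    if rule == "direct":
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"direct rule needs 0 <= r <= 1, got {r}")
        return 100.0 * r
    if not 0.0 <= r < 0.5:
        raise ValueError(f"{rule} map function needs 0 <= r < 0.5, got {r}")
    if rule == "haldane":
        return -50.0 * math.log(1.0 - 2.0 * r)
    if rule == "kosambi":
        return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    raise ValueError(f"unknown map function rule {rule!r}")


@dataclass(frozen=True)
class LineComparison:
    odds_ratio: float
    p_value: float
    method: str = "fisher-exact"


def compare_lines(a: CountTable, b: CountTable) -> LineComparison:
    """Two-sided Fisher exact test of recombinant proportions between two lines.

    Motivated by between-line rate differences over the same physical region
    (e.g. a marker insertion associated with a small rearrangement that
    suppresses recombination locally).
    """
    if a.total < 1 or b.total < 1:
        raise ValueError("both count tables must have N >= 1")
    table = [[a.recombinant, a.parental], [b.recombinant, b.parental]]
    res = stats.fisher_exact(table, alternative="two-sided")
    return LineComparison(odds_ratio=float(res.statistic), p_value=float(res.pvalue))


@dataclass(frozen=True)
class DistortionResult:
    """Exact two-sided binomial tests of 1:1 within each class pair.

    A pair with zero total is not testable and reports ``None``.  The
    recombinant-pair test is the diagnostic for asymmetric recombination on the
    two sides of an interval (e.g. 18 vs 6 recombinants flanking a mutation).
    """

    parental_1to1_p: float | None
    recombinant_1to1_p: float | None


def distortion_tests(counts: CountTable) -> DistortionResult:
    if counts.total < 1:
        raise ValueError("count table is empty (N = 0)")

    def _pair_p(pair: tuple[int, int]) -> float | None:
        tot = pair[0] + pair[1]
        if tot == 0:
            return None
        return float(stats.binomtest(pair[0], tot, 0.5, alternative="two-sided").pvalue)

    return DistortionResult(
        parental_1to1_p=_pair_p(counts.parental_pair),
        recombinant_1to1_p=_pair_p(counts.recombinant_pair),
    )
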