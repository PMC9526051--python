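"""The short-interval traffic-line catalog: 162 marker-pair stocks.

Each traffic line carries a ``pNAP::eGFP`` (CG) and a ``pNAP::DsRed`` (CR)
T-DNA insertion in cis on one of the five Arabidopsis chromosomes, with the
insertion coordinates on the Col reference, the interval length, the four
testcross seed-class counts used to measure the recombination distance, and the
printed cM and cM/Mb values.  The packaged TSV is a verbatim transcription of
the published table, inconsistencies included; ``check_integrity`` recomputes
every derived column and flags the rows where the print contradicts itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from statistics import mean
from typing import Iterable, Literal

from .linkage import CountTable, estimate_r, rate, round_half_up

Channel = Literal["green", "red"]
FlagKind = Literal[
    "length_mismatch", "total_mismatch", "cM_mismatch", "rate_mismatch", "duplicate_counts"
]

CM_TOL = 0.1  # printed-vs-recomputed tolerance, the table mixes rounding conventions
RATE_TOL = 0.2

__all__ = [
    "MarkerInsertion",
    "TrafficLine",
    "CatalogFlag",
    "CoverageSummary",
    "packaged_catalog_path",
    "load_catalog",
    "check_integrity",
    "find_spanning",
    "coverage_summary",
    "export_bed",
    "read_bed",
]


@dataclass(frozen=True)
class MarkerInsertion:
    """A sequenced fluorescent-reporter T-DNA insertion on the Col reference."""

    marker_id: str
    chromosome: int
    position_bp: int

    def __post_init__(self) -> None:
        if not (self.marker_id.startswith("CG") or self.marker_id.startswith("CR")):
            raise ValueError(
                f"unknown marker prefix in {self.marker_id!r}: expected CG (eGFP) or CR (DsRed)"
            )
        if not 1 <= self.chromosome <= 5:
            raise ValueError(f"chromosome must be 1-5, got {self.chromosome}")
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")

    @property
    def channel(self) -> Channel:
        return "green" if self.marker_id.startswith("CG") else "red"


@dataclass(frozen=True)
class TrafficLine:
    """One catalog row: a linked CG/CR marker pair and its testcross data."""

    abrc_id: str
    line_id: str
    upper: MarkerInsertion
    lower: MarkerInsertion
    interval_nt: int
    counts: CountTable
    printed_total: int
    printed_cM: float
    printed_rate: float

    def __post_init__(self) -> None:
        if self.upper.chromosome != self.lower.chromosome:
            raise ValueError(f"line {self.line_id}: markers on different chromosomes")
        chrom_part = self.line_id.split(".")[0]
        if str(self.upper.chromosome) != chrom_part:
            raise ValueError(
                f"line {self.line_id}: chromosome {self.upper.chromosome} does not match line id"
            )
        if not self.upper.position_bp < self.lower.position_bp:
            raise ValueError(f"line {self.line_id}: upper marker is not above lower marker")
        if {self.upper.channel, self.lower.channel} != {"green", "red"}:
            raise ValueError(f"line {self.line_id}: needs one green and one red marker")
        # interval_nt disagreeing with the position difference is a flag, not an error

    @property
    def chromosome(self) -> int:
        return self.upper.chromosome

    def spans(self, position_bp: int) -> bool:
        """Closed-interval containment: marker positions themselves count."""
        return self.upper.position_bp <= position_bp <= self.lower.position_bp


@dataclass(frozen=True)
class CatalogFlag:
    line_id: str
    flag_kind: FlagKind
    detail: str


_COLUMNS = [
    "abrc_id", "line_id", "upper_marker", "upper_pos", "lower_marker", "lower_pos",
    "interval_nt", "n_red", "n_green", "n_both", "n_none", "printed_total",
    "printed_cM", "printed_rate",
]


def packaged_catalog_path() -> Path:
    """Path of the catalog TSV shipped inside the package."""
    return Path(resources.files("trafficlines").joinpath("data/catalog.tsv"))


def _parse_int(raw: str, line_no: int, column: str) -> int:
    try:
        return int(raw.replace(",", ""))
    except ValueError:
        raise ValueError(f"row {line_no}, column {column!r}: cannot parse integer from {raw!r}")


def _parse_float(raw: str, line_no: int, column: str) -> float:
    try:
        return float(raw.replace(",", ""))
    except ValueError:
        raise ValueError(f"row {line_no}, column {column!r}: cannot parse number from {raw!r}")


def load_catalog(path: str | Path | None = None) -> list[TrafficLine]:
    """Load a catalog TSV; with no argument, the packaged published table.

    Numeric columns may carry comma thousands separators (the published table
    prints them); line ids are kept as strings because trailing zeros are
    significant ("1.30" and "1.3" would be different lines).
    """
    path = packaged_catalog_path() if path is None else Path(path)
    lines: list[TrafficLine] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != _COLUMNS:
            raise ValueError(
                f"{path}: expected header columns {_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            if any(row[c] is None for c in _COLUMNS):
                raise ValueError(f"{path}: row {i} is malformed (wrong column count)")
            chrom_part = row["line_id"].split(".")[0]
            try:
                chromosome = int(chrom_part)
            except ValueError:
                raise ValueError(f"row {i}, column 'line_id': bad chromosome in {row['line_id']!r}")
            upper = MarkerInsertion(
                row["upper_marker"], chromosome, _parse_int(row["upper_pos"], i, "upper_pos")
            )
            lower = MarkerInsertion(
                row["lower_marker"], chromosome, _parse_int(row["lower_pos"], i, "lower_pos")
            )
            counts = CountTable(
                n_red=_parse_int(row["n_red"], i, "n_red"),
                n_green=_parse_int(row["n_green"], i, "n_green"),
                n_both=_parse_int(row["n_both"], i, "n_both"),
                n_none=_parse_int(row["n_none"], i, "n_none"),
                phase="repulsion",
            )
            lines.append(
                TrafficLine(
                    abrc_id=row["abrc_id"],
                    line_id=row["line_id"],
                    upper=upper,
                    lower=lower,
                    interval_nt=_parse_int(row["interval_nt"], i, "interval_nt"),
                    counts=counts,
                    printed_total=_parse_int(row["printed_total"], i, "printed_total"),
                    printed_cM=_parse_float(row["printed_cM"], i, "printed_cM"),
                    printed_rate=_parse_float(row["printed_rate"], i, "printed_rate"),
                )
            )
    return lines


def recomputed_cM(line: TrafficLine) -> float:
    """Map distance recomputed from the class-sum counts, 1 dp half-up."""
    return estimate_r(line.counts).cM


def recomputed_rate(line: TrafficLine) -> float:
    """cM/Mb recomputed from the rounded cM over the printed interval length."""
    return rate(estimate_r(line.counts), line.interval_nt).cM_per_Mb


def check_integrity(catalog: Iterable[TrafficLine]) -> list[CatalogFlag]:
    """Recompute every derived column and report internal contradictions.

    Sample size for recomputation is always the sum of the four class counts:
    some printed totals contradict the class sum, and where they do the printed
    cM is consistent with the class sum, not the total.
    """
    flags: list[CatalogFlag] = []
    seen_counts: dict[tuple[int, int, int, int], str] = {}
    for line in catalog:
        pos_diff = line.lower.position_bp - line.upper.position_bp
        if line.interval_nt != pos_diff:
            flags.append(
                CatalogFlag(
                    line.line_id,
                    "length_mismatch",
                    f"printed interval {line.interval_nt} nt vs position difference {pos_diff} nt",
                )
            )
        class_sum = line.counts.total
        if line.printed_total != class_sum:
            flags.append(
                CatalogFlag(
                    line.line_id,
                    "total_mismatch",
                    f"printed total {line.printed_total} vs class sum {class_sum}",
                )
            )
        cm = recomputed_cM(line)
        if abs(line.printed_cM - cm) > CM_TOL + 1e-9:
            flags.append(
                CatalogFlag(
                    line.line_id,
                    "cM_mismatch",
                    f"printed {line.printed_cM} cM vs recomputed {cm} cM (N = class sum {class_sum})",
                )
            )
        rt = recomputed_rate(line)
        if abs(line.printed_rate - rt) > RATE_TOL + 1e-9:
            flags.append(
                CatalogFlag(
                    line.line_id,
                    "rate_mismatch",
                    f"printed {line.printed_rate} cM/Mb vs recomputed {rt} cM/Mb",
                )
            )
        key = (line.counts.n_red, line.counts.n_green, line.counts.n_both, line.counts.n_none)
        if key in seen_counts:
            flags.append(
                CatalogFlag(
                    line.line_id,
                    "duplicate_counts",
                    f"count vector {key} identical to line {seen_counts[key]}",
                )
            )
        else:
            seen_counts[key] = line.line_id
    return flags


def find_spanning(
    catalog: Iterable[TrafficLine], chromosome: int, position_bp: int
) -> list[TrafficLine]:
    """All lines whose marked interval contains the position, shortest first.

    Containment is closed at both ends (a position equal to a marker position
    is spanned).  Useful for picking a balancer over a locus of interest.
    """
    if not 1 <= chromosome <= 5:
        raise ValueError(f"chromosome must be 1-5, got {chromosome}")
    hits = [ln for ln in catalog if ln.chromosome == chromosome and ln.spans(position_bp)]
    return sorted(hits, key=lambda ln: ln.interval_nt)


@dataclass(frozen=True)
class CoverageSummary:
    """Unweighted catalog averages plus uncovered gaps per chromosome.

    Two candidate genome-wide rate summaries are reported because they
    disagree: the column mean of the printed per-line cM/Mb values and the
    ratio of mean cM to mean Mb.  ``gaps`` lists the maximal regions between
    consecutive merged marked intervals on each chromosome (regions no line
    spans), as closed bp intervals.
    """

    n_lines: int
    mean_interval_Mb: float
    mean_cM: float
    mean_interval_Mb_1dp: float
    mean_cM_1dp: float
    mean_printed_rate: float
    ratio_of_means_rate: float
    gaps: dict[int, list[tuple[int, int]]]
    rate_note: str = (
        "genome-wide cM/Mb is ambiguous: the column mean of printed rates and the "
        "ratio mean-cM/mean-Mb disagree; both are reported"
    )


def coverage_summary(catalog: list[TrafficLine]) -> CoverageSummary:
    if not catalog:
        raise ValueError("catalog is empty")
    intervals_mb = [ln.interval_nt / 1e6 for ln in catalog]
    cms = [ln.printed_cM for ln in catalog]
    gaps: dict[int, list[tuple[int, int]]] = {}
    for chrom in sorted({ln.chromosome for ln in catalog}):
        spans = sorted(
            (ln.upper.position_bp, ln.lower.position_bp)
            for ln in catalog
            if ln.chromosome == chrom
        )
        merged: list[list[int]] = []
        for start, end in spans:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        gaps[chrom] = [
            (merged[i][1] + 1, merged[i + 1][0] - 1) for i in range(len(merged) - 1)
        ]
    return CoverageSummary(
        n_lines=len(catalog),
        mean_interval_Mb=mean(intervals_mb),
        mean_cM=mean(cms),
        mean_interval_Mb_1dp=round_half_up(mean(intervals_mb), 1),
        mean_cM_1dp=round_half_up(mean(cms), 1),
        mean_printed_rate=mean(ln.printed_rate for ln in catalog),
        ratio_of_means_rate=sum(cms) / sum(intervals_mb),
        gaps=gaps,
    )


def export_bed(catalog: Iterable[TrafficLine], path: str | Path) -> None:
    """Write the marked intervals as BED (0-based half-open).

    name = line id, score = printed cM x 10 truncated to an integer.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in catalog:
            fh.write(
                f"Chr{line.chromosome}\t{line.upper.position_bp - 1}\t"
                f"{line.lower.position_bp}\t{line.line_id}\t{int(line.printed_cM * 10)}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int]]:
    """Read back a 5-column BED written by export_bed."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw:
                continue
            chrom, start, end, name, score = raw.split("\t")
            records.append((chrom, int(start), int(end), name, int(score)))
    return records
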