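"""Mask-and-recompute analysis: how much do candidate introgressed regions
contribute to genome-wide diversity?

"Removing" a region set means dropping the SNPs inside it and shrinking the
accessibility mask to the genomic complement, so per-bp denominators
(effective sites) contract correspondingly; the standard windowed summary is
then recomputed on what remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .diversity import DiversitySummary
from .io_core import RegionSet, VariantMatrix


@dataclass
class ReductionReport:
    """Before/after contrast of one genome-wide diversity statistic."""

    statistic: str  # "pi" or "he"
    value_before: float
    value_after: float
    percent_reduction: float | None  # 100 * (before - after) / before
    masked_fraction: float


def mask_regions(
    matrices: Mapping[str, VariantMatrix],
    regions: RegionSet,
    genome: Mapping[str, int],
) -> tuple[dict[str, VariantMatrix], RegionSet]:
    """Drop SNPs inside ``regions``; return the reduced matrices and the
    genomic complement to use as the accessibility mask downstream."""
    complement = regions.complement(genome)
    if complement.total_length == 0:
        raise ValueError("regions cover the entire genome; nothing left to analyze")
    out = {}
    for chrom, vm in matrices.items():
        inside = regions.contains(chrom, vm.positions - 1)
        out[chrom] = vm.take_sites(~inside)
    return out, complement


def percent_reduction(before: float, after: float) -> float | None:
    """100 * (before - after) / before; None when the baseline is zero."""
    if before == 0:
        return None
    return 100.0 * (before - after) / before


def reduction_summary(
    before: DiversitySummary,
    after: DiversitySummary,
    masked_fraction: float,
) -> list[ReductionReport]:
    """Percent reduction of pi and H_E between two summaries of one group."""
    if before.group != after.group:
        raise ValueError(
            f"summaries are for different groups: {before.group!r} vs {after.group!r}"
        )
    reports = []
    for stat in ("pi", "he"):
        b = getattr(before, stat)
        a = getattr(after, stat)
        reports.append(
            ReductionReport(
                statistic=stat,
                value_before=b,
                value_after=a,
                percent_reduction=percent_reduction(b, a),
                masked_fraction=masked_fraction,
            )
        )
    return reports


def coverage_fraction(regions: RegionSet, genome: Mapping[str, int] | int) -> float:
    """Percent of the genome covered by ``regions`` (two decimals in reports).

    ``genome`` may be a per-chromosome length mapping (bounds are then
    validated) or a total length in bp.
    """
    if isinstance(genome, Mapping):
        total = sum(genome.values())
        for chrom, start, end in regions.intervals:
            if chrom not in genome or end > genome[chrom]:
                raise ValueError(f"region {chrom}:{start}-{end} outside genome bounds")
    else:
        total = int(genome)
        if regions.total_length > total:
            raise ValueError("regions exceed the stated genome length")
    if total <= 0:
        raise ValueError("genome length must be positive")
    return 100.0 * regions.total_length / total
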