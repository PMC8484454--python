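"""Core containers and I/O for genotype matrices, intervals, and maps.

All internal coordinates are 0-based half-open; VCF positions (1-based) are
converted on read and back on write, BED is written natively. Genotypes are
stored as per-site ALT-allele dosages (0, 1, 2) with -1 for missing calls;
phase is discarded because every downstream statistic is frequency-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantMatrix:
    """Biallelic-SNP genotype matrix for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int
        1-based site coordinates, strictly increasing.
    genotypes : ndarray of shape (n_sites, n_samples)
        ALT-allele dosage per diploid sample; ``-1`` marks a missing call.
    sample_ids : list of str
        Sample identifiers, column order of ``genotypes``.
    ref, alt : ndarray of str
        Per-site REF/ALT alleles.
    """

    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str]
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.chrom}: positions must be strictly increasing")
        if self.genotypes.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError(
                f"{self.chrom}: genotype matrix shape {self.genotypes.shape} does not "
                f"match {len(self.positions)} sites x {len(self.sample_ids)} samples"
            )
        bad = (self.genotypes > 2) | (self.genotypes < MISSING)
        if np.any(bad):
            raise ValueError(f"{self.chrom}: dosages must be in {{-1, 0, 1, 2}}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def take_sites(self, keep: np.ndarray) -> "VariantMatrix":
        """Return a new matrix restricted to sites selected by ``keep``."""
        return VariantMatrix(
            chrom=self.chrom,
            positions=self.positions[keep],
            genotypes=self.genotypes[keep],
            sample_ids=list(self.sample_ids),
            ref=self.ref[keep],
            alt=self.alt[keep],
        )


@dataclass
class PopulationMap:
    """Sample-to-group assignment with ordered group labels."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.groups: dict[str, int] = {}
        for g in self.assignments.values():
            self.groups[g] = self.groups.get(g, 0) + 1

    def samples_of(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.assignments.items() if g == group]

    def size(self, group: str) -> int:
        return self.groups[group]

    def require(self, samples: Iterable[str]) -> None:
        absent = [s for s in samples if s not in self.assignments]
        if absent:
            raise KeyError(f"samples missing from population map: {absent}")


@dataclass(frozen=True)
class Window:
    """Half-open genomic window [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """Normalized set of half-open genomic intervals.

    Intervals are sorted per chromosome and any overlapping or book-ended
    pairs are merged on construction, so ``total_length`` is the number of
    distinct covered bases.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if not (0 <= start < end):
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(by_chrom):
            merged: list[list[int]] = []
            for start, end in sorted(by_chrom[chrom]):
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            arr = np.array(merged, dtype=np.int64)
            self._by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, (starts, ends) in self._by_chrom.items():
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    @property
    def total_length(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends in self._by_chrom.values())
        )

    def __len__(self) -> int:
        return sum(len(starts) for starts, _ in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __or__(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(self.intervals + other.intervals)

    def union(self, other: "RegionSet") -> "RegionSet":
        return self | other

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) on ``chrom`` covered by this set."""
        if chrom not in self._by_chrom:
            return 0
        starts, ends = self._by_chrom[chrom]
        lo = np.clip(starts, start, end)
        hi = np.clip(ends, start, end)
        return int(np.maximum(hi - lo, 0).sum())

    def contains(self, chrom: str, coords: np.ndarray) -> np.ndarray:
        """Membership of 0-based coordinates in the covered set."""
        coords = np.asarray(coords, dtype=np.int64)
        if chrom not in self._by_chrom:
            return np.zeros(len(coords), dtype=bool)
        starts, ends = self._by_chrom[chrom]
        idx = np.searchsorted(starts, coords, side="right") - 1
        inside = idx >= 0
        inside[inside] &= coords[inside] < ends[idx[inside]]
        return inside

    def complement(self, genome: Mapping[str, int]) -> "RegionSet":
        """Uncovered intervals within genome bounds."""
        out: list[tuple[str, int, int]] = []
        for chrom, length in genome.items():
            cursor = 0
            if chrom in self._by_chrom:
                starts, ends = self._by_chrom[chrom]
                for s, e in zip(starts, ends):
                    if s > length:
                        raise ValueError(f"interval beyond {chrom} length {length}")
                    if s > cursor:
                        out.append((chrom, cursor, int(min(s, length))))
                    cursor = max(cursor, int(e))
            if cursor < length:
                out.append((chrom, cursor, length))
        return RegionSet(out)


@dataclass
class GeneTable:
    """Gene intervals (half-open) with identifiers.

    ``df`` has columns ``gene_id``, ``chrom``, ``start``, ``end``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if (self.df["end"] <= self.df["start"]).any():
            raise ValueError("gene table contains empty or inverted intervals")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in gene table")

    @property
    def n_genes(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# VCF


def read_variants(
    path: str, samples: Sequence[str] | None = None
) -> tuple[dict[str, VariantMatrix], Counter]:
    """Read biallelic SNPs from a VCF into per-chromosome matrices.

    Multiallelic records and non-SNPs are skipped and tallied in the returned
    counter under ``multiallelic``, ``indel`` and ``other``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    header_samples = list(vcf.samples)
    if samples is not None:
        absent = [s for s in samples if s not in header_samples]
        if absent:
            raise KeyError(f"samples not in VCF header: {absent}")
        vcf.close()
        vcf = VCF(path, samples=list(samples))
    sample_ids = list(vcf.samples)

    skipped: Counter = Counter()
    per_chrom: dict[str, dict[str, list]] = {}
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dosage_of = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if v.is_indel:
            skipped["indel"] += 1
            continue
        if not v.is_snp:
            skipped["other"] += 1
            continue
        rec = per_chrom.setdefault(
            v.CHROM, {"pos": [], "gt": [], "ref": [], "alt": []}
        )
        rec["pos"].append(v.POS)
        rec["gt"].append(dosage_of[np.asarray(v.gt_types)])
        rec["ref"].append(v.REF)
        rec["alt"].append(v.ALT[0])
    vcf.close()

    matrices = {
        chrom: VariantMatrix(
            chrom=chrom,
            positions=np.array(rec["pos"], dtype=np.int64),
            genotypes=np.array(rec["gt"], dtype=np.int8),
            sample_ids=sample_ids,
            ref=np.array(rec["ref"]),
            alt=np.array(rec["alt"]),
        )
        for chrom, rec in per_chrom.items()
    }
    return matrices, skipped


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrices: Mapping[str, VariantMatrix], path: str) -> None:
    """Write matrices as an uncompressed VCF with GT-only genotype fields."""
    chroms = list(matrices)
    sample_ids = matrices[chroms[0]].sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germflow\n")
        for chrom in chroms:
            vm = matrices[chrom]
            length = int(vm.positions[-1]) if vm.n_sites else 0
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for chrom in chroms:
            vm = matrices[chrom]
            if vm.sample_ids != sample_ids:
                raise ValueError("all chromosomes must share one sample panel")
            for i in range(vm.n_sites):
                gts = "\t".join(_GT_STRINGS[int(g)] for g in vm.genotypes[i])
                fh.write(
                    f"{chrom}\t{vm.positions[i]}\t.\t{vm.ref[i]}\t{vm.alt[i]}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )


# ---------------------------------------------------------------------------
# thinning and windows


def thin_variants(vm: VariantMatrix, min_gap: int) -> VariantMatrix:
    """Greedy 5'->3' LD thinning: drop sites closer than ``min_gap`` bp to
    the last retained site."""
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if min_gap == 0 or vm.n_sites == 0:
        return vm
    keep = np.zeros(vm.n_sites, dtype=bool)
    last = -np.inf
    for i, pos in enumerate(vm.positions):
        if pos - last >= min_gap:
            keep[i] = True
            last = pos
    return vm.take_sites(keep)


def iter_windows(
    chrom_length: int, size: int, step: int, chrom: str = ""
) -> list[Window]:
    """Sliding windows [0, size), [step, step+size), ... truncated at the
    chromosome end; the terminal short window is emitted."""
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    return [
        Window(chrom, start, min(start + size, chrom_length))
        for start in range(0, chrom_length, step)
    ]


# ---------------------------------------------------------------------------
# tabular formats


def write_regions_bed(rs: RegionSet, path: str, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for chrom, start, end in rs.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_regions_bed(path: str) -> RegionSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
    return RegionSet(intervals)


def read_genes(path: str, fmt: str | None = None) -> GeneTable:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive, converted; only ``gene`` features are kept)."""
    if fmt is None:
        lower = path.lower()
        fmt = "gff" if lower.endswith((".gff", ".gff3")) else "bed"
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "bed":
                    if len(parts) < 3:
                        raise ValueError("expected >=3 BED columns")
                    gene_id = parts[3] if len(parts) > 3 else f"gene{lineno}"
                    records.append((gene_id, parts[0], int(parts[1]), int(parts[2])))
                else:
                    if len(parts) < 9:
                        raise ValueError("expected 9 GFF columns")
                    if parts[2] != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    gene_id = attrs.get("ID", f"gene{lineno}")
                    records.append((gene_id, parts[0], int(parts[3]) - 1, int(parts[4])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line") from exc
    df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end"])
    return GeneTable(df)


def read_popmap(path: str) -> PopulationMap:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            sample, group = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = group
    return PopulationMap(assignments)


def write_popmap(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, group in pm.assignments.items():
            fh.write(f"{sample}\t{group}\n")
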