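"""Four-taxon introgression scans: Patterson's D, block jackknife, f_d.

Sites are polarized against an outgroup treated as a sampled population: the
ancestral allele is the outgroup allele only when its frequency reaches the
fixation threshold (default 0.9); other sites are excluded.

Sign convention: genome-wide D is reported in the orientation where a
*negative* value indicates excess derived-allele sharing between P2 and P3
(``convention="p2p3-negative"``, the default); ``"textbook"`` gives the usual
(ABBA - BABA)/(ABBA + BABA). Windowed f_d always uses the textbook
orientation internally — windows whose windowed D is <= 0 get f_d = 0, so
the top-quantile threshold has a defined support.

f_d follows the dynamic-donor form of Martin, Davey & Jiggins (2015): the
denominator replaces both P2 and P3 by the higher-frequency of the two at
each site, bounding the windowed admixture fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import PopulationMap, RegionSet, VariantMatrix, Window, iter_windows
from .diversity import group_site_counts, _cumsum0, _window_bounds

P2P3_NEGATIVE = "p2p3-negative"


@dataclass(frozen=True)
class Quartet:
    """Ordered four-population test (P1, P2, P3; outgroup)."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        labels = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(labels)) != 4:
            raise ValueError(f"quartet labels must be distinct: {labels}")

    def swapped(self) -> "Quartet":
        return Quartet(self.p1, self.p3, self.p2, self.outgroup)


@dataclass(frozen=True)
class MigrationEventSpec:
    """A hypothesized donor->recipient gene-flow event and the quartet used
    to localize it (donor = P3, recipient = P2)."""

    event_id: str
    donor: str
    recipient: str
    quartet: Quartet

    def __post_init__(self) -> None:
        if self.quartet.p3 != self.donor or self.quartet.p2 != self.recipient:
            raise ValueError(
                f"{self.event_id}: donor must be quartet P3 and recipient P2"
            )


@dataclass
class PolarizedSites:
    """Derived-allele frequencies (w, x, y) = (P1, P2, P3) at usable sites."""

    chrom: str
    positions: np.ndarray  # 1-based, usable sites only
    w: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_excluded_outgroup: int
    n_excluded_missing: int


@dataclass
class DStatResult:
    quartet: Quartet
    d: float
    jackknife_se: float | None
    z: float | None
    n_sites_used: int
    block_count: int
    sum_abba: float
    sum_baba: float
    convention: str = P2P3_NEGATIVE


@dataclass
class FdWindowRecord:
    window: Window
    fd: float
    snp_count: int
    window_d_sign: int  # sign of the textbook-orientation windowed D
    excluded: bool


@dataclass
class CandidateRegionSet:
    event_id: str
    regions: RegionSet
    threshold: float
    genome_fraction: float
    n_windows_selected: int


# ---------------------------------------------------------------------------
# polarization


def polarize(
    vm: VariantMatrix,
    popmap: PopulationMap,
    quartet: Quartet,
    outgroup_fix_threshold: float = 0.9,
) -> PolarizedSites:
    """Polarize sites by the outgroup and return derived-allele frequencies.

    Excluded: sites where the outgroup has no called allele or is not fixed
    to the threshold, and sites where any of P1/P2/P3 has no called allele.
    """
    counts = {}
    for g in (quartet.p1, quartet.p2, quartet.p3, quartet.outgroup):
        idx = vm.sample_indices(popmap.samples_of(g))
        counts[g] = group_site_counts(vm, idx)
    n_o, d_o = counts[quartet.outgroup]
    with np.errstate(invalid="ignore"):
        f_alt = np.where(n_o > 0, d_o / np.maximum(n_o, 1), np.nan)
    anc_ref = (n_o > 0) & (1.0 - f_alt >= outgroup_fix_threshold)
    anc_alt = (n_o > 0) & (f_alt >= outgroup_fix_threshold)
    polarizable = anc_ref | anc_alt
    n_excl_out = int(vm.n_sites - polarizable.sum())

    called = np.ones(vm.n_sites, dtype=bool)
    freqs = {}
    for g in (quartet.p1, quartet.p2, quartet.p3):
        n, d = counts[g]
        called &= n > 0
        p = np.zeros(vm.n_sites)
        np.divide(d, n, out=p, where=n > 0)
        freqs[g] = p
    usable = polarizable & called
    n_excl_missing = int((polarizable & ~called).sum())

    def derived(p):
        return np.where(anc_alt, 1.0 - p, p)[usable]

    return PolarizedSites(
        chrom=vm.chrom,
        positions=vm.positions[usable],
        w=derived(freqs[quartet.p1]),
        x=derived(freqs[quartet.p2]),
        y=derived(freqs[quartet.p3]),
        n_excluded_outgroup=n_excl_out,
        n_excluded_missing=n_excl_missing,
    )


def site_patterns(ps: PolarizedSites) -> tuple[np.ndarray, np.ndarray]:
    """Per-site frequency-weighted ABBA and BABA (outgroup ancestral)."""
    abba = (1.0 - ps.w) * ps.x * ps.y
    baba = ps.w * (1.0 - ps.x) * ps.y
    return abba, baba


# ---------------------------------------------------------------------------
# Patterson's D and the block jackknife


def _oriented(d_textbook: float, convention: str) -> float:
    if convention == "textbook":
        return d_textbook
    if convention == P2P3_NEGATIVE:
        return -d_textbook
    raise ValueError(f"unknown D convention {convention!r}")


def patterson_d(
    polarized: PolarizedSites | list[PolarizedSites],
    convention: str = P2P3_NEGATIVE,
) -> DStatResult:
    """Genome-wide D without significance (see :func:`dstat` for Z)."""
    chunks = polarized if isinstance(polarized, list) else [polarized]
    abba = baba = 0.0
    n_sites = 0
    quartet = None
    for ps in chunks:
        a, b = site_patterns(ps)
        abba += float(a.sum())
        baba += float(b.sum())
        n_sites += len(ps.positions)
    if abba + baba == 0:
        raise ValueError("no informative sites: ABBA + BABA = 0")
    d = _oriented((abba - baba) / (abba + baba), convention)
    return DStatResult(
        quartet=quartet,
        d=d,
        jackknife_se=None,
        z=None,
        n_sites_used=n_sites,
        block_count=0,
        sum_abba=abba,
        sum_baba=baba,
        convention=convention,
    )


def block_jackknife(
    num: np.ndarray,
    den: np.ndarray,
    block_ids: np.ndarray,
) -> tuple[float, float, float | None, int]:
    """Weighted delete-one-block jackknife of a ratio estimator.

    Blocks are weighted by their site counts (Busing, Meijer & van der
    Leeden 1999, as used for genome-block D standard errors). Returns
    (estimate, se, z, n_blocks); z is None when se = 0.
    """
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    blocks = np.unique(block_ids)
    m = np.array([(block_ids == b).sum() for b in blocks], dtype=float)
    keep = m > 0
    blocks, m = blocks[keep], m[keep]
    g = len(blocks)
    if g < 2:
        raise ValueError(
            "block jackknife needs >= 2 non-empty blocks; shrink the block size"
        )
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise ValueError("jackknife ratio undefined: zero denominator")
    theta = total_num / total_den
    theta_del = np.empty(g)
    for j, b in enumerate(blocks):
        sel = block_ids == b
        dden = total_den - den[sel].sum()
        theta_del[j] = (total_num - num[sel].sum()) / dden if dden != 0 else theta
    n = m.sum()
    h = n / m
    theta_jack = g * theta - np.sum((1.0 - m / n) * theta_del)
    pseudo = h * theta - (h - 1.0) * theta_del
    var = np.sum((pseudo - theta_jack) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = float(theta / se) if se > 0 else None
    return float(theta), se, z, g


def _block_ids(chrom: str, positions: np.ndarray, block_size: int) -> np.ndarray:
    """Fixed coordinate bins; the terminal short bin is its own block."""
    bins = (positions - 1) // block_size
    return np.array([f"{chrom}:{b}" for b in bins])


def dstat(
    matrices: dict[str, VariantMatrix],
    popmap: PopulationMap,
    quartet: Quartet,
    block_size: int = 5_000_000,
    outgroup_fix_threshold: float = 0.9,
    convention: str = P2P3_NEGATIVE,
) -> DStatResult:
    """Genome-wide Patterson's D with block-jackknife Z score."""
    nums, dens, ids = [], [], []
    abba_t = baba_t = 0.0
    n_sites = 0
    for chrom, vm in matrices.items():
        ps = polarize(vm, popmap, quartet, outgroup_fix_threshold)
        abba, baba = site_patterns(ps)
        nums.append(abba - baba)
        dens.append(abba + baba)
        ids.append(_block_ids(chrom, ps.positions, block_size))
        abba_t += float(abba.sum())
        baba_t += float(baba.sum())
        n_sites += len(ps.positions)
    num = np.concatenate(nums)
    den = np.concatenate(dens)
    if den.sum() == 0:
        raise ValueError("no informative sites: ABBA + BABA = 0")
    d_tex, se, z_tex, g = block_jackknife(num, den, np.concatenate(ids))
    sign = 1.0 if convention == "textbook" else -1.0
    return DStatResult(
        quartet=quartet,
        d=sign * d_tex,
        jackknife_se=se,
        z=(sign * z_tex) if z_tex is not None else None,
        n_sites_used=n_sites,
        block_count=g,
        sum_abba=abba_t,
        sum_baba=baba_t,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# f_d


def fd_components(ps: PolarizedSites) -> tuple[np.ndarray, np.ndarray]:
    """Per-site f_d numerator and dynamic-donor denominator."""
    abba, baba = site_patterns(ps)
    pd_ = np.maximum(ps.x, ps.y)
    den = (1.0 - ps.w) * pd_ * pd_ - ps.w * (1.0 - pd_) * pd_
    return abba - baba, den


def fd_window(ps: PolarizedSites, window: Window, min_snps: int = 30) -> FdWindowRecord:
    """f_d for a single window of polarized sites."""
    return fd_scan(ps, [window], min_snps)[0]


def fd_scan(
    ps: PolarizedSites, windows: list[Window], min_snps: int = 30
) -> list[FdWindowRecord]:
    """Windowed f_d records; windows with < ``min_snps`` usable sites or an
    undefined ratio are marked excluded, windows with windowed D <= 0 carry
    f_d = 0 (retained in the quantile support)."""
    num, den_fd = fd_components(ps)
    abba, baba = site_patterns(ps)
    den_d = abba + baba
    cs = {k: _cumsum0(v) for k, v in
          {"num": num, "den_fd": den_fd, "den_d": den_d}.items()}
    cs_n = _cumsum0(np.ones(len(ps.positions)))
    lo, hi = _window_bounds(ps.positions, windows)
    out = []
    for j, w in enumerate(windows):
        snp = int(cs_n[hi[j]] - cs_n[lo[j]])
        s_num = float(cs["num"][hi[j]] - cs["num"][lo[j]])
        s_dfd = float(cs["den_fd"][hi[j]] - cs["den_fd"][lo[j]])
        s_dd = float(cs["den_d"][hi[j]] - cs["den_d"][lo[j]])
        if snp < min_snps or s_dd <= 0:
            out.append(FdWindowRecord(w, float("nan"), snp, 0, excluded=True))
            continue
        d_sign = int(np.sign(s_num))
        if s_num <= 0:
            out.append(FdWindowRecord(w, 0.0, snp, d_sign, excluded=False))
        elif s_dfd <= 0:
            out.append(FdWindowRecord(w, float("nan"), snp, d_sign, excluded=True))
        else:
            out.append(FdWindowRecord(w, s_num / s_dfd, snp, d_sign, excluded=False))
    return out


# ---------------------------------------------------------------------------
# candidate regions


def call_candidate_regions(
    records: list[FdWindowRecord],
    genome_length: int,
    top_quantile: float = 0.05,
    event_id: str = "",
) -> CandidateRegionSet:
    """Select the top-quantile f_d windows (ties included) and merge them.

    The threshold is the k-th largest f_d with k = ceil(quantile * n) over
    non-excluded windows; overlapping/adjacent selected windows are merged.
    """
    if not 0 < top_quantile < 1:
        raise ValueError("top_quantile must be in (0, 1)")
    usable = [r for r in records if not r.excluded]
    if not usable:
        raise ValueError("no usable f_d windows to call regions from")
    fd = np.array([r.fd for r in usable])
    k = math.ceil(top_quantile * len(usable))
    threshold = float(np.sort(fd)[::-1][k - 1])
    selected = [r for r in usable if r.fd >= threshold]
    regions = RegionSet(
        (r.window.chrom, r.window.start, r.window.end) for r in selected
    )
    return CandidateRegionSet(
        event_id=event_id,
        regions=regions,
        threshold=threshold,
        genome_fraction=regions.total_length / genome_length,
        n_windows_selected=len(selected),
    )


@dataclass
class EventScanResult:
    events: dict[str, CandidateRegionSet]
    dstats: dict[str, DStatResult]
    fd_records: dict[str, list[FdWindowRecord]]
    union: RegionSet
    union_fraction: float


def scan_events(
    matrices: dict[str, VariantMatrix],
    popmap: PopulationMap,
    events: list[MigrationEventSpec],
    genome: dict[str, int],
    window_size: int = 20_000,
    step: int = 10_000,
    min_snps: int = 30,
    top_quantile: float = 0.05,
    block_size: int = 5_000_000,
    outgroup_fix_threshold: float = 0.9,
) -> EventScanResult:
    """Run polarize -> f_d windows -> top-quantile region calling per event,
    plus genome-wide D with jackknife, and the de-duplicated union."""
    genome_length = sum(genome.values())
    per_event: dict[str, CandidateRegionSet] = {}
    dstats: dict[str, DStatResult] = {}
    fd_all: dict[str, list[FdWindowRecord]] = {}
    for ev in events:
        popmap.require(
            s
            for g in (ev.quartet.p1, ev.quartet.p2, ev.quartet.p3, ev.quartet.outgroup)
            for s in popmap.samples_of(g)
        )
        records: list[FdWindowRecord] = []
        for chrom, vm in matrices.items():
            ps = polarize(vm, popmap, ev.quartet, outgroup_fix_threshold)
            windows = iter_windows(genome[chrom], window_size, step, chrom)
            records.extend(fd_scan(ps, windows, min_snps))
        per_event[ev.event_id] = call_candidate_regions(
            records, genome_length, top_quantile, ev.event_id
        )
        fd_all[ev.event_id] = records
        dstats[ev.event_id] = dstat(
            matrices, popmap, ev.quartet, block_size, outgroup_fix_threshold
        )
    union = RegionSet()
    for crs in per_event.values():
        union = union | crs.regions
    return EventScanResult(
        events=per_event,
        dstats=dstats,
        fd_records=fd_all,
        union=union,
        union_fraction=union.total_length / genome_length,
    )


# ---------------------------------------------------------------------------
# tabular export


def fd_records_to_frame(records: list[FdWindowRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in records],
            "start": [r.window.start for r in records],
            "end": [r.window.end for r in records],
            "fd": [r.fd for r in records],
            "snp_count": [r.snp_count for r in records],
            "window_d_sign": [r.window_d_sign for r in records],
            "excluded": [r.excluded for r in records],
        }
    )


def dstats_to_frame(results: dict[str, DStatResult]) -> pd.DataFrame:
    rows = []
    for event_id, r in results.items():
        rows.append(
            {
                "event": event_id,
                "p1": r.quartet.p1,
                "p2": r.quartet.p2,
                "p3": r.quartet.p3,
                "outgroup": r.quartet.outgroup,
                "d": r.d,
                "jackknife_se": r.jackknife_se,
                "z": r.z,
                "n_sites": r.n_sites_used,
                "n_abba": r.sum_abba,
                "n_baba": r.sum_baba,
                "blocks": r.block_count,
                "convention": r.convention,
            }
        )
    return pd.DataFrame(rows)
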