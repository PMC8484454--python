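"""Synthetic multi-group diploid cohorts with known introgression tracts.

The generator uses the Balding-Nichols frequency model: each SNP draws an
ancestral frequency p uniformly within bounds, and each group k draws its
own frequency from Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k), so F_k sets the
expected differentiation from the ancestral pool. Diploid dosages are
binomial draws from the group frequency. This gives closed-form
expectations and exact truth tracts without a coalescent dependency; it
deliberately has no linkage structure beyond the injected tracts.

The outgroup is simulated near-fixed for the ancestral allele, with a small
rate of intermediate-frequency sites so outgroup-polarization exclusions are
exercised. A fraction of sites has REF/ALT swapped relative to the
ancestral/derived orientation, exercising allele-flip polarization.

Introgression is modeled as tract transfer: inside a tract, each selected
recipient individual (selection probability = admixture fraction) has one of
its two haploid alleles redrawn as Bernoulli(donor frequency), mimicking
heterozygous introgressed ancestry.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_core import (
    MISSING,
    GeneTable,
    PopulationMap,
    VariantMatrix,
    write_popmap,
    write_vcf,
)


@dataclass(frozen=True)
class GroupModel:
    label: str
    size: int  # diploid individuals
    fst: float  # Balding-Nichols F, in [0, 1)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"{self.label}: group size must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError(f"{self.label}: F must be in [0, 1)")


@dataclass
class TruthTract:
    """A known donor->recipient introgression tract (half-open).

    ``haplotypes`` sets how many of a selected individual's two haploid
    genomes are replaced by donor draws: 1 mimics heterozygous introgressed
    ancestry (tract-level donor ancestry = fraction/2), 2 replaces the full
    individual (ancestry = fraction).
    """

    chrom: str
    start: int
    end: int
    donor: str
    recipient: str
    admixture_fraction: float
    haplotypes: int = 1
    replaced_individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid tract [{self.start}, {self.end})")
        if not 0 <= self.admixture_fraction <= 1:
            raise ValueError("admixture fraction must be in [0, 1]")
        if self.haplotypes not in (1, 2):
            raise ValueError("haplotypes replaced must be 1 or 2")


@dataclass
class PopulationModel:
    groups: list[GroupModel]
    genome: dict[str, int]
    seed: int
    outgroup: str | None = None
    snp_density_per_kb: float = 4.0
    ancestral_bounds: tuple[float, float] = (0.05, 0.95)
    outgroup_poly_rate: float = 0.005
    allele_swap_rate: float = 0.05
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.snp_density_per_kb <= 0:
            raise ValueError("SNP density must be positive")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if self.outgroup is not None and self.outgroup not in labels:
            raise ValueError(f"outgroup {self.outgroup!r} not among groups")

    @property
    def group_labels(self) -> list[str]:
        return [g.label for g in self.groups]


@dataclass
class SimulatedCohort:
    model: PopulationModel
    variants: dict[str, VariantMatrix]
    popmap: PopulationMap
    tracts: list[TruthTract]
    frequencies: dict[str, dict[str, np.ndarray]]  # chrom -> group -> derived p
    ancestral_is_alt: dict[str, np.ndarray]  # chrom -> per-site swap flag
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# frequency and genotype draws


def draw_site_frequencies(
    model: PopulationModel, n_sites: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Ancestral and per-group derived-allele frequencies for n_sites SNPs."""
    lo, hi = model.ancestral_bounds
    p = rng.uniform(lo, hi, n_sites)
    freqs: dict[str, np.ndarray] = {}
    for g in model.groups:
        if g.label == model.outgroup:
            pk = np.zeros(n_sites)
            poly = rng.random(n_sites) < model.outgroup_poly_rate
            pk[poly] = rng.uniform(0.1, 0.9, int(poly.sum()))
        elif g.fst == 0:
            pk = p.copy()
        else:
            ratio = (1.0 - g.fst) / g.fst
            pk = rng.beta(p * ratio, (1.0 - p) * ratio)
        freqs[g.label] = pk
    return p, freqs


def simulate_genotypes(
    pk: np.ndarray,
    n_individuals: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Diploid derived-allele dosages, Binomial(2, p) per individual."""
    g = rng.binomial(2, pk[:, None], size=(len(pk), n_individuals)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return g


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(
    model: PopulationModel, tracts: list[TruthTract] | None = None
) -> SimulatedCohort:
    """Simulate a cohort; the base cohort depends only on the model seed, so
    runs with and without ``tracts`` are paired replicates."""
    rng = np.random.default_rng(model.seed)
    assignments: dict[str, str] = {}
    for g in model.groups:
        for i in range(g.size):
            assignments[f"{g.label}_{i:03d}"] = g.label
    popmap = PopulationMap(assignments)
    sample_ids = list(assignments)

    variants: dict[str, VariantMatrix] = {}
    frequencies: dict[str, dict[str, np.ndarray]] = {}
    swaps: dict[str, np.ndarray] = {}
    for chrom, length in model.genome.items():
        n_sites = int(round(length * model.snp_density_per_kb / 1000.0))
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        _, freqs = draw_site_frequencies(model, n_sites, rng)
        blocks = [
            simulate_genotypes(freqs[g.label], g.size, rng, model.missing_rate)
            for g in model.groups
        ]
        derived = np.concatenate(blocks, axis=1)
        swap = rng.random(n_sites) < model.allele_swap_rate
        alt_dosage = np.where(
            (derived != MISSING) & swap[:, None], 2 - derived, derived
        ).astype(np.int8)
        ref = np.where(swap, "G", "A")
        alt = np.where(swap, "A", "G")
        variants[chrom] = VariantMatrix(
            chrom=chrom,
            positions=positions,
            genotypes=alt_dosage,
            sample_ids=sample_ids,
            ref=ref,
            alt=alt,
        )
        frequencies[chrom] = freqs
        swaps[chrom] = swap

    cohort = SimulatedCohort(
        model=model,
        variants=variants,
        popmap=popmap,
        tracts=[],
        frequencies=frequencies,
        ancestral_is_alt=swaps,
        log={"seed": model.seed, "n_sites": {c: v.n_sites for c, v in variants.items()}},
    )
    if tracts:
        cohort = inject_introgression(cohort, tracts)
    return cohort


def _merge_tracts(tracts: list[TruthTract]) -> list[TruthTract]:
    """Merge overlapping tracts of the same donor/recipient pair, warning."""
    by_key: dict[tuple, list[TruthTract]] = {}
    for t in tracts:
        by_key.setdefault((t.chrom, t.donor, t.recipient), []).append(t)
    out: list[TruthTract] = []
    for key, group in by_key.items():
        group.sort(key=lambda t: t.start)
        merged = [group[0]]
        for t in group[1:]:
            if t.start < merged[-1].end:
                warnings.warn(
                    f"overlapping tracts for {key[1]}->{key[2]} on {key[0]}; merging"
                )
                last = merged[-1]
                merged[-1] = TruthTract(
                    last.chrom,
                    last.start,
                    max(last.end, t.end),
                    last.donor,
                    last.recipient,
                    max(last.admixture_fraction, t.admixture_fraction),
                    max(last.haplotypes, t.haplotypes),
                )
            else:
                merged.append(t)
        out.extend(merged)
    return out


def inject_introgression(
    cohort: SimulatedCohort, tracts: list[TruthTract]
) -> SimulatedCohort:
    """Inject donor tracts into recipient individuals; returns a new cohort
    (the input is not modified). Uses an RNG stream derived from the model
    seed but independent of base-cohort generation."""
    rng = np.random.default_rng([cohort.model.seed, 7919])
    tracts = _merge_tracts([TruthTract(**{**asdict(t), "replaced_individuals": []}) for t in tracts])
    new_variants = {c: vm.genotypes.copy() for c, vm in cohort.variants.items()}
    sample_ids = cohort.variants[next(iter(cohort.variants))].sample_ids

    for tract in tracts:
        if tract.chrom not in cohort.variants:
            raise KeyError(f"tract chromosome {tract.chrom!r} not in cohort")
        vm = cohort.variants[tract.chrom]
        recip = cohort.popmap.samples_of(tract.recipient)
        if not recip or tract.donor not in cohort.popmap.groups:
            raise KeyError("tract donor/recipient group missing from cohort")
        cols = vm.sample_indices(recip)
        chosen = rng.random(len(cols)) < tract.admixture_fraction
        tract.replaced_individuals = [s for s, c in zip(recip, chosen) if c]
        if not chosen.any():
            continue
        coords = vm.positions - 1
        rows = np.where((coords >= tract.start) & (coords < tract.end))[0]
        if len(rows) == 0:
            continue
        swap = cohort.ancestral_is_alt[tract.chrom][rows]
        g = new_variants[tract.chrom]
        sub = g[np.ix_(rows, cols[chosen])]
        derived = np.where(swap[:, None], 2 - sub, sub).astype(np.int16)
        p_donor = cohort.frequencies[tract.chrom][tract.donor][rows]
        if tract.haplotypes == 2:
            new_derived = rng.binomial(2, np.broadcast_to(p_donor[:, None], derived.shape))
        else:
            kept = rng.binomial(1, np.clip(derived, 0, 2) / 2.0)
            donor_allele = (rng.random(derived.shape) < p_donor[:, None]).astype(np.int16)
            new_derived = kept + donor_allele
        new_derived[derived == MISSING] = MISSING
        new_alt = np.where(
            (new_derived != MISSING) & swap[:, None], 2 - new_derived, new_derived
        ).astype(np.int8)
        g[np.ix_(rows, cols[chosen])] = new_alt

    variants = {
        c: VariantMatrix(
            chrom=c,
            positions=vm.positions,
            genotypes=new_variants[c],
            sample_ids=list(sample_ids),
            ref=vm.ref,
            alt=vm.alt,
        )
        for c, vm in cohort.variants.items()
    }
    return SimulatedCohort(
        model=cohort.model,
        variants=variants,
        popmap=cohort.popmap,
        tracts=cohort.tracts + tracts,
        frequencies=cohort.frequencies,
        ancestral_is_alt=cohort.ancestral_is_alt,
        log={**cohort.log, "tracts": [asdict(t) for t in tracts]},
    )


# ---------------------------------------------------------------------------
# emission


def emit_dataset(cohort: SimulatedCohort, out_dir: str) -> dict[str, str]:
    """Write VCF, popmap TSV, truth-tract BED and a JSON run log; returns the
    paths keyed by artifact name."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "truth_bed": os.path.join(out_dir, "truth_tracts.bed"),
        "log": os.path.join(out_dir, "model.json"),
    }
    write_vcf(cohort.variants, paths["vcf"])
    write_popmap(cohort.popmap, paths["popmap"])
    with open(paths["truth_bed"], "w") as fh:
        for t in cohort.tracts:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.donor}\t{t.recipient}"
                f"\t{t.admixture_fraction}\n"
            )
    model = cohort.model
    log = {
        "seed": model.seed,
        "genome": model.genome,
        "snp_density_per_kb": model.snp_density_per_kb,
        "ancestral_bounds": list(model.ancestral_bounds),
        "outgroup": model.outgroup,
        "outgroup_poly_rate": model.outgroup_poly_rate,
        "allele_swap_rate": model.allele_swap_rate,
        "missing_rate": model.missing_rate,
        "groups": [asdict(g) for g in model.groups],
        "tracts": [asdict(t) for t in cohort.tracts],
    }
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# presets (desk-scale study design)


#: Group sizes mirroring the resequenced cohort design (unequal 6-38 diploids
#: per group) plus a small peach-like outgroup panel.
STUDY_GROUP_SIZES: dict[str, int] = {
    "NWC_C": 28,
    "NC_C": 38,
    "West_C": 30,
    "XJ_C": 29,
    "NWC_W": 6,
    "XJ_W": 7,
    "KU_C": 21,
    "NEC_C": 11,
    "PsPma": 10,
}
OUTGROUP_LABEL = "peach"
DESK_GENOME: dict[str, int] = {"chr1": 2_000_000, "chr2": 2_000_000}
#: Jackknife block size at desk scale: ~40 blocks on the 4 Mb genome, the
#: same block-to-genome ratio regime as 5 Mb blocks on a full genome.
DESK_BLOCK_SIZE = 100_000


def desk_scale_model(
    seed: int, fst: float = 0.1, outgroup_size: int = 2, **overrides
) -> PopulationModel:
    """Nine study groups plus outgroup on a 2 x 2 Mb genome at 4 SNPs/kb."""
    groups = [GroupModel(label, size, fst) for label, size in STUDY_GROUP_SIZES.items()]
    groups.append(GroupModel(OUTGROUP_LABEL, outgroup_size, 0.0))
    kwargs = dict(
        groups=groups,
        genome=dict(DESK_GENOME),
        seed=seed,
        outgroup=OUTGROUP_LABEL,
    )
    kwargs.update(overrides)
    return PopulationModel(**kwargs)


def signal_tracts(
    genome: dict[str, int],
    donor: str = "XJ_C",
    recipient: str = "NWC_C",
    coverage: float = 0.05,
    admixture_fraction: float = 1.0,
    haplotypes: int = 2,
    n_per_chrom: int = 1,
) -> list[TruthTract]:
    """``n_per_chrom`` evenly spaced tracts per chromosome jointly covering
    ``coverage`` of the genome.

    The default is a saturating pulse — every recipient individual carries
    full donor ancestry inside the tract — the regime in which a fixed-F
    frequency model without linkage gives windowed f_d a usable
    signal-to-noise ratio (see the methods note). Spreading the coverage
    over several shorter tracts mimics the fragmented tract structure of an
    old admixture pulse and spreads the D signal across jackknife blocks.
    """
    tracts = []
    for chrom, length in genome.items():
        tract_len = int(round(length * coverage / n_per_chrom))
        spacing = length // n_per_chrom
        for i in range(n_per_chrom):
            start = i * spacing + spacing // 4
            tracts.append(
                TruthTract(
                    chrom, start, start + tract_len, donor, recipient,
                    admixture_fraction, haplotypes,
                )
            )
    return tracts


#: Larger cohort for signal-recovery studies: genome-wide D precision scales
#: with the total informative-site count, so tract recovery and jackknife Z
#: are assessed on a 2 x 25 Mb genome at 8 SNPs/kb (~400k SNPs) with 1 Mb
#: jackknife blocks (the same block:genome ratio regime as 5 Mb blocks on a
#: ~250 Mb genome).
SIGNAL_GENOME: dict[str, int] = {"chr1": 25_000_000, "chr2": 25_000_000}
SIGNAL_BLOCK_SIZE = 1_000_000
SIGNAL_DENSITY = 8.0
#: The 5% tract coverage is spread over 20 tracts per chromosome (62.5 kb
#: each) so the introgression signal is distributed across jackknife blocks
#: rather than concentrated in one or two; a single contiguous tract inflates
#: the delete-one-block variance with its own signal and caps |Z|.
SIGNAL_TRACTS_PER_CHROM = 20


def signal_scale_model(seed: int, fst: float = 0.1, **overrides) -> PopulationModel:
    """Study groups on the signal-recovery genome (see :data:`SIGNAL_GENOME`)."""
    kwargs = dict(
        genome=dict(SIGNAL_GENOME), snp_density_per_kb=SIGNAL_DENSITY
    )
    kwargs.update(overrides)
    return desk_scale_model(seed, fst=fst, **kwargs)


def simulate_gene_annotation(
    genome: dict[str, int],
    rng: np.random.Generator,
    n_genes: int = 800,
    gene_length: int = 2_000,
    n_pathways: int = 40,
    pathway_size: int = 15,
    planted_pathway: str | None = None,
    planted_size: int = 25,
    planted_in_tract_fraction: float = 0.8,
    tracts: list[TruthTract] | None = None,
) -> tuple[GeneTable, pd.DataFrame]:
    """Synthetic gene intervals and a flat pathway annotation.

    When ``planted_pathway`` is given, that pathway's genes are placed
    preferentially inside the truth tracts, creating a known enrichment
    signal; all other pathways sample genes uniformly.
    """
    chroms = list(genome)
    lens = np.array([genome[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_genes, p=lens / lens.sum())
    starts = np.array(
        [rng.integers(0, genome[chroms[i]] - gene_length) for i in chrom_idx]
    )
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "chrom": [chroms[i] for i in chrom_idx],
            "start": starts,
            "end": starts + gene_length,
        }
    )
    genes = GeneTable(df)

    rows = []
    for j in range(n_pathways):
        members = rng.choice(df["gene_id"], size=pathway_size, replace=False)
        rows.extend(
            {"gene_id": g, "pathway_id": f"pw{j:03d}", "pathway_name": f"pathway {j}"}
            for g in members
        )
    if planted_pathway is not None:
        if not tracts:
            raise ValueError("planted pathway requires truth tracts")
        from .io_core import RegionSet

        tract_rs = RegionSet((t.chrom, t.start, t.end) for t in tracts)
        inside = df.apply(
            lambda r: tract_rs.overlap_length(r.chrom, r.start, r.end) > 0, axis=1
        )
        in_ids = df.loc[inside, "gene_id"].to_numpy()
        out_ids = df.loc[~inside, "gene_id"].to_numpy()
        n_in = min(int(round(planted_size * planted_in_tract_fraction)), len(in_ids))
        picks = list(rng.choice(in_ids, size=n_in, replace=False)) + list(
            rng.choice(out_ids, size=planted_size - n_in, replace=False)
        )
        rows.extend(
            {"gene_id": g, "pathway_id": planted_pathway, "pathway_name": planted_pathway}
            for g in picks
        )
    return genes, pd.DataFrame(rows)
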