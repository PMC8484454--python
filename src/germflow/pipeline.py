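"""End-to-end orchestration: simulate -> diversity -> dstat -> fdscan ->
regions -> mask -> enrich -> report.

Every stage logs timings and record counts; output tables carry the config
hash so artifacts are traceable to the parameters that produced them. Given
the same seed and config the run is deterministic.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contribution, diversity, enrichment, introgression, synth
from .config import ScanConfig
from .io_core import (
    PopulationMap,
    RegionSet,
    VariantMatrix,
    write_regions_bed,
)

log = logging.getLogger("germflow")


@dataclass
class PipelineInputs:
    matrices: dict[str, VariantMatrix]
    popmap: PopulationMap
    genome: dict[str, int]
    events: list[introgression.MigrationEventSpec]
    diversity_groups: list[str] | None = None
    genes: "object | None" = None  # GeneTable
    annotation: pd.DataFrame | None = None
    truth_tracts: list[synth.TruthTract] = field(default_factory=list)


@dataclass
class PipelineResult:
    summaries_before: dict[str, diversity.DiversitySummary]
    summaries_after: dict[str, diversity.DiversitySummary]
    reductions: dict[str, list[contribution.ReductionReport]]
    scan: introgression.EventScanResult
    enrichment_table: pd.DataFrame | None
    artifacts: dict[str, str]


def events_from_dicts(specs: list[dict]) -> list[introgression.MigrationEventSpec]:
    """Build migration-event specs from mapping entries with keys
    ``id, p1, donor (p3), recipient (p2), outgroup``."""
    events = []
    for s in specs:
        quartet = introgression.Quartet(
            p1=s["p1"], p2=s["recipient"], p3=s["donor"], outgroup=s["outgroup"]
        )
        events.append(
            introgression.MigrationEventSpec(
                event_id=str(s["id"]), donor=s["donor"], recipient=s["recipient"],
                quartet=quartet,
            )
        )
    return events


def _stamp(df: pd.DataFrame, path: str, config: ScanConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: ScanConfig,
    inputs: PipelineInputs,
    out_dir: str,
    diversity_scope: str = "all",
) -> PipelineResult:
    """Run the full scan on prepared inputs and write all artifacts.

    ``diversity_scope`` chooses which groups get before/after diversity
    summaries: ``"all"`` (every non-outgroup group in the events' quartets is
    still scanned individually) or a recipient-only subset via
    ``inputs.diversity_groups``.
    """
    os.makedirs(out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    groups = inputs.diversity_groups
    if groups is None:
        exclude = {ev.quartet.outgroup for ev in inputs.events}
        groups = [g for g in inputs.popmap.groups if g not in exclude]

    def windows_for(chrom):
        return introgression.iter_windows(
            inputs.genome[chrom], config.window_size, config.step, chrom
        )

    # -- diversity (before) -------------------------------------------------
    t0 = time.perf_counter()
    records_before: dict[str, list] = {g: [] for g in groups}
    for chrom, vm in inputs.matrices.items():
        for g in groups:
            records_before[g].extend(
                diversity.diversity_scan(
                    vm, inputs.popmap, g, windows_for(chrom),
                    min_call_rate=config.min_call_rate,
                )
            )
    summaries_before = {
        g: diversity.summarize_group(r, config.min_effective_sites)
        for g, r in records_before.items()
    }
    all_records = [r for rs in records_before.values() for r in rs]
    path = os.path.join(out_dir, "diversity_windows.tsv")
    _stamp(diversity.records_to_frame(all_records), path, config)
    artifacts["diversity_windows"] = path
    timings["diversity"] = time.perf_counter() - t0
    log.info(
        "diversity: %d windows x %d groups in %.1fs",
        len(all_records), len(groups), timings["diversity"],
    )

    # -- introgression scan --------------------------------------------------
    t0 = time.perf_counter()
    scan = introgression.scan_events(
        inputs.matrices,
        inputs.popmap,
        inputs.events,
        inputs.genome,
        window_size=config.window_size,
        step=config.step,
        min_snps=config.min_snps_fd,
        top_quantile=config.top_quantile,
        block_size=config.block_size,
        outgroup_fix_threshold=config.outgroup_fix_threshold,
    )
    for event_id, records in scan.fd_records.items():
        path = os.path.join(out_dir, f"fd_{event_id}.tsv")
        _stamp(introgression.fd_records_to_frame(records), path, config)
        artifacts[f"fd_{event_id}"] = path
    for event_id, crs in scan.events.items():
        path = os.path.join(out_dir, f"regions_{event_id}.bed")
        write_regions_bed(crs.regions, path, header=f"config_hash={config.config_hash}")
        artifacts[f"regions_{event_id}"] = path
    path = os.path.join(out_dir, "regions_union.bed")
    write_regions_bed(scan.union, path, header=f"config_hash={config.config_hash}")
    artifacts["regions_union"] = path
    path = os.path.join(out_dir, "dstats.tsv")
    _stamp(introgression.dstats_to_frame(scan.dstats), path, config)
    artifacts["dstats"] = path
    timings["introgression"] = time.perf_counter() - t0
    log.info(
        "introgression: %d events, union fraction %.2f%% in %.1fs",
        len(scan.events), 100 * scan.union_fraction, timings["introgression"],
    )

    # -- mask and recompute --------------------------------------------------
    t0 = time.perf_counter()
    masked, mask = contribution.mask_regions(inputs.matrices, scan.union, inputs.genome)
    summaries_after: dict[str, diversity.DiversitySummary] = {}
    reductions: dict[str, list[contribution.ReductionReport]] = {}
    masked_fraction = scan.union.total_length / sum(inputs.genome.values())
    for g in groups:
        records = []
        for chrom, vm in masked.items():
            records.extend(
                diversity.diversity_scan(
                    vm, inputs.popmap, g, windows_for(chrom), mask=mask,
                    min_call_rate=config.min_call_rate,
                )
            )
        summaries_after[g] = diversity.summarize_group(records, config.min_effective_sites)
        reductions[g] = contribution.reduction_summary(
            summaries_before[g], summaries_after[g], masked_fraction
        )
    rows = []
    for g, reports in reductions.items():
        for r in reports:
            rows.append(
                {
                    "group": g,
                    "statistic": r.statistic,
                    "before": r.value_before,
                    "after": r.value_after,
                    "percent_reduction": (
                        round(r.percent_reduction, 1)
                        if r.percent_reduction is not None
                        else None
                    ),
                    "masked_fraction": r.masked_fraction,
                }
            )
    path = os.path.join(out_dir, "reduction.tsv")
    _stamp(pd.DataFrame(rows), path, config)
    artifacts["reduction"] = path
    timings["mask"] = time.perf_counter() - t0

    # -- enrichment ----------------------------------------------------------
    table = None
    if inputs.genes is not None and inputs.annotation is not None:
        t0 = time.perf_counter()
        table = enrichment.enrich(scan.union, inputs.genes, inputs.annotation)
        path = os.path.join(out_dir, "enrichment.tsv")
        _stamp(table, path, config)
        artifacts["enrichment"] = path
        timings["enrich"] = time.perf_counter() - t0

    # -- report --------------------------------------------------------------
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "union_fraction_percent": round(100 * scan.union_fraction, 2),
        "per_event_fraction_percent": {
            eid: round(100 * crs.genome_fraction, 2) for eid, crs in scan.events.items()
        },
        "dstats": {
            eid: {"d": r.d, "z": r.z, "blocks": r.block_count}
            for eid, r in scan.dstats.items()
        },
        "diversity_before": {g: s.__dict__ for g, s in summaries_before.items()},
        "diversity_after": {g: s.__dict__ for g, s in summaries_after.items()},
    }
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    artifacts["report"] = path

    return PipelineResult(
        summaries_before=summaries_before,
        summaries_after=summaries_after,
        reductions=reductions,
        scan=scan,
        enrichment_table=table,
        artifacts=artifacts,
    )
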