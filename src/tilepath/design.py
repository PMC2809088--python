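"""Promoter tile-path assembly under a probe budget.

Design regions come from three (partially overlapping) sources: enriched
peak regions, gene 5' ends and EST-derived TSS clusters, each widened by
2 kb per side; whole background scaffolds are added for genomic-background
estimation.  The merged regions are tiled with isothermal probes,
non-unique probes are dropped, and the result must fit one array
(~2.1 million probes by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import probes as probes_mod
from .errors import BudgetError, DataError
from .probes import Probe, TilingParams, count_exact_matches, tile_scaffold
from .types import GeneModel, Region, Scaffold, merge_intervals


@dataclass
class DesignParams:
    extend: int = 2000  # bp added on each side of a seed region
    probe_budget: int = 2_100_000
    background_scaffolds: tuple[str, ...] = ()
    tiling: TilingParams = field(default_factory=TilingParams)

    def __post_init__(self):
        if self.extend < 0:
            raise ValueError("extend must be >= 0")
        if self.probe_budget <= 0:
            raise ValueError("probe_budget must be positive")


@dataclass
class ArrayDesign:
    regions: list[Region]
    probes: list[Probe]
    n_probes: int
    n_regions: int
    median_region_len: float
    source_probe_counts: dict[str, int]


@dataclass
class BudgetReport:
    passed: bool
    n_probes: int
    budget: int
    headroom: int  # budget - n_probes (negative on fail)
    suggestion: str = ""

    @property
    def overshoot(self) -> int:
        return max(0, self.n_probes - self.budget)


def _merge_tag(tags) -> str:
    parts = sorted({p for t in tags for p in t.split("+")})
    return "+".join(parts)


def extend_and_merge(
    regions: list[Region], extend: int, scaffold_lengths: dict[str, int]
) -> list[Region]:
    """Widen each region by ``extend`` bp per side, clip, and merge.

    Overlapping or touching results merge transitively; merged regions
    concatenate their source tags and keep the max score.
    """
    by_scaffold: dict[str, list[Region]] = {}
    for reg in regions:
        if reg.scaffold not in scaffold_lengths:
            raise DataError(f"unknown scaffold {reg.scaffold!r}")
        by_scaffold.setdefault(reg.scaffold, []).append(reg)
    out = []
    for scaf in sorted(by_scaffold):
        length = scaffold_lengths[scaf]
        widened = sorted(
            (max(0, r.start - extend), min(length, r.end + extend), r)
            for r in by_scaffold[scaf]
        )
        cur_s, cur_e, first = widened[0]
        cur_tags = [first.source]
        cur_scores = [first.score]
        for s, e, r in widened[1:]:
            if s <= cur_e:  # touching (gap 0) merges
                cur_e = max(cur_e, e)
                cur_tags.append(r.source)
                cur_scores.append(r.score)
            else:
                out.append(_merged_region(scaf, cur_s, cur_e, cur_tags, cur_scores))
                cur_s, cur_e, cur_tags, cur_scores = s, e, [r.source], [r.score]
        out.append(_merged_region(scaf, cur_s, cur_e, cur_tags, cur_scores))
    return out


def _merged_region(scaf, start, end, tags, scores) -> Region:
    real = [s for s in scores if s is not None]
    return Region(
        scaffold=scaf,
        start=start,
        end=end,
        score=max(real) if real else None,
        source=_merge_tag(tags),
    )


def tss_regions(
    genes: list[GeneModel], extend: int, scaffold_lengths: dict[str, int] | None = None
) -> list[Region]:
    """One region [tss - extend, tss + extend) per gene, tagged gene_tss."""
    out = []
    for gene in genes:
        start = max(0, gene.tss - extend)
        end = gene.tss + extend
        if scaffold_lengths is not None:
            end = min(end, scaffold_lengths[gene.scaffold])
        out.append(Region(scaffold=gene.scaffold, start=start, end=end, source="gene_tss"))
    return out


def assemble_design(
    peak_regions: list[Region],
    gene_regions: list[Region],
    est_regions: list[Region],
    params: DesignParams,
    genome: list[Scaffold],
) -> ArrayDesign:
    """Merge all design regions, add background scaffolds, tile, budget-check.

    The three region sets are assumed already extended (peak regions via
    extend_and_merge, gene/EST TSS regions via tss_regions).  Background
    scaffolds enter as full-length regions.  Regions are tiled with the
    isothermal tiler; multi-mapping probes are removed.  Exceeding the
    probe budget raises BudgetError carrying the overshoot and a
    per-source probe breakdown.
    """
    lengths = {sc.name: sc.length for sc in genome}
    all_regions = list(peak_regions) + list(gene_regions) + list(est_regions)
    for name in params.background_scaffolds:
        if name not in lengths:
            raise DataError(f"unknown background scaffold {name!r}")
        all_regions.append(
            Region(scaffold=name, start=0, end=lengths[name], source="background")
        )
    for reg in all_regions:
        if reg.scaffold not in lengths:
            raise DataError(f"unknown scaffold {reg.scaffold!r}")
    # regions are final: merge without further extension
    merged = extend_and_merge(all_regions, 0, lengths)

    # tile by masking everything outside the design regions, so anchors
    # restart at each region and probes never straddle two regions
    regions_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for reg in merged:
        regions_by_scaffold.setdefault(reg.scaffold, []).append((reg.start, reg.end))
    probes: list[Probe] = []
    for sc in genome:
        keep = regions_by_scaffold.get(sc.name)
        if not keep:
            continue
        outside = _complement(keep, sc.length)
        design_mask = merge_intervals(list(sc.mask) + outside)
        probes.extend(
            tile_scaffold(
                Scaffold(name=sc.name, sequence=sc.sequence, mask=design_mask),
                params.tiling,
            )
        )
    counts = count_exact_matches(probes, genome)
    probes = probes_mod.filter_multimapping(probes, counts)

    source_counts = _probes_per_source(probes, merged)
    region_lengths = [r.length for r in merged]
    design = ArrayDesign(
        regions=merged,
        probes=probes,
        n_probes=len(probes),
        n_regions=len(merged),
        median_region_len=float(np.median(region_lengths)) if merged else 0.0,
        source_probe_counts=source_counts,
    )
    if design.n_probes > params.probe_budget:
        raise BudgetError(
            f"design needs {design.n_probes} probes, budget is "
            f"{params.probe_budget} (overshoot {design.n_probes - params.probe_budget}); "
            f"per-source breakdown: {source_counts}",
            overshoot=design.n_probes - params.probe_budget,
            breakdown=source_counts,
        )
    return design


def _complement(intervals, length: int) -> list[tuple[int, int]]:
    merged = merge_intervals(intervals)
    out, prev = [], 0
    for s, e in merged:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def _probes_per_source(probes: list[Probe], regions: list[Region]) -> dict[str, int]:
    by_scaffold: dict[str, list[Region]] = {}
    for reg in regions:
        by_scaffold.setdefault(reg.scaffold, []).append(reg)
    counts: dict[str, int] = {}
    for scaf, regs in by_scaffold.items():
        regs.sort(key=lambda r: r.start)
    for probe in probes:
        for reg in by_scaffold.get(probe.scaffold, []):
            if probe.start >= reg.start and probe.end <= reg.end:
                counts[reg.source] = counts.get(reg.source, 0) + 1
                break
    return counts


def check_budget(design: ArrayDesign, params: DesignParams) -> BudgetReport:
    """Pass/fail budget report with headroom and a relaxation hint."""
    headroom = params.probe_budget - design.n_probes
    passed = headroom >= 0
    suggestion = "" if passed else (
        "raise peak-detection thresholds (or drop lowest-score "
        "h3k4me3_peak-only regions) to shrink the design"
    )
    return BudgetReport(
        passed=passed,
        n_probes=design.n_probes,
        budget=params.probe_budget,
        headroom=headroom,
        suggestion=suggestion,
    )
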