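"""Synthetic fixtures with known ground truth.

The generator emulates the statistical structure of promoter-mark
ChIP-chip data on a draft genome: scaffolds of i.i.d. sequence with a
repeat mask, non-overlapping genes on both strands, probe log2 ratios
that are background noise except for flat enrichment plateaus centered
on a subset of TSSs, two (or more) noisy replicate arrays, and ESTs
whose aligned blocks are split across scaffold pairs with the 5' block
next to an enriched TSS.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .probes import Probe
from .types import ESTAlignment, GeneModel, Region, Scaffold, SignalTable, merge_intervals

_MOD = 2**31


@dataclass
class SimulationParams:
    """Knobs of the synthetic data regime (log2 units for signal fields)."""

    n_scaffolds: int = 4
    scaffold_len_bp: int = 200_000
    gc_fraction: float = 0.4
    mask_fraction: float = 0.10
    n_genes: int = 100
    gene_len_range: tuple[int, int] = (2_000, 8_000)
    enriched_gene_fraction: float = 0.5
    enrichment_mean: float = 2.0
    noise_sd: float = 0.5
    replicate_noise_sd: float = 0.25
    enriched_width_bp: int = 1_000
    n_split_est_pairs: int = 5
    ests_per_pair: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "mask_fraction", "enriched_gene_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0 or self.replicate_noise_sd <= 0:
            raise ValueError("noise sds must be > 0")


@dataclass
class GroundTruth:
    enriched_regions: list[Region] = field(default_factory=list)
    enriched_gene_ids: list[str] = field(default_factory=list)
    planted_links: list[dict] = field(default_factory=list)


def _rng(params: SimulationParams, offset: int) -> np.random.Generator:
    return np.random.default_rng((params.seed + offset) % _MOD)


def simulate_genome(params: SimulationParams):
    """Random scaffolds with mask and non-overlapping genes.

    Bases are i.i.d. at the given GC fraction; the mask is random
    intervals (exponential lengths, mean ~500 bp) accumulated until the
    requested coverage; genes are placed uniformly on both strands by
    rejection sampling (bounded retries).
    Returns ``(scaffolds, genes)``.
    """
    rng = _rng(params, 0)
    p_base = np.array(
        [
            (1 - params.gc_fraction) / 2,  # A
            params.gc_fraction / 2,  # C
            params.gc_fraction / 2,  # G
            (1 - params.gc_fraction) / 2,  # T
        ]
    )
    bases = np.array(list("ACGT"))
    scaffolds = []
    for i in range(params.n_scaffolds):
        length = params.scaffold_len_bp
        seq = "".join(rng.choice(bases, size=length, p=p_base))
        mask: list[tuple[int, int]] = []
        target = int(params.mask_fraction * length)
        covered = 0
        while covered < target:
            span = int(rng.exponential(500)) + 50
            start = int(rng.integers(0, max(1, length - span)))
            mask = merge_intervals(mask + [(start, min(start + span, length))])
            covered = sum(e - s for s, e in mask)
        scaffolds.append(Scaffold(name=f"scaffold_{i + 1}", sequence=seq, mask=mask))

    genes = []
    occupied: dict[str, list[tuple[int, int]]] = {sc.name: [] for sc in scaffolds}
    for gi in range(params.n_genes):
        placed = False
        for _ in range(200):
            sc = scaffolds[int(rng.integers(0, len(scaffolds)))]
            glen = int(rng.integers(params.gene_len_range[0], params.gene_len_range[1] + 1))
            if glen >= sc.length:
                continue
            start = int(rng.integers(0, sc.length - glen))
            end = start + glen
            if any(start < e and s < end for s, e in occupied[sc.name]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    id=f"gene_{gi:04d}", scaffold=sc.name, strand=strand,
                    start=start, end=end,
                )
            )
            occupied[sc.name].append((start, end))
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"could not place gene {gi} after 200 attempts; "
                "reduce n_genes or enlarge scaffolds"
            )
    genes.sort(key=lambda g: (g.scaffold, g.start))
    return scaffolds, genes


def grid_probes(
    scaffold_lengths: dict[str, int], spacing: int = 100, probe_len: int = 50
) -> list[Probe]:
    """Coordinate-only probes on a regular grid (no sequence, no Tm).

    Handy when only the signal layer matters and real tiling would be
    gratuitous.
    """
    probes = []
    for scaf in sorted(scaffold_lengths):
        length = scaffold_lengths[scaf]
        for start in range(0, length - probe_len + 1, spacing):
            end = start + probe_len
            probes.append(
                Probe(
                    probe_id=f"{scaf}:{start}-{end}", scaffold=scaf,
                    start=start, end=end, sequence="", tm=float("nan"),
                )
            )
    return probes


def select_enriched_genes(genes: list[GeneModel], params: SimulationParams) -> list[str]:
    """Deterministic choice of which genes carry enrichment."""
    rng = _rng(params, 17)
    ids = sorted(g.id for g in genes)
    k = round(params.enriched_gene_fraction * len(ids))
    return sorted(rng.choice(ids, size=k, replace=False).tolist())


def simulate_signals(
    scaffolds: list[Scaffold],
    genes: list[GeneModel],
    probes: list[Probe],
    params: SimulationParams,
    array_names: tuple[str, ...] = ("rep1", "rep2"),
):
    """Replicate probe signals with planted promoter enrichment.

    Each probe draws a base value: Normal(0, noise_sd) on background,
    Normal(enrichment_mean, noise_sd) when its midpoint lies in an
    enriched region (a plateau of ``enriched_width_bp`` centered on an
    enriched gene's TSS).  Each replicate adds independent
    Normal(0, replicate_noise_sd).  Returns ``(SignalTable, GroundTruth)``.
    """
    rng = _rng(params, 2)
    lengths = {sc.name: sc.length for sc in scaffolds}
    enriched_ids = select_enriched_genes(genes, params)
    gene_by_id = {g.id: g for g in genes}
    half = params.enriched_width_bp // 2
    regions = []
    for gid in enriched_ids:
        g = gene_by_id[gid]
        start = max(0, g.tss - half)
        end = min(lengths[g.scaffold], g.tss + half)
        regions.append(Region(scaffold=g.scaffold, start=start, end=end,
                              source="h3k4me3_peak"))

    meta = pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "scaffold": [p.scaffold for p in probes],
            "start": [p.start for p in probes],
            "end": [p.end for p in probes],
        }
    )
    mids = ((meta["start"] + meta["end"]) // 2).to_numpy()
    scafs = meta["scaffold"].to_numpy()
    enriched_mask = np.zeros(len(meta), dtype=bool)
    kept_regions, kept_ids = [], []
    for reg, gid in zip(regions, enriched_ids):
        inside = (scafs == reg.scaffold) & (mids >= reg.start) & (mids < reg.end)
        if not inside.any():
            warnings.warn(
                f"enriched region {reg.scaffold}:{reg.start}-{reg.end} "
                "contains no probe; dropped from ground truth"
            )
            continue
        enriched_mask |= inside
        kept_regions.append(reg)
        kept_ids.append(gid)

    base = rng.normal(0.0, params.noise_sd, size=len(meta))
    base[enriched_mask] += params.enrichment_mean
    df = meta.copy()
    for name in array_names:
        df[name] = base + rng.normal(0.0, params.replicate_noise_sd, size=len(meta))
    truth = GroundTruth(enriched_regions=kept_regions, enriched_gene_ids=kept_ids)
    return SignalTable(df), truth


def simulate_split_ests(
    scaffolds: list[Scaffold],
    genes: list[GeneModel],
    params: SimulationParams,
    enriched_gene_ids: list[str] | None = None,
):
    """ESTs split across scaffold pairs, 5' block at an enriched TSS.

    For each planted pair, ``ests_per_pair`` ESTs carry one block next to
    the TSS of an enriched gene on scaffold A and one block at a random
    position on scaffold B.  Decoy ESTs mapping to one or three scaffolds
    are mixed in.  Returns ``(ests, planted_links)`` where each planted
    link records the unordered scaffold pair and its EST ids.
    """
    if len(scaffolds) < 2:
        raise SimulationError("need at least 2 scaffolds for split ESTs")
    rng = _rng(params, 29)
    lengths = {sc.name: sc.length for sc in scaffolds}
    names = [sc.name for sc in scaffolds]
    if enriched_gene_ids is None:
        enriched_gene_ids = select_enriched_genes(genes, params)
    gene_by_id = {g.id: g for g in genes}
    candidates = [gene_by_id[g] for g in enriched_gene_ids]

    ests: list[ESTAlignment] = []
    planted_links: list[dict] = []
    used_pairs: set[tuple[str, str]] = set()
    block = 150
    for pi in range(params.n_split_est_pairs):
        pair = None
        for _ in range(200):
            gene = candidates[int(rng.integers(0, len(candidates)))]
            partner = names[int(rng.integers(0, len(names)))]
            if partner == gene.scaffold:
                continue
            key = tuple(sorted((gene.scaffold, partner)))
            if key in used_pairs:
                continue
            pair = (gene, partner, key)
            break
        if pair is None:
            raise SimulationError("could not find a fresh scaffold pair to plant")
        gene, partner, key = pair
        used_pairs.add(key)
        est_ids = []
        for j in range(params.ests_per_pair):
            jitter = int(rng.integers(0, 100))
            s5 = min(max(0, gene.tss + jitter), lengths[gene.scaffold] - block)
            s3 = int(rng.integers(0, lengths[partner] - block))
            est_id = f"est_pair{pi}_{j}"
            ests.append(
                ESTAlignment(
                    est_id=est_id,
                    blocks=tuple(sorted([
                        (gene.scaffold, s5, s5 + block),
                        (partner, s3, s3 + block),
                    ])),
                )
            )
            est_ids.append(est_id)
        planted_links.append(
            {"scaffold_a": key[0], "scaffold_b": key[1], "est_ids": est_ids}
        )

    # decoys: single-scaffold and three-scaffold ESTs (fail criterion 1)
    for di in range(params.n_split_est_pairs + 5):
        k = 1 if di % 2 == 0 else 3
        chosen = rng.choice(names, size=min(k, len(names)), replace=False)
        blocks = []
        for scaf in chosen:
            s = int(rng.integers(0, lengths[scaf] - block))
            blocks.append((scaf, s, s + block))
        ests.append(
            ESTAlignment(est_id=f"est_decoy{di}", blocks=tuple(sorted(blocks)))
        )
    return ests, planted_links
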