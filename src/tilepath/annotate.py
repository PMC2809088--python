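"""Relating peaks to genes, replicates, independent peak sets and ESTs.

Distances between intervals (and between an interval and a TSS) are
edge-to-edge gaps on half-open coordinates: a peak [s, e) and a TSS t
are 0 apart when s <= t < e, else ``t - e`` (downstream) or ``s - t``
(upstream).  "Within 1 kb" is inclusive (gap <= 1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .errors import DataError, TilepathError
from .types import ESTAlignment, GeneModel, Peak, Region, SignalTable, merge_intervals


@dataclass
class PeakAssociation:
    peak: Region
    gene_ids: list[str]  # nearest first
    min_distance: int | None  # None when no gene within the cutoff


@dataclass
class ScaffoldLink:
    """Two scaffolds joined by >=2 filtered ESTs, one side carrying a peak."""

    scaffold_a: str
    scaffold_b: str
    est_ids: list[str]
    peak_id: str
    peak_side: str  # "a" or "b"


def _gap_point(start: int, end: int, point: int) -> int:
    """Edge gap between half-open [start, end) and a point coordinate."""
    if point < start:
        return start - point
    if point >= end:
        return point - end
    return 0


def _gap_interval(s1: int, e1: int, s2: int, e2: int) -> int:
    """Edge gap between two half-open intervals (0 when overlapping)."""
    return max(0, s2 - e1, s1 - e2)


def associate_peaks(
    peaks: list[Region],
    genes: list[GeneModel],
    max_dist: int = 1000,
    anchor: str = "tss",
) -> list[PeakAssociation]:
    """Associate each peak with all genes within ``max_dist``.

    ``anchor`` selects the distance definition: "tss" measures peak edge
    to TSS (the "within 1 kb of the TSS" statistic); "gene" measures peak
    edge to the whole gene interval (the "within 1 kb of genes"
    statistic).  Qualifying genes are listed nearest first.
    """
    if anchor not in ("tss", "gene"):
        raise ValueError(f"unknown anchor {anchor!r}")
    genes_by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_scaffold.setdefault(g.scaffold, []).append(g)
    out = []
    for peak in peaks:
        hits = []
        for g in genes_by_scaffold.get(peak.scaffold, []):
            if anchor == "tss":
                d = _gap_point(peak.start, peak.end, g.tss)
            else:
                d = _gap_interval(peak.start, peak.end, g.start, g.end)
            if d <= max_dist:
                hits.append((d, g.id))
        hits.sort()
        out.append(
            PeakAssociation(
                peak=peak,
                gene_ids=[gid for _, gid in hits],
                min_distance=hits[0][0] if hits else None,
            )
        )
    return out


def fraction_near_genes(associations: list[PeakAssociation]):
    """Fraction of peaks with at least one associated gene.

    Returns ``(fraction, Fraction(hits, total))``.
    """
    if not associations:
        raise TilepathError("fraction undefined for zero peaks")
    hits = sum(1 for a in associations if a.gene_ids)
    return hits / len(associations), Fraction(hits, len(associations))


def _union_tree(regions: list[Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.scaffold, IntervalTree()).addi(r.start, r.end)
    for t in trees.values():
        t.merge_overlaps()
    return trees


def _overlap_bp(trees: dict[str, IntervalTree], region: Region) -> int:
    total = 0
    for iv in trees.get(region.scaffold, IntervalTree()).overlap(
        region.start, region.end
    ):
        total += min(iv.end, region.end) - max(iv.begin, region.start)
    return total


def overlap_fraction(
    peaks_a: list[Region], peaks_b: list[Region], min_overlap: int = 1
):
    """Fraction of peaks_a intersecting the union of peaks_b.

    A peak counts when its intersection with the union of peaks_b is at
    least ``min_overlap`` bp.  Returns ``(fraction, (n_overlapping,
    n_total))``.
    """
    if not peaks_a:
        raise TilepathError("overlap fraction undefined for empty peaks_a")
    trees = _union_tree(peaks_b)
    n_hit = sum(1 for p in peaks_a if _overlap_bp(trees, p) >= min_overlap)
    return n_hit / len(peaks_a), (n_hit, len(peaks_a))


class _Coverage:
    """Overlap-bp queries against the union of a region set, per scaffold."""

    def __init__(self, regions: list[Region]):
        grouped: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            grouped.setdefault(r.scaffold, []).append((r.start, r.end))
        self.per_scaffold = {}
        for scaf, ivals in grouped.items():
            merged = merge_intervals(ivals)
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self.per_scaffold[scaf] = (starts, ends, cum)

    def _cov(self, scaf: str, x: np.ndarray) -> np.ndarray:
        """Union bp covered in [0, x) for each coordinate in x."""
        if scaf not in self.per_scaffold:
            return np.zeros(len(x), dtype=np.int64)
        starts, ends, cum = self.per_scaffold[scaf]
        j = np.searchsorted(starts, x, side="right") - 1
        jj = np.maximum(j, 0)
        valid = j >= 0
        inside = np.clip(np.minimum(x, ends[jj]) - starts[jj], 0, None)
        return np.where(valid, cum[jj] + inside, 0)

    def overlap_bp(self, scaf: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self._cov(scaf, ends) - self._cov(scaf, starts)


def overlap_significance(
    peaks_a: list[Region],
    peaks_b: list[Region],
    scaffold_lengths: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 1,
) -> float:
    """Permutation p-value for the overlap count of peaks_a with peaks_b.

    peaks_a are re-placed uniformly at random within their own scaffolds
    (lengths preserved, overlaps among placed peaks allowed) ``n_perm``
    times; p = (1 + #permutations with count >= observed) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cov = _Coverage(peaks_b)
    by_scaffold: dict[str, list[int]] = {}
    for p in peaks_a:
        by_scaffold.setdefault(p.scaffold, []).append(p.end - p.start)
    observed = 0
    for p in peaks_a:
        bp = cov.overlap_bp(
            p.scaffold, np.array([p.start]), np.array([p.end])
        )[0]
        observed += int(bp >= min_overlap)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_perm, dtype=np.int64)
    for scaf, spans in by_scaffold.items():
        spans = np.asarray(spans, dtype=np.int64)
        limits = scaffold_lengths[scaf] - spans
        if (limits < 0).any():
            raise DataError(f"peak longer than scaffold {scaf}")
        # (n_perm, n_peaks) random placements, lengths preserved
        u = rng.random((n_perm, len(spans)))
        starts = (u * (limits + 1)).astype(np.int64)
        ends = starts + spans
        for k in range(n_perm):
            bp = cov.overlap_bp(scaf, starts[k], ends[k])
            counts[k] += int((bp >= min_overlap).sum())
    n_ge = int((counts >= observed).sum())
    return (1 + n_ge) / (1 + n_perm)


def per_peak_mean_signal(
    peaks: list[Region], table: SignalTable, array: str
):
    """Mean log2 ratio of the probes whose midpoint lies inside each peak.

    Returns ``(means, empty)``: ``means`` maps peak index -> mean value;
    ``empty`` lists indices of peaks containing no probe midpoint (these
    are excluded from downstream correlations).
    """
    values = table.values(array)
    df = table.df
    mids = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    scafs = df["scaffold"].to_numpy()
    means: dict[int, float] = {}
    empty: list[int] = []
    order = np.lexsort((mids, scafs))
    scafs_s, mids_s, vals_s = scafs[order], mids[order], values[order]
    for i, peak in enumerate(peaks):
        sel = scafs_s == peak.scaffold
        lo = np.searchsorted(mids_s[sel], peak.start, side="left")
        hi = np.searchsorted(mids_s[sel], peak.end - 1, side="right")
        chunk = vals_s[sel][lo:hi]
        if chunk.size == 0:
            empty.append(i)
        else:
            means[i] = float(chunk.mean())
    return means, empty


def correlate_tracks(values_a, values_b, method: str = "pearson"):
    """Correlation coefficient and two-sided p-value for two tracks."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise DataError("tracks must be equal-length 1-D with n >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DataError("tracks contain non-finite values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("correlation undefined for zero-variance track")
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def tss_profile(
    table: SignalTable,
    array: str,
    genes: list[GeneModel],
    flank_bp: int = 5000,
    bin_bp: int = 250,
):
    """Mean signal around the TSS, strand-oriented, averaged across genes.

    Probe values are binned by the offset of the probe midpoint from the
    TSS (negated for - strand genes so that positive offsets always point
    downstream of transcription).  Per-gene bin means are averaged across
    genes.  Returns ``(bin_mids, mean_signal, n_genes_per_bin)``.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    edges = np.arange(-flank_bp, flank_bp + 1, bin_bp)
    bin_mids = (edges[:-1] + edges[1:]) / 2.0
    values = table.values(array)
    df = table.df
    mids = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
    scafs = df["scaffold"].to_numpy()
    sums = np.zeros(n_bins)
    gene_counts = np.zeros(n_bins, dtype=int)
    for gene in genes:
        sel = scafs == gene.scaffold
        offs = mids[sel] - gene.tss
        if gene.strand == "-":
            offs = -offs
        inside = (offs >= -flank_bp) & (offs < flank_bp)
        if not inside.any():
            continue
        idx = (offs[inside] + flank_bp) // bin_bp
        vals = values[sel][inside]
        gsum = np.bincount(idx, weights=vals, minlength=n_bins)
        gcount = np.bincount(idx, minlength=n_bins)
        has = gcount > 0
        sums[has] += gsum[has] / gcount[has]
        gene_counts[has] += 1
    mean_signal = np.full(n_bins, np.nan)
    nonzero = gene_counts > 0
    mean_signal[nonzero] = sums[nonzero] / gene_counts[nonzero]
    return bin_mids, mean_signal, gene_counts


def link_orphan_scaffolds(
    ests: list[ESTAlignment], peaks: list[Region], max_dist: int = 1000
) -> list[ScaffoldLink]:
    """Join scaffold pairs via split ESTs anchored by an enrichment peak.

    An EST passes when (1) its blocks map to exactly two scaffolds and
    (2) some peak lies within ``max_dist`` (edge-to-edge) of one of its
    blocks.  Unordered scaffold pairs with at least two passing ESTs
    become links; the nearest qualifying peak and its side are recorded.
    """
    peaks_by_scaffold: dict[str, list[tuple[Region, int]]] = {}
    for i, p in enumerate(peaks):
        peaks_by_scaffold.setdefault(p.scaffold, []).append((p, i))

    passing: dict[tuple[str, str], list[tuple[str, int, str, int]]] = {}
    for est in ests:
        scaffolds = sorted(est.scaffolds)
        if len(scaffolds) != 2:
            continue
        best = None  # (distance, peak_index, side)
        for scaf, s, e in est.blocks:
            side = "a" if scaf == scaffolds[0] else "b"
            for peak, pidx in peaks_by_scaffold.get(scaf, []):
                d = _gap_interval(s, e, peak.start, peak.end)
                if d <= max_dist and (best is None or d < best[0]):
                    best = (d, pidx, side)
        if best is not None:
            key = (scaffolds[0], scaffolds[1])
            passing.setdefault(key, []).append(
                (est.est_id, best[1], best[2], best[0])
            )

    links = []
    for (sa, sb), records in sorted(passing.items()):
        if len(records) < 2:
            continue
        _, pidx, side, _ = min(records, key=lambda r: r[3])
        peak = peaks[pidx]
        links.append(
            ScaffoldLink(
                scaffold_a=sa,
                scaffold_b=sb,
                est_ids=sorted(r[0] for r in records),
                peak_id=f"{peak.scaffold}:{peak.start}-{peak.end}",
                peak_side=side,
            )
        )
    assert all(len(link.est_ids) >= 2 for link in links)
    return links
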