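"""Peak-gene association, overlap statistics, profiles and EST links."""

import numpy as np
import pytest
from scipy import stats

from tilepath.annotate import (
    associate_peaks,
    correlate_tracks,
    fraction_near_genes,
    link_orphan_scaffolds,
    overlap_fraction,
    overlap_significance,
    per_peak_mean_signal,
    tss_profile,
)
from tilepath.errors import DataError, TilepathError
from tilepath.types import ESTAlignment, GeneModel, Region

from conftest import make_track


def _peak(start, end, scaf="s1"):
    return Region(scaffold=scaf, start=start, end=end, source="h3k4me3_peak")


def _gene(tss, scaf="s1", strand="+", length=3000, gid="g"):
    if strand == "+":
        return GeneModel(id=gid, scaffold=scaf, strand="+", start=tss,
                         end=tss + length)
    return GeneModel(id=gid, scaffold=scaf, strand="-", start=tss - length + 1,
                     end=tss + 1)


class TestAssociation:
    @pytest.mark.parametrize(
        "tss,expected_dist",
        [(2400, 900), (2500, 1000), (2501, None), (1200, 0)],
    )
    def test_distance_boundaries(self, tss, expected_dist):
        (assoc,) = associate_peaks([_peak(1000, 1500)], [_gene(tss)], max_dist=1000)
        assert assoc.min_distance == expected_dist
        assert bool(assoc.gene_ids) == (expected_dist is not None)

    def test_qualifying_genes_listed_nearest_first(self):
        genes = [_gene(2400, gid="far"), _gene(1600, gid="near")]
        (assoc,) = associate_peaks([_peak(1000, 1500)], genes)
        assert assoc.gene_ids == ["near", "far"]

    def test_gene_anchor_uses_whole_interval(self):
        # gene body reaches to 5000; TSS far away at 2000 on + strand
        gene = GeneModel(id="g", scaffold="s1", strand="+", start=2000, end=5000)
        (by_tss,) = associate_peaks([_peak(5500, 6000)], [gene], anchor="tss")
        (by_gene,) = associate_peaks([_peak(5500, 6000)], [gene], anchor="gene")
        assert by_tss.gene_ids == [] and by_gene.gene_ids == ["g"]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(41)
        for anchor in ("tss", "gene"):
            peaks = [
                _peak(int(s), int(s) + int(rng.integers(100, 2000)))
                for s in rng.integers(0, 80_000, 30)
            ]
            genes = [
                _gene(int(t), strand="+" if rng.random() < 0.5 else "-",
                      gid=f"g{i}")
                for i, t in enumerate(rng.integers(3000, 80_000, 40))
            ]
            got = associate_peaks(peaks, genes, max_dist=1000, anchor=anchor)
            for assoc in got:
                p = assoc.peak
                expected = []
                for g in genes:
                    if anchor == "tss":
                        t = g.tss
                        d = 0 if p.start <= t < p.end else (
                            t - p.end if t >= p.end else p.start - t
                        )
                    else:
                        d = max(0, g.start - p.end, p.start - g.end)
                    if d <= 1000:
                        expected.append((d, g.id))
                expected.sort()
                assert assoc.gene_ids == [gid for _, gid in expected]

    def test_translation_invariance(self):
        peaks = [_peak(1000, 1500)]
        genes = [_gene(2400)]
        shift = 12_345
        shifted_peaks = [_peak(1000 + shift, 1500 + shift)]
        shifted_genes = [_gene(2400 + shift)]
        a = associate_peaks(peaks, genes)[0]
        b = associate_peaks(shifted_peaks, shifted_genes)[0]
        assert (a.gene_ids, a.min_distance) == (b.gene_ids, b.min_distance)


class TestFractionNearGenes:
    def test_hand_count_on_ten_peak_fixture(self):
        peaks = [_peak(i * 10_000, i * 10_000 + 500) for i in range(10)]
        genes = [_gene(i * 10_000 + 700, gid=f"g{i}") for i in range(7)]
        frac, exact = fraction_near_genes(associate_peaks(peaks, genes))
        assert frac == pytest.approx(0.7)
        assert (exact.numerator, exact.denominator) == (7, 10)

    def test_all_associated_gives_one(self):
        peaks = [_peak(0, 500)]
        frac, _ = fraction_near_genes(associate_peaks(peaks, [_gene(600)]))
        assert frac == 1.0

    def test_zero_peaks_undefined(self):
        with pytest.raises(TilepathError):
            fraction_near_genes([])


class TestOverlap:
    def test_half_open_one_bp_boundary(self):
        frac, _ = overlap_fraction([_peak(0, 100)], [_peak(99, 200)])
        assert frac == 1.0
        frac, _ = overlap_fraction([_peak(0, 100)], [_peak(100, 200)])
        assert frac == 0.0

    def test_self_overlap_is_identity(self):
        rng = np.random.default_rng(42)
        peaks = [_peak(int(s), int(s) + 200) for s in rng.integers(0, 50_000, 20)]
        frac, (n, total) = overlap_fraction(peaks, peaks)
        assert frac == 1.0 and n == total == 20

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            a = [_peak(int(s), int(s) + int(rng.integers(50, 800)))
                 for s in rng.integers(0, 20_000, 15)]
            b = [_peak(int(s), int(s) + int(rng.integers(50, 800)))
                 for s in rng.integers(0, 20_000, 15)]
            frac, (n, _) = overlap_fraction(a, b)
            expected = sum(
                1 for pa in a
                if any(min(pa.end, pb.end) - max(pa.start, pb.start) >= 1
                       for pb in b)
            )
            assert n == expected

    def test_min_overlap_respected(self):
        frac, _ = overlap_fraction([_peak(0, 100)], [_peak(90, 200)],
                                   min_overlap=10)
        assert frac == 1.0
        frac, _ = overlap_fraction([_peak(0, 100)], [_peak(91, 200)],
                                   min_overlap=10)
        assert frac == 0.0


class TestOverlapSignificance:
    def test_identical_sets_give_minimal_p(self):
        rng = np.random.default_rng(44)
        peaks = [_peak(int(s), int(s) + 300)
                 for s in rng.integers(0, 900_000, 10)]
        p = overlap_significance(peaks, peaks, {"s1": 1_000_000},
                                 n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_empty_reference_gives_p_one(self):
        p = overlap_significance([_peak(0, 100)], [], {"s1": 10_000},
                                 n_perm=100, seed=0)
        assert p == 1.0

    def test_null_pvalues_superuniform(self):
        """Under the null, P(p <= x) should not exceed x by more than
        Monte-Carlo error (spot check at a few quantiles)."""
        rng = np.random.default_rng(45)
        L = 500_000
        pvals = []
        for i in range(120):
            b = [_peak(int(s), int(s) + 1500)
                 for s in rng.integers(0, L - 1500, 80)]
            a = [_peak(int(s), int(s) + 800)
                 for s in rng.integers(0, L - 800, 150)]
            pvals.append(
                overlap_significance(a, b, {"s1": L}, n_perm=199,
                                     seed=int(rng.integers(0, 2**31)))
            )
        pvals = np.array(pvals)
        for x in (0.05, 0.25, 0.5):
            assert (pvals <= x).mean() <= x + 3 * np.sqrt(x * (1 - x) / 120)


class TestPerPeakSignal:
    def test_mean_of_contained_probes(self):
        t = make_track([1.0, 2.0, 3.0])
        means, empty = per_peak_mean_signal([_peak(0, 300)], t, "a")
        assert means[0] == pytest.approx(2.0) and empty == []

    def test_single_probe_peak(self):
        t = make_track([1.0, 2.0, 3.0])
        means, _ = per_peak_mean_signal([_peak(90, 160)], t, "a")
        assert means[0] == pytest.approx(2.0)  # only probe 1's midpoint inside

    def test_probeless_peak_flagged(self):
        t = make_track([1.0, 2.0])
        means, empty = per_peak_mean_signal([_peak(5000, 6000)], t, "a")
        assert means == {} and empty == [0]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(46)
        t = make_track(rng.normal(size=100))
        peaks = [_peak(int(s), int(s) + int(rng.integers(100, 2000)))
                 for s in rng.integers(0, 9000, 15)]
        means, empty = per_peak_mean_signal(peaks, t, "a")
        df, vals = t.df, t.values("a")
        for i, p in enumerate(peaks):
            expected = [
                vals[j] for j in range(len(df))
                if p.start <= (df["start"].iat[j] + df["end"].iat[j]) // 2 < p.end
            ]
            if expected:
                assert means[i] == pytest.approx(np.mean(expected))
            else:
                assert i in empty


class TestCorrelation:
    def test_identical_vectors(self):
        r, p = correlate_tracks([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_rank_invariance_of_spearman(self):
        x = np.linspace(1, 5, 20)
        y = np.exp(x)  # monotone, nonlinear
        rs, _ = correlate_tracks(x, y, "spearman")
        rp, _ = correlate_tracks(x, y, "pearson")
        assert rs == pytest.approx(1.0) and rp < 1.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            a = rng.normal(size=30)
            b = 0.5 * a + rng.normal(size=30)
            r, _ = correlate_tracks(a, b, "pearson")
            am, bm = a - a.mean(), b - b.mean()
            expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
            assert r == pytest.approx(expected, abs=1e-12)
            rs, _ = correlate_tracks(a, b, "spearman")
            ra, rb = stats.rankdata(a), stats.rankdata(b)
            ram, rbm = ra - ra.mean(), rb - rb.mean()
            assert rs == pytest.approx(
                (ram @ rbm) / np.sqrt((ram @ ram) * (rbm @ rbm)), abs=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            correlate_tracks([1, 1, 1, 1], [1, 2, 3, 4])


class TestTssProfile:
    def test_constant_signal_gives_flat_profile(self):
        t = make_track([0.7] * 100)
        genes = [_gene(3000, gid="g1"), _gene(6000, strand="-", gid="g2")]
        _, mean_signal, counts = tss_profile(t, "a", genes, 2000, 500)
        observed = mean_signal[counts > 0]
        assert np.allclose(observed, 0.7)

    def test_strand_flip_orients_downstream(self):
        """Enrichment only in [TSS, TSS+500) on both strands shows up on
        the positive-offset side after orientation."""
        vals = np.zeros(100)
        plus_tss, minus_tss = 3000, 7000
        for i in range(100):
            mid = i * 100 + 25
            if plus_tss <= mid < plus_tss + 500:
                vals[i] = 2.0
            if minus_tss - 500 < mid <= minus_tss:  # downstream of - gene
                vals[i] = 2.0
        t = make_track(vals)
        genes = [_gene(plus_tss, gid="gp"),
                 _gene(minus_tss, strand="-", gid="gm")]
        mids, mean_signal, counts = tss_profile(t, "a", genes, 2000, 250)
        down = mean_signal[(mids > 0) & (mids < 500)]
        up = mean_signal[(mids < 0) & (mids > -500)]
        assert np.nanmean(down) > np.nanmean(up) + 1.0

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(48)
        t = make_track(rng.normal(size=200))
        genes = [
            _gene(int(tss), strand="+" if rng.random() < 0.5 else "-",
                  gid=f"g{i}")
            for i, tss in enumerate(rng.integers(4000, 16_000, 8))
        ]
        flank, binw = 2000, 500
        mids, mean_signal, counts = tss_profile(t, "a", genes, flank, binw)
        df, vals = t.df, t.values("a")
        n_bins = 2 * flank // binw
        per_gene = []
        for g in genes:
            sums = np.zeros(n_bins)
            ns = np.zeros(n_bins)
            for j in range(len(df)):
                off = (df["start"].iat[j] + df["end"].iat[j]) // 2 - g.tss
                if g.strand == "-":
                    off = -off
                if -flank <= off < flank:
                    b = (off + flank) // binw
                    sums[b] += vals[j]
                    ns[b] += 1
            with np.errstate(invalid="ignore"):
                per_gene.append(np.where(ns > 0, sums / np.maximum(ns, 1), np.nan))
        per_gene = np.array(per_gene)
        for b in range(n_bins):
            col = per_gene[:, b]
            expected_n = int(np.sum(~np.isnan(col)))
            assert counts[b] == expected_n
            if expected_n:
                assert mean_signal[b] == pytest.approx(np.nanmean(col))

    def test_planted_promoter_signal_peaks_at_tss(self, default_fixture):
        """On simulated data the profile maximum sits within one bin of
        the planted plateau center (the TSS)."""
        fx = default_fixture
        gene_by_id = {g.id: g for g in fx["genes"]}
        enriched = [gene_by_id[g] for g in fx["truth"].enriched_gene_ids]
        mids, mean_signal, counts = tss_profile(
            fx["table"], "rep1", enriched, 4000, 250
        )
        peak_bin = np.nanargmax(mean_signal)
        assert abs(mids[peak_bin]) <= 250  # plateau centered on the TSS


class TestOrphanLinks:
    def test_constructed_pair_with_peak_on_one_side(self):
        ests = [
            ESTAlignment(est_id=f"e{i}",
                         blocks=(("s5", 1000, 1200), ("s9", 500, 700)))
            for i in range(2)
        ]
        peaks = [_peak(1400, 1600, scaf="s5")]  # 200 bp from the s5 block
        (link,) = link_orphan_scaffolds(ests, peaks)
        assert (link.scaffold_a, link.scaffold_b) == ("s5", "s9")
        assert link.est_ids == ["e0", "e1"] and link.peak_side == "a"

    def test_three_scaffold_est_excluded(self):
        ests = [
            ESTAlignment(
                est_id=f"e{i}",
                blocks=(("s1", 100, 200), ("s2", 100, 200), ("s3", 100, 200)),
            )
            for i in range(3)
        ]
        assert link_orphan_scaffolds(ests, [_peak(150, 250, scaf="s1")]) == []

    def test_single_est_pair_not_linked(self):
        ests = [ESTAlignment(est_id="only",
                             blocks=(("s5", 1000, 1200), ("s9", 500, 700)))]
        assert link_orphan_scaffolds(ests, [_peak(1000, 1200, scaf="s5")]) == []

    def test_peak_beyond_one_kb_fails_criterion_two(self):
        ests = [
            ESTAlignment(est_id=f"e{i}",
                         blocks=(("s5", 1000, 1200), ("s9", 500, 700)))
            for i in range(2)
        ]
        far = [_peak(2201, 2400, scaf="s5")]  # gap 1001
        near = [_peak(2200, 2400, scaf="s5")]  # gap 1000, inclusive
        assert link_orphan_scaffolds(ests, far) == []
        assert len(link_orphan_scaffolds(ests, near)) == 1

    def test_recovers_planted_links_exactly(self, default_fixture):
        """End-to-end truth recovery against a brute-force filter+group
        oracle on the simulated split-scaffold fixture."""
        fx = default_fixture
        peaks = fx["truth"].enriched_regions
        links = link_orphan_scaffolds(fx["ests"], peaks)
        got = sorted((l.scaffold_a, l.scaffold_b) for l in links)
        planted = sorted(
            (l["scaffold_a"], l["scaffold_b"]) for l in fx["planted_links"]
        )
        assert got == planted
        # independent oracle: quadratic filter + group
        passing = {}
        for est in fx["ests"]:
            scafs = sorted({s for s, _, _ in est.blocks})
            if len(scafs) != 2:
                continue
            near = False
            for scaf, s, e in est.blocks:
                for pk in peaks:
                    if pk.scaffold == scaf and max(0, pk.start - e, s - pk.end) <= 1000:
                        near = True
            if near:
                passing.setdefault(tuple(scafs), []).append(est.est_id)
        oracle = sorted(k for k, v in passing.items() if len(v) >= 2)
        assert got == oracle
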