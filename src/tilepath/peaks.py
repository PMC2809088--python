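"""Sliding-window peak detection with randomization-calibrated FDR.

The detector scans runs of consecutive probes (same scaffold, adjacent
starts at most ``max_probe_gap`` apart).  A window of ``window_len``
consecutive probes qualifies when every probe value meets the threshold;
overlapping qualifying windows are unioned into one peak.  Several window
lengths with their own thresholds are scanned so that small high peaks
and broader low peaks are both caught.

Thresholds are calibrated against randomized probes: the array's values
are permuted once, detection is repeated on real and randomized data over
an increasing threshold grid, and the smallest threshold whose
randomized/real peak-count ratio (the theoretical FDR) falls below the
target is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigurationError, DataError
from .types import Peak, SignalTable


def _default_grid() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.1, 4.0 + 1e-9, 0.1), 10))


@dataclass
class PeakCallParams:
    """Detection, calibration and post-processing parameters.

    Thresholds are log2-ratio units.  ``thresholds`` maps window length to
    its threshold; leave None to calibrate from ``threshold_grid``.
    """

    window_lengths: tuple[int, ...] = (3, 4, 5)
    thresholds: dict | None = None
    fdr_target: float = 0.10
    threshold_grid: tuple[float, ...] = field(default_factory=_default_grid)
    max_probe_gap: int = 500
    merge_gap: int = 1500
    min_probes_per_peak: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr_target < 1:
            raise ConfigurationError("fdr_target must be in (0, 1)")
        if any(w < 2 for w in self.window_lengths):
            raise ConfigurationError("window lengths must be >= 2")
        if list(self.threshold_grid) != sorted(set(self.threshold_grid)):
            raise ConfigurationError("threshold_grid must be strictly increasing")


def _probe_runs(table: SignalTable, max_probe_gap: int):
    """Yield (global index array) for each run of consecutive probes."""
    df = table.df
    starts = df["start"].to_numpy()
    scafs = df["scaffold"].to_numpy()
    n = len(df)
    if n == 0:
        return
    breaks = np.flatnonzero(
        (scafs[1:] != scafs[:-1]) | (starts[1:] - starts[:-1] > max_probe_gap)
    )
    bounds = np.concatenate([[0], breaks + 1, [n]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        yield np.arange(lo, hi)


def _peak_from_span(table: SignalTable, values: np.ndarray, lo: int, hi: int) -> Peak:
    """Build a Peak from the probes at global indices [lo, hi]."""
    df = table.df
    vals = values[lo : hi + 1]
    return Peak(
        scaffold=df["scaffold"].iat[lo],
        start=int(df["start"].iat[lo]),
        end=int(df["end"].iat[hi]),
        score=float(vals.mean()),
        source="h3k4me3_peak",
        n_probes=hi - lo + 1,
        mean_signal=float(vals.mean()),
        max_signal=float(vals.max()),
        first_probe=lo,
        last_probe=hi,
    )


def sliding_window_detect(
    table: SignalTable,
    array: str,
    window_len: int,
    threshold: float,
    max_probe_gap: int = 500,
) -> list[Peak]:
    """Detect peaks on one array with a single window length.

    A window of ``window_len`` consecutive probes (no inter-probe start
    gap above ``max_probe_gap``) qualifies when every value is >= the
    threshold; overlapping qualifying windows union into one peak whose
    interval spans first probe start to last probe end.
    """
    if window_len < 2:
        raise ConfigurationError("window_len must be >= 2")
    values = table.values(array)
    peaks = []
    for run in _probe_runs(table, max_probe_gap):
        ok = values[run] >= threshold
        if len(run) < window_len:
            continue
        # ok_win[i]: all of ok[i : i + window_len]
        c = np.concatenate([[0], np.cumsum(ok)])
        ok_win = (c[window_len:] - c[:-window_len]) == window_len
        starts = np.flatnonzero(ok_win)
        if starts.size == 0:
            continue
        # union overlapping windows: windows i and j (i<j) overlap when
        # j <= i + window_len - 1
        gaps = np.flatnonzero(np.diff(starts) > window_len - 1)
        lo_idx = np.concatenate([[0], gaps + 1])
        hi_idx = np.concatenate([gaps, [len(starts) - 1]])
        for a, b in zip(starts[lo_idx], starts[hi_idx]):
            lo = int(run[a])
            hi = int(run[b + window_len - 1])
            peaks.append(_peak_from_span(table, values, lo, hi))
    peaks.sort(key=lambda p: (p.scaffold, p.start))
    return peaks


def detect_multi_window(
    table: SignalTable, array: str, params: PeakCallParams
) -> list[Peak]:
    """Union of per-window detections with overlapping peaks merged.

    Statistics of merged peaks are recomputed from their constituent
    probes, not averaged from the inputs.
    """
    if params.thresholds is None:
        raise ConfigurationError("thresholds not configured; calibrate first")
    missing = [w for w in params.window_lengths if w not in params.thresholds]
    if missing:
        raise ConfigurationError(f"no threshold for window length(s) {missing}")
    values = table.values(array)
    all_peaks = []
    for w in params.window_lengths:
        all_peaks.extend(
            sliding_window_detect(
                table, array, w, params.thresholds[w], params.max_probe_gap
            )
        )
    all_peaks.sort(key=lambda p: (p.scaffold, p.start))
    merged: list[Peak] = []
    for peak in all_peaks:
        if (
            merged
            and peak.scaffold == merged[-1].scaffold
            and peak.start < merged[-1].end
        ):
            lo = min(merged[-1].first_probe, peak.first_probe)
            hi = max(merged[-1].last_probe, peak.last_probe)
            merged[-1] = _peak_from_span(table, values, lo, hi)
        else:
            merged.append(peak)
    return merged


def randomize_probes(table: SignalTable, array: str, seed: int) -> SignalTable:
    """Permute one array's values uniformly across probe positions."""
    rng = np.random.default_rng(seed)
    return table.with_values(array, rng.permutation(table.values(array)))


def calibrate_threshold(
    table: SignalTable, array: str, window_len: int, params: PeakCallParams
):
    """Find the smallest grid threshold with theoretical FDR below target.

    The array is randomized once (at ``params.rng_seed``) and detection is
    run on real and randomized values at each grid threshold in increasing
    order.  Returns ``(threshold, fdr_estimate, trace)`` where the trace
    lists ``(threshold, n_real, n_random, ratio)`` for every evaluated
    threshold.  Raises CalibrationError if no real peaks remain before the
    target is met or the grid is exhausted.
    """
    if not params.threshold_grid:
        raise ConfigurationError("empty threshold grid")
    randomized = randomize_probes(table, array, params.rng_seed)
    trace = []
    best_ratio = None
    for t in params.threshold_grid:
        n_real = len(
            sliding_window_detect(table, array, window_len, t, params.max_probe_gap)
        )
        n_rand = len(
            sliding_window_detect(randomized, array, window_len, t, params.max_probe_gap)
        )
        if n_real == 0:
            raise CalibrationError(
                f"no real peaks left at threshold {t:g} before reaching "
                f"FDR target {params.fdr_target:g}; best ratio reached: "
                f"{best_ratio}",
                best_ratio=best_ratio,
                trace=trace,
            )
        ratio = n_rand / n_real
        trace.append((float(t), n_real, n_rand, ratio))
        if best_ratio is None or ratio < best_ratio:
            best_ratio = ratio
        if ratio < params.fdr_target:
            return float(t), ratio, trace
    raise CalibrationError(
        f"no grid threshold reaches FDR target {params.fdr_target:g}; "
        f"best ratio reached: {best_ratio}",
        best_ratio=best_ratio,
        trace=trace,
    )


def calibrate_all_windows(
    table: SignalTable, array: str, params: PeakCallParams
) -> dict[int, float]:
    """Calibrate a threshold for every configured window length."""
    return {
        w: calibrate_threshold(table, array, w, params)[0]
        for w in params.window_lengths
    }


def remove_single_probe_peaks(peaks: list[Peak], min_probes: int = 2) -> list[Peak]:
    """Drop peaks supported by fewer than ``min_probes`` probes."""
    return [p for p in peaks if p.n_probes >= min_probes]


def merge_peaks_within(peaks: list[Peak], merge_gap: int = 1500) -> list[Peak]:
    """Merge peaks on one scaffold whose inter-peak gap is <= merge_gap.

    Merging is transitive; merged peaks sum probe counts, recompute the
    mean probe-weighted, and take the max of maxima.
    """
    ordered = sorted(peaks, key=lambda p: (p.scaffold, p.start))
    out: list[Peak] = []
    for peak in ordered:
        prev = out[-1] if out else None
        if prev is not None and peak.scaffold == prev.scaffold and (
            peak.start - prev.end <= merge_gap
        ):
            n = prev.n_probes + peak.n_probes
            mean = (
                prev.mean_signal * prev.n_probes + peak.mean_signal * peak.n_probes
            ) / n
            out[-1] = Peak(
                scaffold=prev.scaffold,
                start=prev.start,
                end=max(prev.end, peak.end),
                score=mean,
                source="h3k4me3_peak",
                n_probes=n,
                mean_signal=mean,
                max_signal=max(prev.max_signal, peak.max_signal),
                first_probe=min(prev.first_probe, peak.first_probe),
                last_probe=max(prev.last_probe, peak.last_probe),
            )
        else:
            out.append(peak)
    return out


def consensus_peaks(
    table: SignalTable, arrays: list[str], params: PeakCallParams
) -> list[Peak]:
    """Replicate-consensus pipeline: average arrays, detect, post-filter.

    Probe values are averaged across the named arrays; multi-window
    detection, single-probe removal and gap merging are applied in that
    order.  When ``params.thresholds`` is None, thresholds are calibrated
    on the averaged track first.
    """
    if not arrays:
        raise ConfigurationError("no arrays named for consensus")
    for a in arrays:
        if a not in table.arrays:
            raise DataError(f"unknown array {a!r}")
    mean_vals = np.mean([table.values(a) for a in arrays], axis=0)
    df = table.df[SignalTable.META_COLS].copy()
    df["consensus"] = mean_vals
    consensus = SignalTable(df)
    if params.thresholds is None:
        thresholds = calibrate_all_windows(consensus, "consensus", params)
        params = PeakCallParams(
            window_lengths=params.window_lengths,
            thresholds=thresholds,
            fdr_target=params.fdr_target,
            threshold_grid=params.threshold_grid,
            max_probe_gap=params.max_probe_gap,
            merge_gap=params.merge_gap,
            min_probes_per_peak=params.min_probes_per_peak,
            rng_seed=params.rng_seed,
        )
    peaks = detect_multi_window(consensus, "consensus", params)
    peaks = remove_single_probe_peaks(peaks, params.min_probes_per_peak)
    return merge_peaks_within(peaks, params.merge_gap)
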