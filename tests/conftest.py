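"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by enumeration or naive
scanning, independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tilepath.peaks import PeakCallParams, consensus_peaks
from tilepath.simulate import (
    SimulationParams,
    grid_probes,
    simulate_genome,
    simulate_signals,
    simulate_split_ests,
)
from tilepath.types import SignalTable


# ------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_fixture():
    """Full synthetic fixture set at generator defaults, seed 0."""
    params = SimulationParams(seed=0)
    scaffolds, genes = simulate_genome(params)
    probes = grid_probes({sc.name: sc.length for sc in scaffolds})
    table, truth = simulate_signals(scaffolds, genes, probes, params)
    ests, planted_links = simulate_split_ests(
        scaffolds, genes, params, truth.enriched_gene_ids
    )
    return {
        "params": params,
        "scaffolds": scaffolds,
        "genes": genes,
        "probes": probes,
        "table": table,
        "truth": truth,
        "ests": ests,
        "planted_links": planted_links,
    }


@pytest.fixture(scope="session")
def default_consensus_peaks(default_fixture):
    return consensus_peaks(
        default_fixture["table"], ["rep1", "rep2"], PeakCallParams(rng_seed=0)
    )


def make_track(values, spacing=100, probe_len=50, scaffold="s1", start0=0):
    """SignalTable with one array ('a') on an even probe grid."""
    rows = {
        "probe_id": [f"{scaffold}:{start0 + i * spacing}" for i in range(len(values))],
        "scaffold": [scaffold] * len(values),
        "start": [start0 + i * spacing for i in range(len(values))],
        "end": [start0 + i * spacing + probe_len for i in range(len(values))],
        "a": list(values),
    }
    return SignalTable(pd.DataFrame(rows))


def random_track(rng, n_probes=80, n_scaffolds=2, gappy=True):
    """Random multi-scaffold track with occasional large probe gaps."""
    rows = []
    for si in range(n_scaffolds):
        pos = 0
        for i in range(n_probes // n_scaffolds):
            step = 100
            if gappy and rng.random() < 0.07:
                step = int(rng.integers(600, 3000))
            pos += step
            rows.append((f"s{si}", pos, pos + 50, float(rng.normal(0.5, 1.0))))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "a"])
    df.insert(0, "probe_id", [f"p{i}" for i in range(len(df))])
    return SignalTable(df)


# -------------------------------------------------------------- oracles

def _qualifying_windows(table, array, window_len, threshold, max_probe_gap):
    """Enumerate every qualifying window as a frozenset of probe indices."""
    df = table.df
    vals = table.values(array)
    n = len(df)
    windows = []
    for i in range(n - window_len + 1):
        idx = list(range(i, i + window_len))
        if len({df["scaffold"].iat[j] for j in idx}) != 1:
            continue
        starts = [df["start"].iat[j] for j in idx]
        if any(b - a > max_probe_gap for a, b in zip(starts, starts[1:])):
            continue
        if all(vals[j] >= threshold for j in idx):
            windows.append(frozenset(idx))
    return windows


def _union_overlapping_windows(df, windows):
    """Connected components of probe-sharing windows -> peak tuples."""
    merged = []
    for win in sorted(windows, key=min):
        if merged and merged[-1] & win:
            merged[-1] = merged[-1] | win
        else:
            merged.append(set(win))
    # windows are intervals of consecutive indices, so a min-sorted sweep
    # finds all components; verify no residual overlap
    for a, b in zip(merged, merged[1:]):
        assert not (a & b)
    out = []
    for comp in merged:
        lo, hi = min(comp), max(comp)
        out.append(
            (
                df["scaffold"].iat[lo],
                int(df["start"].iat[lo]),
                int(df["end"].iat[hi]),
                hi - lo + 1,
            )
        )
    return sorted(out)


def brute_force_peaks(table, array, window_len, threshold, max_probe_gap=500):
    """Exhaustive window enumeration; overlapping windows union into one
    peak.  Independent of the detector.  Returns sorted
    (scaffold, start, end, n_probes) tuples."""
    windows = _qualifying_windows(table, array, window_len, threshold, max_probe_gap)
    return _union_overlapping_windows(table.df, windows)


def brute_force_multi_window(table, array, params):
    """Pooled brute-force windows over all configured window lengths."""
    windows = []
    for w in params.window_lengths:
        windows.extend(
            _qualifying_windows(
                table, array, w, params.thresholds[w], params.max_probe_gap
            )
        )
    return _union_overlapping_windows(table.df, windows)


def peak_tuples(peaks):
    return sorted((p.scaffold, p.start, p.end, p.n_probes) for p in peaks)


def naive_occurrence_count(genome_seqs, target):
    """Sliding string comparison; counts overlapping occurrences."""
    count = 0
    for seq in genome_seqs:
        for i in range(len(seq) - len(target) + 1):
            if seq[i : i + len(target)] == target:
                count += 1
    return count
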