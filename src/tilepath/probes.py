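"""Isothermal tiling-probe selection and uniqueness filtering.

Probes of variable length (50-75 bp by default) are anchored on a fixed
grid (one anchor every ``spacing`` bp of unmasked sequence) and, at each
anchor, the length whose predicted melting temperature is closest to the
isothermal target (76 degrees C) is kept.  Variable length equalizes
hybridization behaviour across the array.

The Tm model is the unified nearest-neighbor thermodynamic parameter set
with the entropy-based monovalent-salt correction:

    Tm(K) = 1000 * dH / (dS + 0.368 * (L - 1) * ln[Na+] + R * ln(C/4))

with dH (kcal/mol) and dS (cal/mol/K) summed over dinucleotide stacks
plus terminal initiation terms, R = 1.987 cal/mol/K, and C the probe
concentration (excess-probe hybridization, hence C/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .types import Scaffold, SignalTable

_R = 1.987  # gas constant, cal/(mol*K)

# unified NN stack parameters, indexed by 4*code(b1)+code(b2) with
# A=0, C=1, G=2, T=3.  dH in kcal/mol, dS in cal/(mol*K).
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

_NN_DH = np.zeros(16)
_NN_DS = np.zeros(16)
for _pair, (_dh, _ds) in _NN.items():
    _idx = 4 * _CODE[_pair[0]] + _CODE[_pair[1]]
    _NN_DH[_idx] = _dh
    _NN_DS[_idx] = _ds

# terminal initiation by end base (A/T vs G/C)
_INIT_DH = np.array([2.3, 0.1, 0.1, 2.3])
_INIT_DS = np.array([4.1, -2.8, -2.8, 4.1])

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TilingParams:
    """Isothermal tiling parameters (lengths in bp, Tm in deg C, conc in M)."""

    min_len: int = 50
    max_len: int = 75
    target_tm: float = 76.0
    spacing: int = 100
    na_conc: float = 0.05
    probe_conc: float = 2.5e-7

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.spacing < 1:
            raise ValueError("spacing must be >= 1")


@dataclass
class Probe:
    """A tiling oligo: genome slice, predicted Tm, genome match count."""

    probe_id: str
    scaffold: str
    start: int
    end: int
    sequence: str
    tm: float
    match_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_tm(sequence: str, na_conc: float = 0.05, probe_conc: float = 2.5e-7) -> float:
    """Unified nearest-neighbor melting temperature in degrees C.

    ``na_conc`` is the monovalent cation concentration (M); ``probe_conc``
    the total probe concentration (M), of which C/4 enters the duplex term.
    Ambiguous bases are rejected.
    """
    if len(sequence) < 8:
        raise ValueError("sequence shorter than 8 bases")
    seq = sequence.upper()
    if set(seq) - set(_BASES):
        raise ValueError(f"sequence contains non-ACGT characters: {sequence!r}")
    dh = _INIT_DH[_CODE[seq[0]]] + _INIT_DH[_CODE[seq[-1]]]
    ds = _INIT_DS[_CODE[seq[0]]] + _INIT_DS[_CODE[seq[-1]]]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_conc)
    return 1000.0 * dh / (ds + _R * math.log(probe_conc / 4.0)) - 273.15


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4."""
    table = np.full(256, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _mask_bool(length: int, mask) -> np.ndarray:
    out = np.zeros(length, dtype=bool)
    for s, e in mask:
        out[s:e] = True
    return out


def tile_scaffold(scaffold: Scaffold, params: TilingParams = TilingParams()) -> list[Probe]:
    """Tile one scaffold with isothermal probes.

    Anchors sit every ``spacing`` bp within each unmasked run.  At each
    anchor the candidate length in [min_len, max_len] minimizing
    |Tm - target_tm| is selected (ties break to the shorter probe);
    candidates that cross the mask, contain N, or run off the scaffold
    are discarded, and an anchor with no valid candidate emits nothing.
    """
    n = scaffold.length
    if n == 0:
        return []
    codes = _encode(scaffold.sequence)
    bad = _mask_bool(n, scaffold.mask) | (codes == 4)
    badcum = np.concatenate([[0], np.cumsum(bad)])

    # anchors restart at every unmasked run so probes never straddle mask
    anchors = []
    run_start = None
    edges = np.flatnonzero(np.diff(np.concatenate([[1], bad.view(np.int8), [1]])))
    for i in range(0, len(edges), 2):
        run_start, run_end = int(edges[i]), int(edges[i + 1])
        anchors.append(np.arange(run_start, run_end, params.spacing))
    if not anchors:
        return []
    anchors = np.concatenate(anchors)
    if anchors.size == 0:
        return []

    # cumulative NN sums; stacks touching an N are zeroed, but any
    # candidate containing N is invalid anyway
    din = 4 * codes[:-1].astype(np.int64) + codes[1:]
    ok_stack = (codes[:-1] < 4) & (codes[1:] < 4)
    din = np.where(ok_stack, din, 0)
    dh_stack = np.where(ok_stack, _NN_DH[din], 0.0)
    ds_stack = np.where(ok_stack, _NN_DS[din], 0.0)
    dhcum = np.concatenate([[0.0], np.cumsum(dh_stack)])
    dscum = np.concatenate([[0.0], np.cumsum(ds_stack)])

    lengths = np.arange(params.min_len, params.max_len + 1)
    ends = anchors[:, None] + lengths[None, :]  # (n_anchor, n_len)
    valid = ends <= n
    ends_c = np.minimum(ends, n)
    valid &= (badcum[ends_c] - badcum[anchors][:, None]) == 0

    last = ends_c - 1
    dh = (
        dhcum[last] - dhcum[anchors][:, None]
        + _INIT_DH[codes[anchors]][:, None]
        + _INIT_DH[codes[np.minimum(last, n - 1)]]
    )
    ds = (
        dscum[last] - dscum[anchors][:, None]
        + _INIT_DS[codes[anchors]][:, None]
        + _INIT_DS[codes[np.minimum(last, n - 1)]]
        + 0.368 * (lengths - 1)[None, :] * math.log(params.na_conc)
    )
    tm = 1000.0 * dh / (ds + _R * math.log(params.probe_conc / 4.0)) - 273.15

    delta = np.abs(tm - params.target_tm)
    delta[~valid] = np.inf
    best = np.argmin(delta, axis=1)  # first minimum -> shorter length on ties
    keep = np.isfinite(delta[np.arange(len(anchors)), best])

    probes = []
    for idx in np.flatnonzero(keep):
        a, b = int(anchors[idx]), int(best[idx])
        start, end = a, a + int(lengths[b])
        probes.append(
            Probe(
                probe_id=f"{scaffold.name}:{start}-{end}",
                scaffold=scaffold.name,
                start=start,
                end=end,
                sequence=scaffold.sequence[start:end],
                tm=float(tm[idx, b]),
            )
        )
    return probes


def count_exact_matches(probes, scaffolds: list[Scaffold]) -> dict[str, int]:
    """Count exact genome occurrences of each probe on either strand.

    Occurrences may overlap; a probe lifted from the genome always counts
    at least once.  ``probes`` may be Probe objects or (probe_id, sequence)
    pairs.
    """
    pairs = [
        (p.probe_id, p.sequence) if isinstance(p, Probe) else tuple(p) for p in probes
    ]
    # sentinel joins prevent matches spanning scaffold boundaries
    genome = "#".join(sc.sequence for sc in scaffolds)
    cache: dict[str, int] = {}

    def occurrences(target: str) -> int:
        if target not in cache:
            count, pos = 0, genome.find(target)
            while pos != -1:
                count += 1
                pos = genome.find(target, pos + 1)
            cache[target] = count
        return cache[target]

    counts = {}
    for probe_id, seq in pairs:
        rc = reverse_complement(seq)
        total = occurrences(seq)
        if rc != seq:
            total += occurrences(rc)
        counts[probe_id] = total
    return counts


def filter_multimapping(obj, match_counts: dict[str, int]):
    """Keep only uniquely mapping probes (match_count == 1), order preserved.

    Accepts a list of Probe or a SignalTable; returns the same kind.
    Every probe must have a count.
    """
    if isinstance(obj, SignalTable):
        ids = obj.df["probe_id"]
        missing = [i for i in ids if i not in match_counts]
        if missing:
            raise DataError(f"probes without match counts: {missing[:5]}")
        keep = ids.map(match_counts) == 1
        return SignalTable(obj.df.loc[keep].reset_index(drop=True))
    out = []
    for probe in obj:
        if probe.probe_id not in match_counts:
            raise DataError(f"probe without match count: {probe.probe_id}")
        if match_counts[probe.probe_id] == 1:
            probe.match_count = 1
            out.append(probe)
    return out
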