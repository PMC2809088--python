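"""Shared domain types.

All coordinates throughout the package are 0-based, half-open intervals
(BED convention).  Readers of 1-based formats (GFF3) convert at the
boundary; nothing downstream ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

REGION_SOURCES = frozenset(
    {"h3k4me3_peak", "gene_tss", "est_tss", "background", "other"}
)


def validate_interval(start: int, end: int, length: int | None = None) -> None:
    """Reject any interval that is not a proper half-open span.

    ``length``, if given, is the containing scaffold length.
    """
    if start < 0 or start >= end:
        raise ValidationError(f"invalid half-open interval [{start}, {end})")
    if length is not None and end > length:
        raise ValidationError(
            f"interval [{start}, {end}) extends past scaffold length {length}"
        )


@dataclass
class Scaffold:
    """A contiguous assembled genome sequence with an optional repeat mask.

    ``mask`` holds sorted, non-overlapping half-open intervals of
    repeat-masked sequence (from soft-masking or an explicit BED mask).
    """

    name: str
    sequence: str  # uppercase A/C/G/T/N
    mask: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        self.mask = merge_intervals(self.mask)
        for s, e in self.mask:
            validate_interval(s, e, self.length)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-resolved transcription start site.

    The TSS is ``span.start`` on the + strand and ``span.end - 1`` on the
    - strand (the last base of the half-open span).
    """

    id: str
    scaffold: str
    strand: str  # "+" or "-"
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: unknown strand {self.strand!r}")
        validate_interval(self.start, self.end)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ESTAlignment:
    """An EST's aligned blocks, possibly spread over several scaffolds.

    ``blocks`` is a tuple of (scaffold, start, end); blocks on one scaffold
    are sorted and non-overlapping.
    """

    est_id: str
    blocks: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if not self.blocks:
            raise ValidationError(f"EST {self.est_id}: no aligned blocks")
        per_scaffold: dict[str, list[tuple[int, int]]] = {}
        for scaf, s, e in self.blocks:
            validate_interval(s, e)
            per_scaffold.setdefault(scaf, []).append((s, e))
        for scaf, ivals in per_scaffold.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"EST {self.est_id}: overlapping blocks on {scaf}"
                    )

    @property
    def scaffolds(self) -> frozenset[str]:
        return frozenset(scaf for scaf, _, _ in self.blocks)


@dataclass
class Region:
    """A scored half-open genomic interval — the universal interval currency."""

    scaffold: str
    start: int
    end: int
    score: float | None = None
    source: str = "other"

    def __post_init__(self):
        validate_interval(self.start, self.end)
        if self.source not in REGION_SOURCES and "+" not in self.source:
            # merged regions carry concatenated tags like "gene_tss+h3k4me3_peak"
            raise ValidationError(f"unknown region source {self.source!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Peak(Region):
    """An enriched region with per-probe summary statistics."""

    n_probes: int = 1
    mean_signal: float = 0.0
    max_signal: float = 0.0
    # index span of constituent probes in the originating SignalTable
    # (used to recompute stats when peaks from different windows merge)
    first_probe: int = -1
    last_probe: int = -1

    def __post_init__(self):
        super().__post_init__()
        if self.n_probes < 1:
            raise ValidationError("peak must contain at least one probe")


class SignalTable:
    """Per-probe log2(ChIP/input) values across one or more arrays.

    Thin wrapper around a DataFrame with columns
    ``probe_id, scaffold, start, end, <array>...`` sorted by genome
    position.  Values must be finite; probe ids must be unique.
    """

    META_COLS = ["probe_id", "scaffold", "start", "end"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.META_COLS if c not in df.columns]
        if missing:
            raise DataError(f"signal table missing columns: {missing}")
        arrays = [c for c in df.columns if c not in self.META_COLS]
        if not arrays:
            raise DataError("signal table has no array columns")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise DataError(f"duplicate probe_id {dup!r}")
        vals = df[arrays].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataError("signal table contains missing or non-finite values")
        df = df.sort_values(["scaffold", "start"], kind="stable").reset_index(drop=True)
        self.df = df
        self.arrays = arrays

    @property
    def n_probes(self) -> int:
        return len(self.df)

    def values(self, array: str) -> np.ndarray:
        if array not in self.arrays:
            raise DataError(f"unknown array {array!r}")
        return self.df[array].to_numpy(dtype=float)

    def with_values(self, array: str, values: np.ndarray) -> "SignalTable":
        """Copy of the table with one array's values replaced."""
        if array not in self.arrays:
            raise DataError(f"unknown array {array!r}")
        df = self.df.copy()
        df[array] = values
        return SignalTable(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SignalTable) and self.df.equals(other.df)


def merge_intervals(
    intervals, gap: int = 0
) -> list[tuple[int, int]]:
    """Sort and merge half-open intervals; two intervals merge when the gap
    between them is <= ``gap`` (gap 0 merges touching intervals)."""
    ivals = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivals:
        if out and s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
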