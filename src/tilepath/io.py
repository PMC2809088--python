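"""Readers and writers for the standard formats the pipeline exchanges.

Every reader emits 0-based half-open coordinates.  GFF3 (1-based, closed)
is converted at this boundary.  Soft-masked (lowercase) FASTA runs become
the scaffold's repeat mask; an explicit BED mask can be united with it.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FormatError, ValidationError
from .types import (
    ESTAlignment,
    GeneModel,
    Region,
    REGION_SOURCES,
    Scaffold,
    SignalTable,
    merge_intervals,
)

_IUPAC = set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")
_AMBIG = str.maketrans("RYSWKMBDHV", "NNNNNNNNNN")


def _lowercase_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"[a-z]+", seq)]


def read_fasta(path) -> list[Scaffold]:
    """Read a (possibly soft-masked) FASTA file into Scaffold records.

    Lowercase runs are recorded as mask intervals; sequences are
    uppercased and IUPAC ambiguity codes collapsed to N.
    """
    path = Path(path)
    scaffolds = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        bad = set(raw) - _IUPAC
        if bad or not rec.id:
            _raise_fasta_error(path, bad)
        mask = _lowercase_runs(raw)
        seq = raw.upper().translate(_AMBIG)
        scaffolds.append(Scaffold(name=rec.id, sequence=seq, mask=mask))
    if not scaffolds:
        # SeqIO silently yields nothing for junk input; distinguish an empty
        # parse of a non-empty file from a genuinely empty file
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise FormatError(f"{path}:1: malformed FASTA header")
    return scaffolds


def _raise_fasta_error(path: Path, bad_chars: set) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                if line.strip() == ">":
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                continue
            extra = set(line.strip()) - _IUPAC
            if extra:
                raise FormatError(
                    f"{path}:{lineno}: non-IUPAC character(s) {sorted(extra)}"
                )
    raise FormatError(f"{path}: malformed FASTA ({sorted(bad_chars)})")


def write_fasta(scaffolds: list[Scaffold], path) -> None:
    """Write scaffolds as soft-masked FASTA (mask intervals in lowercase)."""
    records = []
    for sc in scaffolds:
        seq = sc.sequence
        for s, e in sc.mask:
            seq = seq[:s] + seq[s:e].lower() + seq[e:]
        records.append(SeqRecord(Seq(seq), id=sc.name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_mask_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3+ repeat mask into per-scaffold merged interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    for reg in read_bed(path):
        out.setdefault(reg.scaffold, []).append((reg.start, reg.end))
    return {scaf: merge_intervals(iv) for scaf, iv in out.items()}


def apply_mask(scaffolds: list[Scaffold], mask: dict) -> list[Scaffold]:
    """Union an explicit BED mask with each scaffold's soft mask."""
    return [
        Scaffold(
            name=sc.name,
            sequence=sc.sequence,
            mask=merge_intervals(list(sc.mask) + mask.get(sc.name, [])),
        )
        for sc in scaffolds
    ]


# ---------------------------------------------------------------- genes

def read_genes(path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or BED12.

    GFF3 rows of type ``gene`` are used when present (all rows otherwise);
    1-based closed coordinates become 0-based half-open.  The TSS follows
    from the strand.
    """
    if dialect == "gff3":
        return _read_genes_gff3(path)
    if dialect == "bed12":
        return _read_genes_bed12(path)
    raise ValueError(f"unknown gene dialect {dialect!r}")


def _read_genes_gff3(path) -> list[GeneModel]:
    genes = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            rows.append((lineno, fields))
    types = {f[2] for _, f in rows}
    if "gene" in types:
        rows = [(ln, f) for ln, f in rows if f[2] == "gene"]
    for lineno, f in rows:
        seqid, _, _, start, end, _, strand, _, attrs = f
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
        gene_id = _gff3_attr(attrs, "ID") or _gff3_attr(attrs, "Name")
        if gene_id is None:
            raise FormatError(f"{path}:{lineno}: feature without ID attribute")
        genes.append(
            GeneModel(
                id=gene_id,
                scaffold=seqid,
                strand=strand,
                start=int(start) - 1,  # GFF3 is 1-based closed
                end=int(end),
            )
        )
    return genes


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def _read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BED needs >= 6 columns for genes")
            if f[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {f[5]!r}")
            genes.append(
                GeneModel(
                    id=f[3], scaffold=f[0], strand=f[5], start=int(f[1]), end=int(f[2])
                )
            )
    return genes


# ---------------------------------------------------------------- ESTs

def read_ests(path) -> list[ESTAlignment]:
    """Read EST alignments from BED12.

    One BED12 record holds the aligned blocks on one scaffold; records
    sharing a name are one EST split across scaffolds.
    """
    blocks_by_est: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, chrom_start, name = f[0], int(f[1]), f[3]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(starts) or len(sizes) != int(f[9]):
                raise FormatError(f"{path}:{lineno}: inconsistent block columns")
            for size, rel in zip(sizes, starts):
                s = chrom_start + rel
                blocks_by_est.setdefault(name, []).append((chrom, s, s + size))
    return [
        ESTAlignment(est_id=name, blocks=tuple(sorted(blocks)))
        for name, blocks in blocks_by_est.items()
    ]


def write_ests(ests: list[ESTAlignment], path) -> None:
    """Write EST alignments as BED12, one record per (EST, scaffold)."""
    with open(path, "w") as fh:
        for est in ests:
            per_scaf: dict[str, list[tuple[int, int]]] = {}
            for scaf, s, e in est.blocks:
                per_scaf.setdefault(scaf, []).append((s, e))
            for scaf, ivals in sorted(per_scaf.items()):
                ivals.sort()
                cs, ce = ivals[0][0], ivals[-1][1]
                sizes = ",".join(str(e - s) for s, e in ivals)
                rels = ",".join(str(s - cs) for s, _ in ivals)
                fh.write(
                    f"{scaf}\t{cs}\t{ce}\t{est.est_id}\t0\t+\t{cs}\t{ce}\t0\t"
                    f"{len(ivals)}\t{sizes}\t{rels}\n"
                )


# ---------------------------------------------------------------- signal

def read_signal_table(path) -> SignalTable:
    """Read the tab-delimited probe-signal table.

    Header: ``probe_id  scaffold  start  end  <array1> [<array2> ...]``.
    Rows are re-sorted by genome position; missing values are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table: {exc}") from exc
    if df.isna().any().any():
        raise DataError(f"{path}: table contains missing values")
    try:
        return SignalTable(df)
    except DataError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_signal_table(table: SignalTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------- BED

def write_bed(regions: list[Region], path, scaffold_lengths: dict | None = None) -> None:
    """Write regions as BED5 (chrom, start, end, source, score in [0, 1000])."""
    lines = []
    for reg in regions:
        if scaffold_lengths is not None:
            length = scaffold_lengths.get(reg.scaffold)
            if length is None or reg.end > length:
                raise ValidationError(
                    f"region {reg.scaffold}:{reg.start}-{reg.end} outside scaffold"
                )
        score = 0.0 if reg.score is None else min(1000.0, max(0.0, reg.score))
        lines.append(f"{reg.scaffold}\t{reg.start}\t{reg.end}\t{reg.source}\t{score:g}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_bed(path) -> list[Region]:
    """Read BED3/BED5 into Regions; column 4 becomes the source tag."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            source = f[3] if len(f) > 3 else "other"
            if source not in REGION_SOURCES and "+" not in source:
                source = "other"
            score = float(f[4]) if len(f) > 4 else None
            regions.append(
                Region(
                    scaffold=f[0], start=int(f[1]), end=int(f[2]),
                    score=score, source=source,
                )
            )
    return regions
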