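"""Readers and writers for the plain-text genomic formats the pipeline touches.

FASTA (genomes), BED3+ and 1-based inclusive TSV (intervals), TSV gene
tables (annotation), bedGraph and fixedStep wiggle (per-base coverage).
Everything is converted to the internal 0-based half-open convention on
the way in and back out on the way out.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    CoverageTrack,
    GeneAnnotation,
    GeneRecord,
    GenomeSequence,
    Interval,
    IntervalSet,
)

logger = logging.getLogger(__name__)

# IUPAC ambiguity codes collapsed to N; anything else is rejected.
_AMBIGUITY = set("RYSWKMBDHVU")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N (with a logged count); duplicate headers and non-IUPAC characters
    are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    replicons: dict[str, str] = {}
    n_mapped = 0
    for rec in records:
        if rec.id in replicons:
            raise ValueError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN") - _AMBIGUITY
        if bad:
            raise ValueError(
                f"{path}: replicon {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        amb = set(seq) & _AMBIGUITY
        if amb:
            n_mapped += sum(seq.count(c) for c in amb)
            seq = seq.translate(str.maketrans({c: "N" for c in amb}))
        replicons[rec.id] = seq
    if n_mapped:
        logger.info("read_fasta: mapped %d ambiguity bases to N", n_mapped)
    return GenomeSequence(replicons)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.replicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intervals(
    path: str | Path,
    dialect: str = "BED",
    genome: GenomeSequence | None = None,
) -> IntervalSet:
    """Read intervals from BED (0-based half-open) or a 1-based inclusive TSV.

    A row (s, e) in the one_based_inclusive dialect maps to (s-1, e) internally.
    """
    if dialect not in ("BED", "one_based_inclusive_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            rep, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                s, e = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if dialect == "one_based_inclusive_tsv":
                s -= 1
            if s < 0 or s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end after conversion")
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            records.append(Interval(rep, s, e, score))
    out = IntervalSet(records)
    if genome is not None:
        out.validate_against(genome)
    return out


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED3+ with deterministic column order (score as BED column 5)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.score is None:
                fh.write(f"{iv.replicon}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.replicon}\t{iv.start}\t{iv.end}\t.\t{iv.score:g}\n")


_DEFAULT_COLUMNS = {
    "replicon": "replicon",
    "start": "start",
    "end": "end",
    "strand": "strand",
    "gene_id": "gene_id",
}


def read_annotation(
    path: str | Path,
    columns: dict[str, str] | None = None,
    dialect: str = "zero_based",
) -> GeneAnnotation:
    """Read a TSV gene table with a header row.

    `columns` maps internal field names (replicon/start/end/strand/gene_id)
    to column names in the file. `dialect` is "zero_based" (half-open, the
    default) or "one_based_inclusive" for NCBI-style tables.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype={colmap["replicon"]: str})
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        strand = str(row_d[colmap["strand"]])
        if strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {row_d[colmap['gene_id']]!r} unstranded")
        s, e = int(row_d[colmap["start"]]), int(row_d[colmap["end"]])
        if dialect == "one_based_inclusive":
            s -= 1
        records.append(
            GeneRecord(
                str(row_d[colmap["replicon"]]), s, e, strand,
                str(row_d[colmap["gene_id"]]),
            )
        )
    return GeneAnnotation(records)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    rows = [
        (g.replicon, g.start, g.end, g.strand, g.gene_id) for g in annotation
    ]
    df = pd.DataFrame(rows, columns=["replicon", "start", "end", "strand", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


def read_coverage(
    path: str | Path,
    genome: GenomeSequence,
    format: str = "bedGraph",
    label: str = "IP",
) -> CoverageTrack:
    """Read per-base coverage from bedGraph or fixedStep wiggle into dense vectors.

    Unspecified positions are zero-filled. Overlapping bedGraph intervals with
    conflicting values are rejected. Wiggle fixedStep positions are 1-based.
    """
    lengths = genome.lengths()
    depths = {name: np.zeros(n, dtype=float) for name, n in lengths.items()}
    assigned = {name: np.zeros(n, dtype=bool) for name, n in lengths.items()}
    if format == "bedGraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                rep, s, e, v = line.split()[:4]
                s, e, v = int(s), int(e), float(v)
                if rep not in depths:
                    raise ValueError(f"{path}:{lineno}: unknown replicon {rep!r}")
                if not (0 <= s < e <= lengths[rep]):
                    raise ValueError(f"{path}:{lineno}: interval out of bounds")
                overlap = assigned[rep][s:e]
                if overlap.any():
                    clash = depths[rep][s:e][overlap] != v
                    if clash.any():
                        raise ValueError(
                            f"{path}:{lineno}: overlapping interval with conflicting value"
                        )
                depths[rep][s:e] = v
                assigned[rep][s:e] = True
    elif format == "wig_fixedStep":
        rep = None
        pos = step = span = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in line.split()[1:])
                    rep = kv["chrom"]
                    if rep not in depths:
                        raise ValueError(f"{path}:{lineno}: unknown replicon {rep!r}")
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    continue
                if rep is None:
                    raise ValueError(f"{path}:{lineno}: data before fixedStep header")
                v = float(line)
                if pos + span > lengths[rep]:
                    raise ValueError(f"{path}:{lineno}: position out of bounds")
                depths[rep][pos : pos + span] = v
                pos += step
    else:
        raise ValueError(f"unknown coverage format {format!r}")
    track = CoverageTrack(depths, label=label)
    return track


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write bedGraph, run-length encoding constant stretches (zeros omitted)."""
    with open(path, "w") as fh:
        for rep, vec in track.depths.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{rep}\t{s}\t{e}\t{v:g}\n")
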