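"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (feature id + one column per sample) with a separate
sample sheet (sample id, subset, subject); intervals as 6-column BED
(0-based, half-open, sorted on load); sequences as 60-column-wrapped FASTA.
Coordinates are 0-based half-open everywhere internally.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix

__all__ = [
    "GenomicInterval",
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "file_sha256",
    "write_manifest",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an id/class annotation."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    feature_class: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between intervals on the same chromosome (0 if they touch
        or overlap); None for different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def read_counts(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    lengths_col: str | None = None,
    class_col: str | None = None,
) -> CountMatrix:
    """Load a TSV count matrix and its sample sheet into a CountMatrix.

    The TSV carries feature ids in the first column; optional per-feature
    ``lengths_col``/``class_col`` columns are split off from the counts.
    Duplicate feature ids, negative or non-integer counts, and samples
    missing from the sheet are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id in {path}: {dup!r}")
    lengths = None
    fclass = None
    if lengths_col and lengths_col in df.columns:
        lengths = df.pop(lengths_col)
    if class_col and class_col in df.columns:
        fclass = df.pop(class_col)
    vals = df.values
    if not ((vals == vals.astype(int)).all() and (vals >= 0).all()):
        raise ValueError(f"{path}: counts must be non-negative integers")
    if isinstance(sample_sheet, (str, Path)):
        sheet = pd.read_csv(sample_sheet, sep="\t", index_col=0)
    else:
        sheet = sample_sheet
    return CountMatrix(
        counts=df.astype(int), samples=sheet, lengths=lengths, feature_class=fclass
    )


def write_counts(matrix: CountMatrix, path: str | Path, sheet_path: str | Path | None = None) -> None:
    df = matrix.counts.copy()
    if matrix.lengths is not None:
        df.insert(0, "length", matrix.lengths)
    if matrix.feature_class is not None:
        df.insert(0, "feature_class", matrix.feature_class)
    df.to_csv(path, sep="\t", index_label="feature_id")
    if sheet_path is not None:
        matrix.samples.to_csv(sheet_path, sep="\t", index_label="sample_id")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (3-6 columns); output sorted, stable for ties."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered id -> uppercase sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(f"{path}: non-IUPAC characters {sorted(bad)} in {rec.id}")
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: dict[str, str | Path], out_path: str | Path) -> dict:
    """Manifest mapping each logical output name to its path and sha256."""
    manifest = {
        name: {"path": str(p), "sha256": file_sha256(p)} for name, p in paths.items()
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
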