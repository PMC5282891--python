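"""Readers, writers and validated in-memory records for the standard formats.

All genomic coordinates are held internally as 0-based half-open intervals.
GTF (1-based, inclusive) is converted at the read/write boundary; BED and
bedGraph already use the internal convention and pass through unchanged.
Strand is one of ``"+"``, ``"-"`` or ``"."`` (unknown); unknown strand is a
first-class value and is never coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")
UNKNOWN_STRAND = "."
BIOTYPES = ("protein_coding", "known_ncRNA", "unannotated")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class ValidationError(ValueError):
    """An input that parses but violates a record invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded location on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN_STRAND

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class LabeledInterval:
    """A BED-style interval with an optional name label (repeat class, catalog id)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = UNKNOWN_STRAND

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript (isotig or merged raw transcript).

    ``exons`` are (start, end) pairs on ``chrom``, sorted by start, mutually
    non-overlapping, all on the transcript's strand.  ``members`` records the
    isotig ids fused into this model by merging (empty for primary isotigs).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unannotated"
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"{self.transcript_id}: strand must be one of {STRANDS}: {self.strand!r}"
            )
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(
                    f"{self.transcript_id}: exon end <= start ({start}, {end})"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        """Mature (spliced) length: the sum of exon lengths."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in self.exons]

    def with_strand(self, strand: str) -> "TranscriptModel":
        return replace(self, strand=strand)


@dataclass
class ExpressionTable:
    """Transcript x library FPKM matrix with library -> (region, stage) metadata."""

    values: pd.DataFrame
    library_meta: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript ids in expression table: {dups}")
        if self.values.isna().any().any():
            raise ValidationError("expression table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        missing = [c for c in self.values.columns if c not in self.library_meta]
        if missing:
            raise ValidationError(f"libraries absent from metadata: {missing}")
        absent = [l for l in self.library_meta if l not in self.values.columns]
        if absent:
            raise ValidationError(f"declared libraries missing from table: {absent}")
        # stable library order: metadata declaration order
        self.values = self.values[list(self.library_meta)]

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    def row(self, transcript_id: str) -> np.ndarray:
        if transcript_id not in self.values.index:
            raise KeyError(f"transcript {transcript_id!r} absent from expression table")
        return self.values.loc[transcript_id].to_numpy()

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionTable":
        ids = list(transcript_ids)
        missing = [t for t in ids if t not in self.values.index]
        if missing:
            raise KeyError(f"transcripts absent from expression table: {missing}")
        return ExpressionTable(self.values.loc[ids].copy(), dict(self.library_meta))

    def libraries_by_region(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for lib, (region, _stage) in self.library_meta.items():
            out.setdefault(region, []).append(lib)
        return out

    def libraries_by_stage(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for lib, (_region, stage) in self.library_meta.items():
            out.setdefault(stage, []).append(lib)
        return out


@dataclass
class ConservationTrack:
    """Per-base conservation scores from a bedGraph; uncovered bases are missing.

    Intervals are stored per chromosome as sorted, non-overlapping arrays.
    Overlapping input intervals with different scores are rejected.
    """

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, rows: Iterable[tuple[str, int, int, float]]
    ) -> "ConservationTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in rows:
            if end <= start:
                raise ValidationError(f"track interval end <= start on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end, score))
        track = cls()
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, v1), (s2, _e2, v2) in zip(ivs, ivs[1:]):
                if s2 < e1 and v1 != v2:
                    raise ValidationError(
                        f"overlapping track intervals with conflicting scores on "
                        f"{chrom} at {s2}"
                    )
            track.starts[chrom] = np.array([iv[0] for iv in ivs], dtype=np.int64)
            track.ends[chrom] = np.array([iv[1] for iv in ivs], dtype=np.int64)
            track.scores[chrom] = np.array([iv[2] for iv in ivs], dtype=float)
        return track

    def score_at(self, chrom: str, pos: int) -> float | None:
        """Score of one base, or None when the base is not covered."""
        if chrom not in self.starts:
            return None
        i = int(np.searchsorted(self.starts[chrom], pos, side="right")) - 1
        if i >= 0 and pos < self.ends[chrom][i]:
            return float(self.scores[chrom][i])
        return None

    def sum_and_coverage(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(sum of scores, number of covered bases) over [start, end)."""
        if chrom not in self.starts:
            return 0.0, 0
        st, en, sc = self.starts[chrom], self.ends[chrom], self.scores[chrom]
        lo = int(np.searchsorted(en, start, side="right"))
        hi = int(np.searchsorted(st, end, side="left"))
        if lo >= hi:
            return 0.0, 0
        ov = np.minimum(en[lo:hi], end) - np.maximum(st[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, sc[lo:hi])), int(ov.sum())

    def iter_intervals(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self.starts):
            for s, e, v in zip(self.starts[chrom], self.ends[chrom], self.scores[chrom]):
                yield chrom, int(s), int(e), float(v)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: malformed GTF attribute {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into TranscriptModels.

    1-based inclusive GTF coordinates become 0-based half-open; strand "."
    becomes unknown; exons are grouped by transcript_id in file order.  A
    transcript_id appearing on more than one chromosome or strand is an error.
    """
    order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"line {lineno}: expected >=9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ValidationError(f"line {lineno}: exon end < start")
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_s, lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ParseError(f"line {lineno}: missing gene_id/transcript_id attribute")
            tid = attrs["transcript_id"]
            biotype = attrs.get("transcript_biotype", "unannotated")
            key = (attrs["gene_id"], chrom, strand, biotype)
            if tid in info:
                if info[tid][1] != chrom:
                    raise ValidationError(
                        f"line {lineno}: transcript {tid!r} appears on multiple "
                        f"chromosomes ({info[tid][1]}, {chrom})"
                    )
                if info[tid][2] != strand:
                    raise ValidationError(
                        f"line {lineno}: transcript {tid!r} appears on multiple strands"
                    )
            else:
                info[tid] = key
                order.append(tid)
            exons.setdefault(tid, []).append((start1 - 1, end1))
    models = []
    for tid in order:
        gene, chrom, strand, biotype = info[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
                biotype=biotype,
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path, source: str = "lncfeather") -> None:
    """Write one exon line per exon, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'transcript_biotype "{m.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [m.chrom, source, "exon", str(start + 1), str(end),
                         ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression(path, library_meta: Mapping[str, tuple[str, str]]) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df, dict(library_meta))


def write_expression(table: ExpressionTable, path) -> None:
    df = table.values.copy()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t")


def read_library_meta(path) -> dict[str, tuple[str, str]]:
    """TSV with columns library_id, region, stage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "region", "stage"}
    if not required.issubset(df.columns):
        raise ParseError(f"library metadata must have columns {sorted(required)}")
    return {r.library_id: (r.region, r.stage) for r in df.itertuples()}


def write_library_meta(meta: Mapping[str, tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tregion\tstage\n")
        for lib, (region, stage) in meta.items():
            fh.write(f"{lib}\t{region}\t{stage}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph / chrom.sizes
# ---------------------------------------------------------------------------

def read_bed(path) -> list[LabeledInterval]:
    """BED3/BED6, 0-based half-open; column 4 is the label, column 6 the strand."""
    out: list[LabeledInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer BED coordinates") from None
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else UNKNOWN_STRAND
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: invalid strand {strand!r}")
            try:
                out.append(LabeledInterval(fields[0], start, end, name, strand))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
    return out


def write_bed(intervals: Sequence[LabeledInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_track(path) -> ConservationTrack:
    """bedGraph (chrom, start, end, score), 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: bedGraph needs 4 fields")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                raise ParseError(f"line {lineno}: malformed bedGraph values") from None
    return ConservationTrack.from_intervals(rows)


def write_track(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, score in track.iter_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: chrom.sizes needs 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def spliced_sequence(model: TranscriptModel, chrom_seq: str) -> str:
    """Mature transcript sequence: exons concatenated, reverse-complemented on '-'."""
    parts = [chrom_seq[s:e] for s, e in model.exons]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
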