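"""Positional classification of lncRNAs relative to the protein-coding annotation.

Classes: lncNAT (>=1 bp exonic overlap with a coding exon on the opposite
strand), intronic (entire exon set inside a single intron of one coding gene,
no coding-exon overlap on either strand), lincRNA (no overlap with any coding
gene span).  Precedence lncNAT > intronic > lincRNA.  A transcript matching
none of the three (straddling a gene boundary without exon overlap) falls
back to intronic when the majority of its exonic bases lie inside a gene
span, else lincRNA.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import TranscriptModel, ValidationError

LINCRNA = "lincRNA"
INTRONIC = "intronic"
LNCNAT = "lncNAT"
CLASSES = (LINCRNA, INTRONIC, LNCNAT)

_OPPOSITE = {"+": "-", "-": "+"}


@dataclass
class CodingAnnotation:
    """Indexed view of the protein-coding annotation used by the classifier."""

    exon_trees: dict[tuple[str, str], IntervalTree]  # (chrom, strand) -> exons
    span_trees: dict[str, IntervalTree]              # chrom -> gene spans -> gene_id
    introns: dict[str, list[tuple[int, int, str]]]   # chrom -> (start, end, gene strand)
    n_genes: int

    @classmethod
    def from_models(cls, annotation: Sequence[TranscriptModel]) -> "CodingAnnotation":
        exon_trees: dict[tuple[str, str], IntervalTree] = {}
        gene_exons: dict[str, list[tuple[int, int]]] = {}
        gene_loc: dict[str, tuple[str, str]] = {}
        for m in annotation:
            for s, e in m.exons:
                exon_trees.setdefault((m.chrom, m.strand), IntervalTree()).addi(s, e)
                gene_exons.setdefault(m.gene_id, []).append((s, e))
            loc = (m.chrom, m.strand)
            if gene_loc.setdefault(m.gene_id, loc) != loc:
                raise ValidationError(
                    f"gene {m.gene_id!r} spans multiple chromosomes/strands"
                )
        span_trees: dict[str, IntervalTree] = {}
        introns: dict[str, list[tuple[int, int, str]]] = {}
        for gene_id, exons in gene_exons.items():
            chrom, strand = gene_loc[gene_id]
            merged: list[list[int]] = []
            for s, e in sorted(exons):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            span_trees.setdefault(chrom, IntervalTree()).addi(
                merged[0][0], merged[-1][1], gene_id
            )
            for (s1, e1), (s2, _e2) in zip(merged, merged[1:]):
                introns.setdefault(chrom, []).append((e1, s2, strand))
        return cls(exon_trees, span_trees, introns, n_genes=len(gene_exons))

    def exon_overlap(self, model: TranscriptModel, strand: str) -> bool:
        tree = self.exon_trees.get((model.chrom, strand))
        if tree is None:
            return False
        return any(tree.overlap(s, e) for s, e in model.exons)

    def span_overlap_bases(self, model: TranscriptModel) -> int:
        tree = self.span_trees.get(model.chrom)
        if tree is None:
            return 0
        total = 0
        for s, e in model.exons:
            covered: list[tuple[int, int]] = []
            for iv in tree.overlap(s, e):
                covered.append((max(s, iv.begin), min(e, iv.end)))
            # spans may overlap each other only across strands; union their bases
            covered.sort()
            last = s
            for cs, ce in covered:
                total += max(0, ce - max(cs, last))
                last = max(last, ce)
        return total

    def contained_in_one_intron(
        self, model: TranscriptModel, same_strand_only: bool = False
    ) -> bool:
        span_s, span_e = model.span
        for s, e, strand in self.introns.get(model.chrom, ()):
            if s <= span_s and span_e <= e:
                if same_strand_only and strand != model.strand:
                    continue
                return True
        return False


def classify_positional(
    lncrna: TranscriptModel,
    coding_annotation: CodingAnnotation,
    intronic_same_strand_only: bool = False,
) -> str:
    """Assign one positional class to a consensus lncRNA.

    ``intronic_same_strand_only`` restricts intronic calls to transcripts on
    the strand of the host gene (off by default; containment alone defines
    the class).
    """
    if coding_annotation.n_genes == 0:
        warnings.warn("empty coding annotation: classifying everything as lincRNA")
        return LINCRNA
    opposite = _OPPOSITE.get(lncrna.strand)
    if opposite is not None and coding_annotation.exon_overlap(lncrna, opposite):
        return LNCNAT
    if not coding_annotation.exon_overlap(lncrna, lncrna.strand):
        if coding_annotation.contained_in_one_intron(lncrna, intronic_same_strand_only):
            return INTRONIC
        if intronic_same_strand_only and coding_annotation.contained_in_one_intron(lncrna):
            # intron-contained but antisense to the host: excluded by the flag
            return LINCRNA
        inside = coding_annotation.span_overlap_bases(lncrna)
        if inside == 0:
            return LINCRNA
        return INTRONIC if inside * 2 > lncrna.length else LINCRNA
    # same-strand exonic overlap should have been removed by discovery; treat
    # the remainder of the gene-overlap spectrum with the majority rule too
    inside = coding_annotation.span_overlap_bases(lncrna)
    return INTRONIC if inside * 2 > lncrna.length else LINCRNA


def classify_all(
    lncrnas: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel] | CodingAnnotation,
    intronic_same_strand_only: bool = False,
) -> dict[str, str]:
    """Positional class per transcript_id for a set of consensus lncRNAs."""
    if not isinstance(annotation, CodingAnnotation):
        coding = [m for m in annotation if m.biotype == "protein_coding"]
        annotation = CodingAnnotation.from_models(coding)
    return {
        m.transcript_id: classify_positional(m, annotation, intronic_same_strand_only)
        for m in lncrnas
    }


def class_counts(classes: Mapping[str, str] | Sequence[str]) -> dict[str, int]:
    """Counts per positional class, with zero entries for absent classes."""
    values = list(classes.values()) if isinstance(classes, Mapping) else list(classes)
    counts = Counter(values)
    unknown = set(counts) - set(CLASSES)
    if unknown:
        raise ValidationError(f"unknown positional classes: {sorted(unknown)}")
    return {c: counts.get(c, 0) for c in CLASSES}


def chromosome_density(
    records: Sequence[TranscriptModel],
    chrom_sizes: Mapping[str, int],
) -> dict[str, float]:
    """Transcripts per Mb for every chromosome in ``chrom_sizes``."""
    counts: Counter[str] = Counter(m.chrom for m in records)
    unknown = set(counts) - set(chrom_sizes)
    if unknown:
        raise ValidationError(f"records on chromosomes absent from sizes: {sorted(unknown)}")
    return {
        chrom: counts.get(chrom, 0) / (size / 1e6)
        for chrom, size in chrom_sizes.items()
    }
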