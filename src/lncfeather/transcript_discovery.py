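"""Filtering cascade from raw isotigs to the unannotated-transcript set.

Stages: strand filter -> annotated/unannotated partition (same-strand,
exon-level, >=1 bp) -> single-linkage merge of overlapping isotigs into raw
transcripts -> length / expression filter -> novelty labeling against a
known-ncRNA catalog.  Every stage conserves its accounting, recorded in a
FilterReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import (
    ExpressionTable,
    LabeledInterval,
    TranscriptModel,
    UNKNOWN_STRAND,
    ValidationError,
)


@dataclass
class FilterReport:
    """Stage-by-stage accounting of the discovery cascade."""

    input: int = 0
    removed_unstranded: int = 0
    annotated: int = 0
    unannotated_isotigs: int = 0
    merged_raw_transcripts: int = 0
    removed_short: int = 0
    removed_lowexpr: int = 0
    retained: int = 0
    novelty: dict[str, str] = field(default_factory=dict)  # tid -> "known"|"novel"

    def check(self) -> None:
        """Raise when the conservation identities are violated."""
        if self.input != self.removed_unstranded + self.annotated + self.unannotated_isotigs:
            raise AssertionError("stage-1/2 accounting violated")
        if self.retained != self.merged_raw_transcripts - self.removed_short - self.removed_lowexpr:
            raise AssertionError("stage-3 accounting violated")
        if len(self.novelty) != self.retained:
            raise AssertionError("novelty flags do not cover the retained set")

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "removed_unstranded": self.removed_unstranded,
            "annotated": self.annotated,
            "unannotated_isotigs": self.unannotated_isotigs,
            "merged_raw_transcripts": self.merged_raw_transcripts,
            "removed_short": self.removed_short,
            "removed_lowexpr": self.removed_lowexpr,
            "retained": self.retained,
            "known": sum(1 for v in self.novelty.values() if v == "known"),
            "novel": sum(1 for v in self.novelty.values() if v == "novel"),
        }


def filter_stranded(
    isotigs: Sequence[TranscriptModel],
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Split isotigs into (stranded, unstranded); unstranded are discarded upstream."""
    kept = [m for m in isotigs if m.strand != UNKNOWN_STRAND]
    removed = [m for m in isotigs if m.strand == UNKNOWN_STRAND]
    return kept, removed


def _exon_tree(models: Iterable[TranscriptModel], stranded: bool = True) -> dict:
    """IntervalTree of exons keyed by (chrom, strand) or chrom."""
    trees: dict = {}
    for m in models:
        key = (m.chrom, m.strand) if stranded else m.chrom
        tree = trees.setdefault(key, IntervalTree())
        for s, e in m.exons:
            tree.addi(s, e, m.transcript_id)
    return trees


def overlaps_same_strand_exon(model: TranscriptModel, trees: dict) -> bool:
    """True iff >=1 exonic base of ``model`` overlaps an indexed exon on the same strand."""
    tree = trees.get((model.chrom, model.strand))
    if tree is None:
        return False
    return any(tree.overlap(s, e) for s, e in model.exons)


def partition_by_annotation(
    isotigs: Sequence[TranscriptModel],
    reference_annotation: Sequence[TranscriptModel],
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition stranded isotigs into (annotated, unannotated).

    An isotig is annotated iff >=1 bp of its exons overlaps >=1 bp of a
    reference exon on the same strand.  Antisense or intron-contained isotigs
    are unannotated and flow on through the pipeline.
    """
    if not any(m.exons for m in reference_annotation):
        raise ValidationError("reference annotation has no exon features")
    trees = _exon_tree(reference_annotation)
    annotated, unannotated = [], []
    for m in isotigs:
        (annotated if overlaps_same_strand_exon(m, trees) else unannotated).append(m)
    return annotated, unannotated


def _union_exons(exon_sets: Iterable[tuple[tuple[int, int], ...]]) -> tuple[tuple[int, int], ...]:
    """Base-level union of exon intervals; touching intervals fuse."""
    ivs = sorted(iv for exons in exon_sets for iv in exons)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def merge_isotigs(unannotated_isotigs: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Single-linkage merge of isotigs sharing >=1 exonic base on one chrom+strand.

    The merged exon structure is the base union of the members' exons.  A
    merged transcript keeps its member's id when it has a single member;
    multi-member fusions get sequential ``RT`` ids, which makes re-running the
    merge on its own output a no-op.
    """
    parent = list(range(len(unannotated_isotigs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, m in enumerate(unannotated_isotigs):
        for s, e in m.exons:
            by_key.setdefault((m.chrom, m.strand), []).append((s, e, idx))
    # sweep each (chrom, strand): union isotigs whose exons overlap (strict, >=1 bp)
    for ivs in by_key.values():
        ivs.sort()
        active_end, active_idx = -1, -1
        for s, e, idx in ivs:
            if s < active_end:
                union(active_idx, idx)
                if e > active_end:
                    active_end, active_idx = e, idx
            else:
                active_end, active_idx = e, idx

    groups: dict[int, list[int]] = {}
    for idx in range(len(unannotated_isotigs)):
        groups.setdefault(find(idx), []).append(idx)

    merged: list[TranscriptModel] = []
    counter = 0
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = [unannotated_isotigs[i] for i in sorted(groups[root])]
        if len(members) == 1:
            m = members[0]
            merged.append(
                TranscriptModel(
                    m.transcript_id, m.gene_id, m.chrom, m.strand, m.exons,
                    m.biotype, members=(m.transcript_id,),
                )
            )
        else:
            counter += 1
            merged.append(
                TranscriptModel(
                    transcript_id=f"RT{counter:05d}",
                    gene_id=f"RT{counter:05d}",
                    chrom=members[0].chrom,
                    strand=members[0].strand,
                    exons=_union_exons(m.exons for m in members),
                    biotype="unannotated",
                    members=tuple(m.transcript_id for m in members),
                )
            )
    return merged


def aggregate_expression(
    raw_transcripts: Sequence[TranscriptModel],
    expr: ExpressionTable,
    how: str = "max",
) -> ExpressionTable:
    """Per-library FPKM for merged transcripts from their member isotig rows.

    ``how="max"`` (default) takes the per-library maximum over members — a
    conservative proxy for requantification; ``"sum"`` adds members.
    Singletons pass their row through unchanged.
    """
    if how not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {how!r}")
    rows = {}
    for m in raw_transcripts:
        member_ids = list(m.members) if m.members else [m.transcript_id]
        missing = [t for t in member_ids if t not in expr.values.index]
        if missing:
            raise KeyError(f"transcripts absent from expression table: {missing}")
        block = expr.values.loc[member_ids]
        rows[m.transcript_id] = block.max(axis=0) if how == "max" else block.sum(axis=0)
    import pandas as pd

    df = pd.DataFrame(rows).T if rows else expr.values.iloc[0:0].copy()
    df = df[expr.libraries] if len(df) else df
    return ExpressionTable(df, dict(expr.library_meta))


def filter_length_expression(
    raw_transcripts: Sequence[TranscriptModel],
    expr: ExpressionTable,
    min_length: int = 200,
    min_max_fpkm: float = 1.0,
) -> list[TranscriptModel]:
    """Keep transcripts with mature length >= min_length AND max FPKM >= min_max_fpkm.

    Removal is strict on both sides: length < 200 bp, or FPKM below 1 in
    every library.
    """
    kept = []
    for m in raw_transcripts:
        fpkm = expr.row(m.transcript_id)
        if m.length >= min_length and float(np.max(fpkm)) >= min_max_fpkm:
            kept.append(m)
    return kept


def label_novelty(
    kept: Sequence[TranscriptModel],
    known_ncrna_catalog: Sequence[LabeledInterval],
) -> dict[str, str]:
    """Flag each retained transcript "known" or "novel" against the catalog.

    Known iff >=1 bp same-strand exonic overlap with a catalog interval.  All
    transcripts are retained either way; novelty is a label, not a filter.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for iv in known_ncrna_catalog:
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(iv.start, iv.end)
    flags = {}
    for m in kept:
        tree = trees.get((m.chrom, m.strand))
        hit = tree is not None and any(tree.overlap(s, e) for s, e in m.exons)
        flags[m.transcript_id] = "known" if hit else "novel"
    return flags


def run_discovery(
    isotigs: Sequence[TranscriptModel],
    reference_annotation: Sequence[TranscriptModel],
    expr: ExpressionTable,
    known_ncrna_catalog: Sequence[LabeledInterval] = (),
    min_length: int = 200,
    min_max_fpkm: float = 1.0,
) -> tuple[list[TranscriptModel], ExpressionTable, FilterReport]:
    """Full cascade; returns (retained transcripts, their expression, report)."""
    report = FilterReport(input=len(isotigs))
    stranded, unstranded = filter_stranded(isotigs)
    report.removed_unstranded = len(unstranded)
    annotated, unannotated = partition_by_annotation(stranded, reference_annotation)
    report.annotated = len(annotated)
    report.unannotated_isotigs = len(unannotated)
    raw = merge_isotigs(unannotated)
    report.merged_raw_transcripts = len(raw)
    raw_expr = aggregate_expression(raw, expr)
    kept = filter_length_expression(raw, raw_expr, min_length, min_max_fpkm)
    removed = {m.transcript_id for m in raw} - {m.transcript_id for m in kept}
    report.removed_short = sum(
        1 for m in raw if m.transcript_id in removed and m.length < min_length
    )
    report.removed_lowexpr = len(removed) - report.removed_short
    report.retained = len(kept)
    report.novelty = label_novelty(kept, known_ncrna_catalog)
    report.check()
    kept_expr = raw_expr.subset([m.transcript_id for m in kept]) if kept else raw_expr.subset([])
    return kept, kept_expr, report
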