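"""Genomic and expression features of transcript groups.

Covers mature length and exon-count summaries, mean per-base conservation
over exonic bases (uncovered bases ignored), the fraction of transcripts
overlapping a transposable element by >= 1 bp, expression summaries, and the
Jensen-Shannon tissue-specificity score between expression patterns and
condition-specific unit patterns.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import (
    ConservationTrack,
    ExpressionTable,
    LabeledInterval,
    TranscriptModel,
    ValidationError,
)


def length_exon_summary(
    group: Sequence[TranscriptModel],
) -> tuple[float, float, float]:
    """(median length, mean length, mean exon count) over mature lengths."""
    if not group:
        raise ValidationError("empty transcript group")
    lengths = np.array([m.length for m in group], dtype=float)
    exons = np.array([m.n_exons for m in group], dtype=float)
    return float(np.median(lengths)), float(lengths.mean()), float(exons.mean())


def mean_conservation(
    transcript: TranscriptModel, track: ConservationTrack
) -> float | None:
    """Mean score over the transcript's exonic bases that carry a score.

    Returns None when no exonic base is covered by the track; such
    transcripts are excluded from group means rather than counted as zero.
    """
    total, covered = 0.0, 0
    for s, e in transcript.exons:
        t, c = track.sum_and_coverage(transcript.chrom, s, e)
        total += t
        covered += c
    if covered == 0:
        return None
    return total / covered


def group_mean_conservation(
    group: Sequence[TranscriptModel], track: ConservationTrack
) -> float | None:
    vals = [mean_conservation(m, track) for m in group]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


def te_overlap_fraction(
    records: Sequence[TranscriptModel],
    repeat_intervals: Sequence[LabeledInterval],
) -> float:
    """Fraction of transcripts sharing >= 1 exonic base with any repeat.

    Strand-blind: repeat annotations carry no usable strand here.
    """
    if not records:
        return 0.0
    trees: dict[str, IntervalTree] = {}
    for iv in repeat_intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    n_hit = 0
    for m in records:
        tree = trees.get(m.chrom)
        if tree is not None and any(tree.overlap(s, e) for s, e in m.exons):
            n_hit += 1
    return n_hit / len(records)


def expression_summary(
    records: Sequence[TranscriptModel] | Sequence[str],
    expr: ExpressionTable,
    stat: str = "max",
) -> tuple[float, float]:
    """(median, mean) of the per-transcript expression statistic.

    The per-transcript statistic is the maximum FPKM over libraries by
    default (consistent with the expression filter); ``stat="mean"`` averages
    over libraries instead.
    """
    if stat not in ("max", "mean"):
        raise ValueError(f"unknown statistic {stat!r}")
    ids = [m.transcript_id if isinstance(m, TranscriptModel) else m for m in records]
    if not ids:
        raise ValidationError("empty transcript group")
    sub = expr.subset(ids).values.to_numpy()
    per_tx = sub.max(axis=1) if stat == "max" else sub.mean(axis=1)
    return float(np.median(per_tx)), float(per_tx.mean())


# ---------------------------------------------------------------------------
# Jensen-Shannon tissue specificity
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    return _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))


def js_specificity(
    expr_vector: Sequence[float],
    condition_partition: Mapping[str, Sequence[int]],
    per_library: bool = False,
) -> float | None:
    """Maximum Jensen-Shannon specificity score over conditions, in [0, 1].

    The expression vector is collapsed to condition means and normalised to a
    probability vector p; for each condition t the score is
    1 - sqrt(JSD(p, e_t)) with base-2 logs, where e_t is the unit vector of
    condition t.  The transcript score is the maximum over conditions; 1 iff
    expression is confined to a single condition.  With ``per_library`` the
    probability vector stays at library resolution and e_t is uniform over
    the condition's libraries.  An all-zero vector returns None (excluded).
    """
    x = np.asarray(expr_vector, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative expression values")
    if x.sum() == 0:
        return None
    conditions = list(condition_partition)
    if per_library:
        p = x / x.sum()
        best = -math.inf
        for t in conditions:
            e = np.zeros_like(p)
            idx = np.asarray(condition_partition[t], dtype=int)
            e[idx] = 1.0 / len(idx)
            best = max(best, 1.0 - math.sqrt(max(_js_divergence(p, e), 0.0)))
        return best
    means = np.array([x[np.asarray(condition_partition[t], dtype=int)].mean()
                      for t in conditions])
    p = means / means.sum()
    best = -math.inf
    for i, _t in enumerate(conditions):
        e = np.zeros(len(conditions))
        e[i] = 1.0
        best = max(best, 1.0 - math.sqrt(max(_js_divergence(p, e), 0.0)))
    return best


def js_table(expr: ExpressionTable, per_library: bool = False) -> pd.DataFrame:
    """Per-transcript regional and stage JS specificity scores.

    Columns ``js_region`` and ``js_stage``; all-zero transcripts get NaN.
    """
    libs = expr.libraries
    region_part = {
        r: [libs.index(l) for l in ls] for r, ls in expr.libraries_by_region().items()
    }
    stage_part = {
        s: [libs.index(l) for l in ls] for s, ls in expr.libraries_by_stage().items()
    }
    rows = {}
    for tid in expr.transcripts:
        vec = expr.row(tid)
        rows[tid] = (
            js_specificity(vec, region_part, per_library),
            js_specificity(vec, stage_part, per_library),
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["js_region", "js_stage"])
    return df.astype(float)


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sided two-sample t-test p-value (Student's by default, Welch optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2 for a t-test")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def summarize_groups(
    groups: Mapping[str, Sequence[TranscriptModel]],
    expr: ExpressionTable,
    track: ConservationTrack | None = None,
    repeats: Sequence[LabeledInterval] = (),
    reference_group: str = "mRNA",
) -> pd.DataFrame:
    """Per-group feature summary with t-test p-values vs the reference group.

    One row per group: n, median/mean length, mean exon count, mean
    conservation, TE-overlap fraction, median/mean max-library FPKM, and the
    length-comparison p-value against ``reference_group`` (NaN for the
    reference itself or when either group is too small).
    """
    rows = []
    ref_lengths = (
        [m.length for m in groups[reference_group]] if reference_group in groups else []
    )
    for name, models in groups.items():
        if not models:
            continue
        med_len, mean_len, mean_ex = length_exon_summary(models)
        med_fpkm, mean_fpkm = expression_summary(models, expr)
        cons = group_mean_conservation(models, track) if track is not None else None
        te = te_overlap_fraction(models, repeats)
        lengths = [m.length for m in models]
        if name != reference_group and len(ref_lengths) >= 2 and len(lengths) >= 2:
            p_len = group_compare(lengths, ref_lengths)
        else:
            p_len = float("nan")
        rows.append(
            {
                "group": name,
                "n": len(models),
                "median_length": med_len,
                "mean_length": mean_len,
                "mean_exons": mean_ex,
                "mean_conservation": float("nan") if cons is None else cons,
                "te_overlap_fraction": te,
                "median_max_fpkm": med_fpkm,
                "mean_max_fpkm": mean_fpkm,
                "p_length_vs_ref": p_len,
            }
        )
    return pd.DataFrame(rows).set_index("group")
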