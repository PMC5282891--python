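"""Differential expression between pooled library groups, noise-cloud style.

For a comparison scheme the per-transcript signal is (M, D): M the log2
ratio of pseudocounted group means, D the absolute difference of group
means.  An empirical null cloud of (M0, D0) is built from all transcripts
across within-condition library pairs (libraries of the same skin region
act as replicates).  The probability of differential expression is the
fraction of null points strictly dominated by the signal:
q = P(|M0| < |M| and D0 < D).  Transcripts with q > 0.7 are called DE.
An externally computed q table can be plugged in unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, ValidationError


@dataclass(frozen=True)
class ComparisonScheme:
    """Named comparison of two disjoint library groups."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValidationError(f"scheme {self.name!r}: empty group")
        if set(self.group_a) & set(self.group_b):
            raise ValidationError(f"scheme {self.name!r}: groups overlap")

    def swapped(self) -> "ComparisonScheme":
        return ComparisonScheme(self.name + "_swapped", self.group_b, self.group_a)


def build_schemes(
    library_meta: Mapping[str, tuple[str, str]],
    region_pair: tuple[str, str] = ("AD", "PD"),
) -> list[ComparisonScheme]:
    """Regional pooled schemes plus pairwise temporal schemes within regions.

    Regional schemes pool consecutive stage pairs across the two regions
    (e.g. E8+E9 anterior vs E8+E9 posterior); temporal schemes compare each
    stage pair within one region, one library a side.
    """
    by_region_stage: dict[tuple[str, str], str] = {}
    for lib, (region, stage) in library_meta.items():
        if (region, stage) in by_region_stage:
            raise ValidationError(f"duplicate (region, stage) pair for library {lib!r}")
        by_region_stage[(region, stage)] = lib
    def stage_key(stage: str):
        # natural order: E8 < E9 < E12
        m = re.search(r"(\d+)", stage)
        return (0, int(m.group(1)), stage) if m else (1, 0, stage)

    regions = sorted({r for r, _s in by_region_stage})
    stages = sorted({s for _r, s in by_region_stage}, key=stage_key)
    schemes: list[ComparisonScheme] = []
    ra, rb = region_pair
    if ra in regions and rb in regions:
        shared = [
            s for s in stages
            if (ra, s) in by_region_stage and (rb, s) in by_region_stage
        ]
        for s1, s2 in zip(shared, shared[1:]):
            schemes.append(
                ComparisonScheme(
                    name=f"regional_{s1}{s2}",
                    group_a=(by_region_stage[(ra, s1)], by_region_stage[(ra, s2)]),
                    group_b=(by_region_stage[(rb, s1)], by_region_stage[(rb, s2)]),
                )
            )
    for region in regions:
        present = [s for s in stages if (region, s) in by_region_stage]
        for s1, s2 in combinations(present, 2):
            schemes.append(
                ComparisonScheme(
                    name=f"temporal_{region}_{s1}{s2}",
                    group_a=(by_region_stage[(region, s1)],),
                    group_b=(by_region_stage[(region, s2)],),
                )
            )
    return schemes


def _check_libs(expr: ExpressionTable, libs: Sequence[str]) -> None:
    missing = [l for l in libs if l not in expr.values.columns]
    if missing:
        raise ValidationError(f"libraries absent from expression table: {missing}")


def md_statistic(
    expr: ExpressionTable, scheme: ComparisonScheme, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-transcript (M, D) for one scheme.

    M = log2((mean_a + c) / (mean_b + c)); D = |mean_a - mean_b|.
    """
    _check_libs(expr, scheme.group_a + scheme.group_b)
    a = expr.values[list(scheme.group_a)].mean(axis=1)
    b = expr.values[list(scheme.group_b)].mean(axis=1)
    m = np.log2((a + pseudocount) / (b + pseudocount))
    d = (a - b).abs()
    return pd.DataFrame({"M": m, "D": d})


def default_null_pairs(
    library_meta: Mapping[str, tuple[str, str]]
) -> list[tuple[str, str]]:
    """All within-region library pairs: same-condition replicates for the null."""
    by_region: dict[str, list[str]] = {}
    for lib, (region, _stage) in library_meta.items():
        by_region.setdefault(region, []).append(lib)
    pairs = []
    for libs in by_region.values():
        pairs.extend(combinations(sorted(libs), 2))
    return pairs


def noise_null(
    expr: ExpressionTable,
    within_condition_pairs: Sequence[tuple[str, str]],
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Pooled empirical null cloud: one (M0, D0) per transcript per pair."""
    if not within_condition_pairs:
        raise ValidationError("no within-condition pairs for the noise null")
    points = []
    for lib_a, lib_b in within_condition_pairs:
        _check_libs(expr, [lib_a, lib_b])
        a = expr.values[lib_a].to_numpy()
        b = expr.values[lib_b].to_numpy()
        m0 = np.log2((a + pseudocount) / (b + pseudocount))
        d0 = np.abs(a - b)
        points.append(np.column_stack([m0, d0]))
    return np.concatenate(points, axis=0)


def q_probability(m: float, d: float, null_cloud: np.ndarray) -> float:
    """Fraction of null points strictly dominated: |M0| < |M| and D0 < D."""
    if null_cloud.size == 0:
        raise ValidationError("empty null cloud")
    dominated = (np.abs(null_cloud[:, 0]) < abs(m)) & (null_cloud[:, 1] < d)
    return float(dominated.mean())


def q_table(md: pd.DataFrame, null_cloud: np.ndarray) -> pd.Series:
    """Vectorised q for every transcript in an (M, D) table."""
    if null_cloud.size == 0:
        raise ValidationError("empty null cloud")
    abs0 = np.abs(null_cloud[:, 0])
    d0 = null_cloud[:, 1]
    qs = np.empty(len(md))
    m_sig = md["M"].to_numpy()
    d_sig = md["D"].to_numpy()
    # exact 2-D dominance count, blocked to bound memory
    block = 512
    for i in range(0, len(md), block):
        msl = np.abs(m_sig[i : i + block])[:, None]
        dsl = d_sig[i : i + block][:, None]
        qs[i : i + block] = ((abs0[None, :] < msl) & (d0[None, :] < dsl)).mean(axis=1)
    return pd.Series(qs, index=md.index, name="q")


def run_comparison(
    expr: ExpressionTable,
    scheme: ComparisonScheme,
    null_cloud: np.ndarray,
    pseudocount: float = 0.5,
    q_threshold: float = 0.7,
    external_q: pd.Series | None = None,
) -> pd.DataFrame:
    """Full (M, D, q, call) table for one scheme; q > threshold defines a call.

    ``external_q`` substitutes a q column computed by an external method
    (e.g. a full NOISeq run) keyed by transcript id.
    """
    md = md_statistic(expr, scheme, pseudocount)
    if external_q is not None:
        missing = [t for t in md.index if t not in external_q.index]
        if missing:
            raise ValidationError(f"external q missing transcripts: {missing}")
        q = external_q.loc[md.index].astype(float)
        q.name = "q"
    else:
        q = q_table(md, null_cloud)
    out = md.copy()
    out["q"] = q
    out["call"] = out["q"] > q_threshold
    return out


def regional_de_calls(
    expr: ExpressionTable,
    pseudocount: float = 0.5,
    q_threshold: float = 0.7,
) -> tuple[dict[str, pd.DataFrame], set[str]]:
    """Run all regional schemes; a transcript is DE when called in any of them."""
    schemes = [s for s in build_schemes(expr.library_meta) if s.name.startswith("regional")]
    null_cloud = noise_null(expr, default_null_pairs(expr.library_meta), pseudocount)
    results = {}
    called: set[str] = set()
    for scheme in schemes:
        res = run_comparison(expr, scheme, null_cloud, pseudocount, q_threshold)
        results[scheme.name] = res
        called |= set(res.index[res["call"]])
    return results, called
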