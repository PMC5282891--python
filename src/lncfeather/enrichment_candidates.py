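"""Per-cluster term enrichment and candidate lncRNA selection.

Enrichment is a one-sided Fisher's exact (hypergeometric) test of term
over-representation in a cluster against the expressed background, with
Benjamini-Hochberg adjustment per cluster; significance requires p < 0.01
and FDR < 0.05.  Candidate selection conjoins three criteria: membership in
a selected co-expression cluster, a regional differential-expression call,
and a cross-species sequence-similarity hit on the homologous chromosome.
Cross-species similarity uses exact k-mer seeding with ungapped extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Fisher / BH enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    cluster_genes: Iterable[str],
    background_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test for every term present in the cluster.

    ``term_map`` maps gene -> terms.  For a term with K carriers among N
    background genes and k carriers among the n cluster genes,
    p = P(X >= k), X ~ Hypergeom(N, K, n).  BH is applied across the
    cluster's tested terms (those with k >= 1).
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    if not background:
        raise ValidationError("empty background gene set")
    if not cluster <= background:
        raise ValidationError("cluster genes must be a subset of the background")
    n, N = len(cluster), len(background)
    term_carriers: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_carriers.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_carriers):
        carriers = term_carriers[term]
        k = len(carriers & cluster)
        if k < 1:
            continue
        K = len(carriers)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = (df["p"] < p_cutoff) & (df["fdr"] < fdr_cutoff)
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df.sort_values(["p", "term"]).reset_index(drop=True)


def read_term_map(path) -> dict[str, set[str]]:
    """TSV with columns gene_id, term_id (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise ValidationError("term map needs columns gene_id and term_id")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.gene_id, set()).add(row.term_id)
    return out


# ---------------------------------------------------------------------------
# Cross-species sequence similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    target_id: str
    length: int
    identity: float
    strand: str            # strand of the query matching the target ('+' or '-')
    chrom_match: bool


def _validate_seq(name: str, seq: str) -> str:
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValidationError(f"sequence {name!r} contains symbols outside ACGTN")
    return seq


def _diagonal_hit(
    q: str, t: str, k: int, min_length: int, min_identity: float
) -> tuple[int, float] | None:
    """Best ungapped hit between q and t, or None.

    Detection: some diagonal window of exactly ``min_length`` bases contains
    an exact k-mer seed and has >= ceil(min_identity * min_length) matches.
    The reported hit greedily extends that window while identity stays at or
    above ``min_identity``.
    """
    if len(q) < k or len(t) < k:
        return None
    seeds: dict[str, list[int]] = {}
    for i in range(len(t) - k + 1):
        kmer = t[i : i + k]
        if "N" not in kmer:
            seeds.setdefault(kmer, []).append(i)
    need = int(np.ceil(min_identity * min_length))
    best: tuple[int, float] | None = None
    seen_diagonals: set[int] = set()
    for i in range(len(q) - k + 1):
        for j in seeds.get(q[i : i + k], ()):
            diag = i - j
            if diag in seen_diagonals:
                continue
            seen_diagonals.add(diag)
            q_lo = max(0, diag)
            q_hi = min(len(q), len(t) + diag)
            if q_hi - q_lo < min_length:
                continue
            qs = np.frombuffer(q[q_lo:q_hi].encode(), dtype=np.uint8)
            ts = np.frombuffer(t[q_lo - diag : q_hi - diag].encode(), dtype=np.uint8)
            match = (qs == ts).astype(np.int32)
            csum = np.concatenate([[0], np.cumsum(match)])
            w = min_length
            window_matches = csum[w:] - csum[:-w]
            # seed positions along this diagonal, in window coordinates
            kmer_run = np.convolve(match, np.ones(k, dtype=int), mode="valid") == k
            if not kmer_run.any():
                continue
            ok = window_matches >= need
            if not ok.any():
                continue
            # window must contain a full seed: seed start s in [w_start, w_start+w-k]
            seed_starts = np.flatnonzero(kmer_run)
            hit_start = None
            for ws in np.flatnonzero(ok):
                lo = np.searchsorted(seed_starts, ws)
                if lo < len(seed_starts) and seed_starts[lo] <= ws + w - k:
                    hit_start = int(ws)
                    break
            if hit_start is None:
                continue
            # greedy extension keeping identity >= min_identity
            lo_e, hi_e = hit_start, hit_start + w
            matches = int(csum[hi_e] - csum[lo_e])
            while hi_e < len(match):
                if (matches + match[hi_e]) / (hi_e + 1 - lo_e) >= min_identity:
                    matches += int(match[hi_e])
                    hi_e += 1
                else:
                    break
            while lo_e > 0:
                if (matches + match[lo_e - 1]) / (hi_e - lo_e + 1) >= min_identity:
                    matches += int(match[lo_e - 1])
                    lo_e -= 1
                else:
                    break
            length = hi_e - lo_e
            identity = matches / length
            if best is None or (length, identity) > (best[0], best[1]):
                best = (length, identity)
    return best


def cross_species_hits(
    lncrna_sequences: Mapping[str, str],
    query_chroms: Mapping[str, str],
    target_sequences: Mapping[str, str],
    target_chroms: Mapping[str, str],
    homology_map: Mapping[str, str] | None = None,
    k: int = 11,
    min_identity: float = 0.8,
    min_length: int = 50,
    both_strands: bool = True,
) -> list[SimilarityHit]:
    """All (query, target) similarity hits across a second-species catalog.

    ``homology_map`` maps a query chromosome name to its homologous target
    chromosome; the chromosome-match flag of a hit compares the target's
    chromosome to the mapped query chromosome (identity map when None).
    """
    hits: list[SimilarityHit] = []
    homology = dict(homology_map) if homology_map else None
    for qid, qseq in lncrna_sequences.items():
        qseq = _validate_seq(qid, qseq)
        variants = [("+", qseq)]
        if both_strands:
            variants.append(("-", reverse_complement(qseq)))
        for tid, tseq in target_sequences.items():
            tseq = _validate_seq(tid, tseq)
            for strand, qvar in variants:
                found = _diagonal_hit(qvar, tseq, k, min_length, min_identity)
                if found is None:
                    continue
                q_chrom = query_chroms.get(qid)
                expected = homology.get(q_chrom, q_chrom) if homology else q_chrom
                hits.append(
                    SimilarityHit(
                        query_id=qid,
                        target_id=tid,
                        length=found[0],
                        identity=found[1],
                        strand=strand,
                        chrom_match=(target_chroms.get(tid) == expected
                                     and expected is not None),
                    )
                )
                break  # one hit per (query, target) pair is enough
    return hits


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def select_candidates(
    lncrna_ids: Sequence[str],
    cluster_labels: Mapping[str, str],
    selected_clusters: Iterable[str],
    de_called: Iterable[str],
    hits: Sequence[SimilarityHit],
) -> pd.DataFrame:
    """Three-criterion candidate report.

    candidate iff (cluster in selected_clusters) AND (regional DE call) AND
    (>= 1 cross-species hit with chromosome match).  Raises when a lncRNA is
    missing from the cluster assignment.
    """
    selected = set(selected_clusters)
    de = set(de_called)
    missing = [t for t in lncrna_ids if t not in cluster_labels]
    if missing:
        raise ValidationError(f"lncRNAs missing from cluster assignment: {missing}")
    matched_hits: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.chrom_match and h.query_id not in matched_hits:
            matched_hits[h.query_id] = h
    any_hit = {h.query_id for h in hits}
    rows = []
    for tid in lncrna_ids:
        in_cluster = cluster_labels[tid] in selected
        is_de = tid in de
        hit = matched_hits.get(tid)
        rows.append(
            {
                "transcript_id": tid,
                "cluster": cluster_labels[tid],
                "in_selected_cluster": in_cluster,
                "regional_de": is_de,
                "has_hit": tid in any_hit,
                "chrom_matched_hit": hit is not None,
                "hit_target": hit.target_id if hit else "",
                "hit_identity": hit.identity if hit else float("nan"),
                "candidate": in_cluster and is_de and hit is not None,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
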