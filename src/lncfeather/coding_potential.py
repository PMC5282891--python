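"""Coding-potential consensus filtering.

Three independent evidence streams are consumed as per-transcript tables: a
CPC-style ORF/homology score, a PLEK-style k-mer SVM score (negative values
lean noncoding for both), and the minimum protein-domain E-value from a
profile-HMM scan (missing = no hit).  A transcript is called a putative
lncRNA only when all three agree: score < -0.5 on both classifiers and no
domain hit at E < 1e-4.  A naive ORF-coverage score is provided as a
self-contained fallback scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class CodingScores:
    """Per-transcript coding-potential evidence.

    ``table`` is indexed by transcript_id with columns ``cpc_score``,
    ``plek_score`` and ``min_domain_evalue`` (NaN = no domain hit).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cpc_score", "plek_score", "min_domain_evalue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"score table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in score table")
        ev = self.table["min_domain_evalue"]
        if (ev.dropna() < 0).any():
            raise ValidationError("negative domain E-values")

    @property
    def transcripts(self) -> list[str]:
        return list(self.table.index)

    @classmethod
    def from_tsv(cls, path) -> "CodingScores":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def _require(self, column: str, universe: Iterable[str] | None) -> pd.Series:
        ids = list(universe) if universe is not None else list(self.table.index)
        missing = [t for t in ids if t not in self.table.index]
        if missing:
            raise KeyError(f"transcripts without coding scores: {missing}")
        col = self.table.loc[ids, column]
        if column != "min_domain_evalue" and col.isna().any():
            bad = col[col.isna()].index.tolist()
            raise ValidationError(f"missing {column} for transcripts: {bad}")
        return col


def call_noncoding_cpc(
    scores: CodingScores,
    cutoff: float = -0.5,
    universe: Iterable[str] | None = None,
) -> set[str]:
    """Transcripts whose CPC-style score is strictly below ``cutoff``."""
    col = scores._require("cpc_score", universe)
    return set(col.index[col < cutoff])


def call_noncoding_plek(
    scores: CodingScores,
    cutoff: float = -0.5,
    universe: Iterable[str] | None = None,
) -> set[str]:
    """Transcripts whose PLEK-style score is strictly below ``cutoff``."""
    col = scores._require("plek_score", universe)
    return set(col.index[col < cutoff])


def call_domain_free(
    scores: CodingScores,
    evalue_threshold: float = 1e-4,
    universe: Iterable[str] | None = None,
) -> set[str]:
    """Transcripts with no protein-domain hit at E < ``evalue_threshold``.

    Missing E-value (no hit at all) and E exactly at the threshold both count
    as domain-free: exclusion requires a strictly smaller E-value.
    """
    col = scores._require("min_domain_evalue", universe)
    if (col.dropna() < 0).any():
        raise ValidationError("negative domain E-values")
    keep = col.isna() | (col >= evalue_threshold)
    return set(col.index[keep])


def consensus_lncrnas(
    set_cpc: set[str], set_plek: set[str], set_domainfree: set[str]
) -> set[str]:
    """Three-way intersection: putative lncRNAs pass every filter."""
    return set_cpc & set_plek & set_domainfree


def naive_orf_score(nucleotide_sequence: str) -> float:
    """ORF-coverage score in [-1, 1]: 2 * (longest ORF nt / transcript nt) - 1.

    ORFs are complete ATG->stop reading frames (stop codon included) scanned
    in the three forward frames; a sequence with no complete ORF scores -1.
    """
    seq = nucleotide_sequence.upper()
    if len(seq) < 3:
        raise ValidationError("sequence shorter than one codon")
    if set(seq) - set("ACGTN"):
        raise ValidationError("sequence contains symbols outside ACGTN")
    longest = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                longest = max(longest, i + 3 - start)
                start = None
    if longest == 0:
        return -1.0
    return 2.0 * longest / len(seq) - 1.0


def score_transcripts_naive(sequences: dict[str, str]) -> pd.Series:
    """Naive ORF score for every sequence; a built-in stand-in score column."""
    return pd.Series({tid: naive_orf_score(seq) for tid, seq in sequences.items()})
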