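"""Deterministic synthetic genome, transcriptome and expression fixtures.

Generates a toy genome with multi-exon protein-coding genes, planted isotigs
of known class (lincRNA / intronic / lncNAT / coding fragment / unstranded /
short or low-expression decoys), an FPKM matrix with planted co-expression
clusters and anterior-vs-posterior fold changes, repeat and conservation
tracks, coding-potential score tables, a known-ncRNA catalog and a
homologous second-species catalog — all fully determined by one seed, with
the planted truth recorded alongside.

The planted geometry is written against the same predicates the discovery
and classification stages test (>= 1 bp same-strand exonic overlap, intron
containment, antisense exon overlap), so every downstream stage has an
exactly recoverable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coding_potential import CodingScores
from .io_formats import (
    ConservationTrack,
    ExpressionTable,
    LabeledInterval,
    TranscriptModel,
    ValidationError,
    spliced_sequence,
    write_bed,
    write_chrom_sizes,
    write_expression,
    write_fasta,
    write_gtf,
    write_library_meta,
    write_track,
)

#: The six-library design: anterior (AD) and posterior (PD) dorsal skin at
#: three embryonic incubation days.
DEFAULT_LIBRARY_META: dict[str, tuple[str, str]] = {
    "E8A": ("AD", "E8"),
    "E9A": ("AD", "E9"),
    "E12A": ("AD", "E12"),
    "E8P": ("PD", "E8"),
    "E9P": ("PD", "E9"),
    "E12P": ("PD", "E12"),
}

PLANTED_CLASSES = (
    "lincRNA",
    "intronic",
    "lncNAT",
    "coding_fragment",
    "unstranded",
    "short_decoy",
    "lowexpr_decoy",
)
LNCRNA_CLASSES = ("lincRNA", "intronic", "lncNAT")

_DEFAULT_COUNTS = {
    "lincRNA": 20,
    "intronic": 8,
    "lncNAT": 8,
    "coding_fragment": 10,
    "unstranded": 6,
    "short_decoy": 6,
    "lowexpr_decoy": 6,
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 500_000
    n_coding_genes: int = 30
    planted_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    known_fraction: float = 0.3
    n_clusters: int = 4
    de_fraction: float = 0.15
    de_log2fc: float = 2.0
    fpkm_noise_cv: float = 0.3
    repeat_fraction: float = 0.2
    conservation_fraction: float = 0.6
    intronic_same_strand: bool = True
    n_candidates: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.planted_counts) - set(PLANTED_CLASSES)
        if unknown:
            raise ValidationError(f"unknown planted classes: {sorted(unknown)}")
        for cls in PLANTED_CLASSES:
            self.planted_counts.setdefault(cls, 0)
        if any(v < 0 for v in self.planted_counts.values()):
            raise ValidationError("planted counts must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must be in [0, 1]")
        if not 0 <= self.known_fraction <= 1:
            raise ValidationError("known_fraction must be in [0, 1]")
        hosted = (
            self.planted_counts["intronic"]
            + self.planted_counts["lncNAT"]
            + self.planted_counts["coding_fragment"]
        )
        if self.n_coding_genes < hosted:
            raise ValidationError(
                "n_coding_genes must cover intronic + lncNAT + coding_fragment hosts"
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class GroundTruth:
    """Planted truth: per-transcript class/novelty/cluster/DE plus homology."""

    classes: dict[str, str] = field(default_factory=dict)
    known: set[str] = field(default_factory=set)
    clusters: dict[str, int] = field(default_factory=dict)
    de: set[str] = field(default_factory=set)
    selected_planted_clusters: set[int] = field(default_factory=set)
    homologs: dict[str, tuple[str, bool]] = field(default_factory=dict)  # qid -> (tid, chrom ok)
    candidates: set[str] = field(default_factory=set)

    def lncrna_ids(self) -> set[str]:
        return {t for t, c in self.classes.items() if c in LNCRNA_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.classes)
        return pd.DataFrame(
            {
                "transcript_id": ids,
                "class": [self.classes[t] for t in ids],
                "known": [t in self.known for t in ids],
                "cluster": [self.clusters.get(t, -1) for t in ids],
                "de": [t in self.de for t in ids],
                "candidate": [t in self.candidates for t in ids],
            }
        ).set_index("transcript_id")


@dataclass
class Genome:
    """Everything the generator knows about the toy genome."""

    annotation: list[TranscriptModel]
    sequences: dict[str, str]
    repeats: list[LabeledInterval]
    conservation: ConservationTrack
    chrom_sizes: dict[str, int]
    catalog: list[LabeledInterval] = field(default_factory=list)
    occupied: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    gene_models: dict[str, TranscriptModel] = field(default_factory=dict)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _overlaps_any(occupied: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in occupied)


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    span: int,
    chrom_len: int,
    pad: int,
    max_tries: int = 500,
) -> int:
    """Random start for a feature of ``span`` bases avoiding occupied regions."""
    if span + 2 * pad >= chrom_len:
        raise ValidationError("feature span exceeds chromosome; raise chrom_length_bp")
    for _ in range(max_tries):
        start = int(rng.integers(pad, chrom_len - span - pad))
        if not _overlaps_any(occupied, start - pad, start + span + pad):
            occupied.append((start - pad, start + span + pad))
            return start
    raise ValidationError(
        "could not place feature after bounded retries; raise chrom_length_bp"
    )


def _exon_chain(start: int, exon_lens, intron_lens) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    return tuple(exons)


def generate_genome(config: SyntheticConfig) -> Genome:
    """Toy genome: sequences, coding annotation, repeat + conservation tracks."""
    rng = np.random.default_rng(config.seed)
    sizes = {c: config.chrom_length_bp for c in config.chrom_names}
    sequences = {c: _random_sequence(rng, config.chrom_length_bp) for c in config.chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}

    annotation: list[TranscriptModel] = []
    gene_models: dict[str, TranscriptModel] = {}
    for g in range(config.n_coding_genes):
        chrom = config.chrom_names[g % config.n_chromosomes]
        n_exons = int(rng.integers(4, 11))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(100, 801, size=n_exons - 1)
        intron_lens[0] = int(rng.integers(400, 801))  # room for intronic plants
        span = int(exon_lens.sum() + intron_lens.sum())
        start = _place(rng, occupied[chrom], span, sizes[chrom], pad=300)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gene_id = f"G{g + 1:04d}"
        model = TranscriptModel(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=_exon_chain(start, exon_lens, intron_lens),
            biotype="protein_coding",
        )
        annotation.append(model)
        gene_models[gene_id] = model

    # repeats: one interval per 2 kb block covering repeat_fraction of the block
    repeats: list[LabeledInterval] = []
    te_classes = ("SINE", "LINE", "LTR", "DNA")
    block = 2000
    rep_len = int(round(config.repeat_fraction * block))
    for chrom in config.chrom_names:
        if rep_len == 0:
            continue
        for bs in range(0, sizes[chrom] - block + 1, block):
            offset = int(rng.integers(0, block - rep_len + 1))
            te = te_classes[int(rng.integers(0, len(te_classes)))]
            repeats.append(LabeledInterval(chrom, bs + offset, bs + offset + rep_len, te))

    # conservation: per 1 kb block, a scored interval covering the set fraction
    rows = []
    cblock = 1000
    cons_len = int(round(config.conservation_fraction * cblock))
    for chrom in config.chrom_names:
        if cons_len == 0:
            continue
        for bs in range(0, sizes[chrom] - cblock + 1, cblock):
            offset = int(rng.integers(0, cblock - cons_len + 1))
            score = round(float(rng.uniform(0.0, 1.0)), 3)
            rows.append((chrom, bs + offset, bs + offset + cons_len, score))
    conservation = ConservationTrack.from_intervals(rows)

    return Genome(
        annotation=annotation,
        sequences=sequences,
        repeats=repeats,
        conservation=conservation,
        chrom_sizes=sizes,
        occupied=occupied,
        gene_models=gene_models,
    )


def generate_isotigs(
    config: SyntheticConfig, genome: Genome
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Planted isotigs of every configured class, plus the known-ncRNA catalog.

    lincRNAs avoid every gene span; intronics sit inside the (widened) first
    intron of a host gene; lncNATs cover host exons 2-3 antisense;
    coding fragments do the same sense; decoys are intergenic.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = GroundTruth()
    isotigs: list[TranscriptModel] = []
    counts = config.planted_counts

    hosts = [m for m in genome.annotation]
    rng.shuffle(hosts)
    n_intronic, n_nat, n_frag = counts["intronic"], counts["lncNAT"], counts["coding_fragment"]
    intronic_hosts = hosts[:n_intronic]
    nat_hosts = hosts[n_intronic : n_intronic + n_nat]
    frag_hosts = hosts[n_intronic + n_nat : n_intronic + n_nat + n_frag]

    def new_id() -> str:
        return f"ISO{len(isotigs) + 1:05d}"

    def add(model: TranscriptModel, cls: str) -> None:
        isotigs.append(model)
        truth.classes[model.transcript_id] = cls

    def place_intergenic(n_exons_hi: int, exon_lo: int, exon_hi: int, strand: str) -> TranscriptModel:
        chrom = config.chrom_names[int(rng.integers(0, config.n_chromosomes))]
        n_exons = int(rng.integers(1, n_exons_hi + 1))
        exon_lens = rng.integers(exon_lo, exon_hi + 1, size=n_exons)
        intron_lens = rng.integers(100, 401, size=max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        start = _place(rng, genome.occupied[chrom], span, genome.chrom_sizes[chrom], pad=10)
        tid = new_id()
        return TranscriptModel(tid, tid, chrom, strand,
                               _exon_chain(start, exon_lens, intron_lens))

    for _ in range(counts["lincRNA"]):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        # exon length floor keeps even single-exon lincRNAs >= 200 nt mature
        add(place_intergenic(3, 250, 600, strand), "lincRNA")

    for host in intronic_hosts:
        intron = (host.exons[0][1], host.exons[1][0])  # first intron, widened
        room = intron[1] - intron[0] - 40  # 20 bp margins
        length = int(min(room, rng.integers(200, 361)))
        start = intron[0] + 20 + int(rng.integers(0, room - length + 1))
        strand = host.strand if config.intronic_same_strand else (
            "-" if host.strand == "+" else "+"
        )
        tid = new_id()
        add(TranscriptModel(tid, tid, host.chrom, strand, ((start, start + length),)),
            "intronic")

    def spanning_exon23(host: TranscriptModel, strand: str) -> TranscriptModel:
        (e2s, _), (_, e3e) = host.exons[1], host.exons[2]
        intron1_len = host.exons[1][0] - host.exons[0][1]
        f1 = int(min(50, intron1_len - 2))
        tid = new_id()
        return TranscriptModel(tid, tid, host.chrom, strand, ((e2s - f1, e3e),))

    for host in nat_hosts:
        anti = "-" if host.strand == "+" else "+"
        add(spanning_exon23(host, anti), "lncNAT")

    for host in frag_hosts:
        add(spanning_exon23(host, host.strand), "coding_fragment")

    for _ in range(counts["unstranded"]):
        add(place_intergenic(1, 250, 500, "."), "unstranded")
    for _ in range(counts["short_decoy"]):
        add(place_intergenic(1, 80, 150, "+" if rng.integers(0, 2) == 0 else "-"),
            "short_decoy")
    for _ in range(counts["lowexpr_decoy"]):
        add(place_intergenic(1, 250, 500, "+" if rng.integers(0, 2) == 0 else "-"),
            "lowexpr_decoy")

    # known-ncRNA catalog covers a seeded subset of the planted lncRNAs
    lnc_ids = sorted(truth.lncrna_ids())
    n_known = int(round(config.known_fraction * len(lnc_ids)))
    known = set(rng.choice(lnc_ids, size=n_known, replace=False)) if n_known else set()
    truth.known = known
    by_id = {m.transcript_id: m for m in isotigs}
    catalog = []
    for i, tid in enumerate(sorted(known)):
        m = by_id[tid]
        s, e = m.span
        catalog.append(LabeledInterval(m.chrom, s, e, f"NONC{i + 1:05d}", m.strand))
    genome.catalog = catalog
    return isotigs, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _templates(n_clusters: int, meta) -> np.ndarray:
    """Planted cluster mean profiles over the libraries.

    Stage-peaked templates are balanced between regions; when four or more
    clusters are requested the last template is region-biased (high in AD),
    emulating a regionally associated cluster.
    """
    libs = list(meta)
    stages = []
    for lib in libs:
        stages.append(meta[lib][1])
    stage_order = list(dict.fromkeys(stages))
    base = []
    for c in range(n_clusters):
        if n_clusters >= 4 and c == n_clusters - 1:
            base.append([5.0 if meta[lib][0] == "AD" else 1.0 for lib in libs])
        else:
            peak = stage_order[c % len(stage_order)]
            base.append([5.0 if meta[lib][1] == peak else 1.0 for lib in libs])
    return np.array(base)


def generate_expression(
    config: SyntheticConfig,
    isotigs: list[TranscriptModel],
    genome: Genome,
    truth: GroundTruth,
) -> ExpressionTable:
    """FPKM matrix over annotated genes + isotigs with planted structure.

    Fills ``truth.clusters`` (template index per transcript), ``truth.de``
    and ``truth.selected_planted_clusters``.  Explicitly planted DE
    transcripts (balanced templates) get an exact pooled AD/PD mean ratio of
    2**de_log2fc before noise; members of the region-biased template — which
    are regionally differential by construction — get the fold change
    multiplied on top of their template bias and are recorded as DE too.
    """
    rng = np.random.default_rng(config.seed + 2)
    meta = dict(DEFAULT_LIBRARY_META)
    libs = list(meta)
    n_lib = len(libs)
    templates = _templates(config.n_clusters, meta)
    biased_cluster = config.n_clusters - 1 if config.n_clusters >= 4 else None
    if biased_cluster is not None:
        truth.selected_planted_clusters = {biased_cluster}

    ann_ids = [m.transcript_id for m in genome.annotation]
    iso_ids = [m.transcript_id for m in isotigs]
    lowexpr = {t for t in iso_ids if truth.classes[t] == "lowexpr_decoy"}
    clustered = ann_ids + [t for t in iso_ids if t not in lowexpr]

    # cluster assignment: deterministic interleave, then record
    for i, tid in enumerate(clustered):
        truth.clusters[tid] = i % config.n_clusters

    # explicit DE plants: balanced-cluster members only (region-biased members
    # are differential already, by template)
    balanced = [t for t in clustered
                if truth.clusters[t] != biased_cluster]
    n_de = int(round(config.de_fraction * len(balanced)))
    de_ids = set(rng.choice(balanced, size=n_de, replace=False)) if n_de else set()
    truth.de = set(de_ids)
    if biased_cluster is not None:
        truth.de |= {t for t in clustered if truth.clusters[t] == biased_cluster}

    ad_mask = np.array([meta[l][0] == "AD" for l in libs])
    rows: dict[str, np.ndarray] = {}
    for tid in clustered:
        template = templates[truth.clusters[tid]].copy()
        base = float(rng.lognormal(mean=np.log(20.0), sigma=0.5))
        profile = base * template / template.mean()
        if tid in de_ids:
            t_ad, t_pd = template[ad_mask].mean(), template[~ad_mask].mean()
            profile[ad_mask] *= (2.0 ** config.de_log2fc) * (t_pd / t_ad)
        elif truth.clusters[tid] == biased_cluster:
            profile[ad_mask] *= 2.0 ** config.de_log2fc
        rows[tid] = profile
    for tid in sorted(lowexpr):
        rows[tid] = rng.uniform(0.05, 0.6, size=n_lib)

    values = pd.DataFrame.from_dict(rows, orient="index", columns=libs)
    values = values.loc[ann_ids + iso_ids]

    if config.fpkm_noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.fpkm_noise_cv**2)))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=values.shape)
        values = values * noise

    # guarantees: non-decoy rows pass the max-FPKM filter, decoys never do
    arr = values.to_numpy()
    for i, tid in enumerate(values.index):
        if tid in lowexpr:
            arr[i] = np.minimum(arr[i], 0.95)
        else:
            peak = arr[i].max()
            if peak < 1.2:
                arr[i] *= 1.2 / peak
    values.iloc[:, :] = arr
    return ExpressionTable(values, meta)


def generate_coding_scores(
    config: SyntheticConfig,
    isotigs: list[TranscriptModel],
    truth: GroundTruth,
) -> CodingScores:
    """Score table: noncoding-leaning for planted lncRNAs and decoys,
    coding-leaning with strong domain hits for coding fragments."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for m in isotigs:
        cls = truth.classes[m.transcript_id]
        if cls == "coding_fragment":
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "cpc_score": float(rng.uniform(0.5, 3.0)),
                    "plek_score": float(rng.uniform(0.5, 3.0)),
                    "min_domain_evalue": float(10.0 ** rng.uniform(-30, -5)),
                }
            )
        else:
            has_weak_hit = rng.uniform() < 0.1
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "cpc_score": float(rng.uniform(-2.5, -0.7)),
                    "plek_score": float(rng.uniform(-2.5, -0.7)),
                    "min_domain_evalue": float(rng.uniform(1e-3, 10.0))
                    if has_weak_hit
                    else float("nan"),
                }
            )
    return CodingScores(pd.DataFrame(rows).set_index("transcript_id"))


# ---------------------------------------------------------------------------
# Second species and term map
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.uniform(size=len(arr)) < rate
    subs = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    # force a real substitution by cycling when the draw equals the original
    orig = arr[hit]
    same = subs == orig
    idx = {65: 67, 67: 71, 71: 84, 84: 65}
    subs[same] = np.array([idx[b] for b in orig[same]], dtype=np.uint8)
    arr[hit] = subs
    return arr.tobytes().decode()


def generate_second_species(
    config: SyntheticConfig,
    isotigs: list[TranscriptModel],
    genome: Genome,
    truth: GroundTruth,
    sub_rate: float = 0.04,
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Homologous catalog for cross-species similarity, plus the homology map.

    Designated candidates (members of the region-biased cluster) receive
    same-chromosome homologs; controls receive a wrong-chromosome homolog, a
    matched homolog without the other criteria, or nothing.  Returns
    (target_sequences, target_chroms, homology_map) and fills
    ``truth.homologs`` / ``truth.candidates``.
    """
    rng = np.random.default_rng(config.seed + 4)
    by_id = {m.transcript_id: m for m in isotigs}
    homology = {c: f"g{c}" for c in config.chrom_names}

    lnc_sorted = sorted(truth.lncrna_ids())
    selected_members = [
        t for t in lnc_sorted
        if truth.clusters.get(t) in truth.selected_planted_clusters
    ]
    others = [t for t in lnc_sorted if t not in selected_members]
    candidates = selected_members[: config.n_candidates]
    truth.candidates = set(candidates)

    targets: dict[str, str] = {}
    target_chroms: dict[str, str] = {}

    def plant(qid: str, chrom_ok: bool) -> None:
        m = by_id[qid]
        qseq = spliced_sequence(m, genome.sequences[m.chrom])
        tid = f"tgt_{qid}"
        targets[tid] = _mutate(rng, qseq, sub_rate)
        if chrom_ok:
            target_chroms[tid] = homology[m.chrom]
        else:
            wrong = [homology[c] for c in config.chrom_names if homology[c] != homology[m.chrom]]
            target_chroms[tid] = wrong[0] if wrong else "gNOWHERE"
        truth.homologs[qid] = (tid, chrom_ok)

    for qid in candidates:
        plant(qid, chrom_ok=True)
    # controls: fails chromosome match / fails cluster + DE / no homolog at all
    extra_selected = selected_members[config.n_candidates :]
    if extra_selected:
        plant(extra_selected[0], chrom_ok=False)
    non_de_others = [t for t in others if t not in truth.de]
    if non_de_others:
        plant(non_de_others[0], chrom_ok=True)
    # unrelated decoy targets
    for i in range(2):
        tid = f"tgt_random{i + 1}"
        targets[tid] = _random_sequence(rng, 400)
        target_chroms[tid] = homology[config.chrom_names[i % config.n_chromosomes]]
    return targets, target_chroms, homology


def generate_term_map(
    config: SyntheticConfig,
    genome: Genome,
    truth: GroundTruth,
) -> dict[str, set[str]]:
    """Term annotations with one strongly cluster-specific term per cluster."""
    rng = np.random.default_rng(config.seed + 5)
    out: dict[str, set[str]] = {}
    for m in genome.annotation:
        tid = m.transcript_id
        terms = set()
        cluster = truth.clusters.get(tid)
        if cluster is not None and rng.uniform() < 0.8:
            terms.add(f"TERM_CLUSTER_{cluster}")
        if rng.uniform() < 0.5:
            terms.add("TERM_COMMON")
        if rng.uniform() < 0.2:
            terms.add(f"TERM_NOISE_{int(rng.integers(0, 5))}")
        if terms:
            out[tid] = terms
    return out


# ---------------------------------------------------------------------------
# Full fixture
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    config: SyntheticConfig
    genome: Genome
    isotigs: list[TranscriptModel]
    truth: GroundTruth
    expression: ExpressionTable
    scores: CodingScores
    targets: dict[str, str]
    target_chroms: dict[str, str]
    homology: dict[str, str]
    term_map: dict[str, set[str]]

    def isotig_sequences(self) -> dict[str, str]:
        return {
            m.transcript_id: spliced_sequence(m, self.genome.sequences[m.chrom])
            for m in self.isotigs
        }


def generate_fixture(config: SyntheticConfig) -> Fixture:
    """Run the full generator chain under one config."""
    genome = generate_genome(config)
    isotigs, truth = generate_isotigs(config, genome)
    expression = generate_expression(config, isotigs, genome, truth)
    scores = generate_coding_scores(config, isotigs, truth)
    targets, target_chroms, homology = generate_second_species(
        config, isotigs, genome, truth
    )
    term_map = generate_term_map(config, genome, truth)
    return Fixture(
        config, genome, isotigs, truth, expression, scores,
        targets, target_chroms, homology, term_map,
    )


def write_fixture(fixture: Fixture, outdir) -> dict[str, str]:
    """Write the complete fixture as standard files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "isotigs_gtf": outdir / "isotigs.gtf",
        "annotation_gtf": outdir / "annotation.gtf",
        "expression_tsv": outdir / "expression.tsv",
        "library_meta_tsv": outdir / "library_meta.tsv",
        "scores_tsv": outdir / "coding_scores.tsv",
        "catalog_bed": outdir / "known_ncrna.bed",
        "repeats_bed": outdir / "repeats.bed",
        "conservation_bedgraph": outdir / "conservation.bedgraph",
        "chrom_sizes": outdir / "chrom.sizes",
        "genome_fasta": outdir / "genome.fa",
        "transcripts_fasta": outdir / "transcripts.fa",
        "targets_fasta": outdir / "second_species.fa",
        "targets_bed": outdir / "second_species.bed",
        "homology_tsv": outdir / "homology.tsv",
        "term_map_tsv": outdir / "term_map.tsv",
        "truth_tsv": outdir / "ground_truth.tsv",
        "truth_json": outdir / "ground_truth.json",
    }
    write_gtf(fixture.isotigs, paths["isotigs_gtf"])
    write_gtf(fixture.genome.annotation, paths["annotation_gtf"])
    write_expression(fixture.expression, paths["expression_tsv"])
    write_library_meta(fixture.expression.library_meta, paths["library_meta_tsv"])
    fixture.scores.to_tsv(paths["scores_tsv"])
    write_bed(fixture.genome.catalog, paths["catalog_bed"])
    write_bed(fixture.genome.repeats, paths["repeats_bed"])
    write_track(fixture.genome.conservation, paths["conservation_bedgraph"])
    write_chrom_sizes(fixture.genome.chrom_sizes, paths["chrom_sizes"])
    write_fasta(fixture.genome.sequences, paths["genome_fasta"])
    write_fasta(fixture.isotig_sequences(), paths["transcripts_fasta"])
    write_fasta(fixture.targets, paths["targets_fasta"])
    write_bed(
        [
            LabeledInterval(chrom, 0, max(len(fixture.targets[tid]), 1), tid)
            for tid, chrom in fixture.target_chroms.items()
        ],
        paths["targets_bed"],
    )
    with open(paths["homology_tsv"], "w") as fh:
        fh.write("query_chrom\ttarget_chrom\n")
        for q, t in fixture.homology.items():
            fh.write(f"{q}\t{t}\n")
    with open(paths["term_map_tsv"], "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(fixture.term_map):
            for term in sorted(fixture.term_map[gene]):
                fh.write(f"{gene}\t{term}\n")
    fixture.truth.to_frame().to_csv(paths["truth_tsv"], sep="\t")
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "selected_planted_clusters": sorted(fixture.truth.selected_planted_clusters),
                "candidates": sorted(fixture.truth.candidates),
                "homologs": {q: list(v) for q, v in sorted(fixture.truth.homologs.items())},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return {k: str(v) for k, v in paths.items()}


def generate_de_benchmark(
    seed: int,
    n_transcripts: int = 200,
    de_fraction: float = 0.25,
    de_log2fc: float = 2.0,
    fpkm_noise_cv: float = 0.3,
) -> tuple[ExpressionTable, set[str]]:
    """Flat-profile expression benchmark with a planted AD-vs-PD fold change.

    Baseline abundance is log-normal (median 20 FPKM, ln-sd 0.8); DE
    transcripts have their anterior libraries multiplied by 2**de_log2fc, so
    the pooled AD/PD mean ratio is exact before noise.  Used to measure the
    sensitivity and false-positive rate of the q > 0.7 call.
    """
    rng = np.random.default_rng(seed)
    meta = dict(DEFAULT_LIBRARY_META)
    libs = list(meta)
    ad_mask = np.array([meta[l][0] == "AD" for l in libs])
    ids = [f"T{i + 1:04d}" for i in range(n_transcripts)]
    n_de = int(round(de_fraction * n_transcripts))
    de_ids = set(rng.choice(ids, size=n_de, replace=False)) if n_de else set()
    base = rng.lognormal(mean=np.log(20.0), sigma=0.8, size=n_transcripts)
    values = np.tile(base[:, None], (1, len(libs)))
    de_rows = np.array([t in de_ids for t in ids])
    values[np.ix_(de_rows, ad_mask)] *= 2.0 ** de_log2fc
    if fpkm_noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(fpkm_noise_cv**2)))
        values = values * rng.lognormal(-sigma**2 / 2, sigma, size=values.shape)
    table = ExpressionTable(pd.DataFrame(values, index=ids, columns=libs), meta)
    return table, de_ids
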