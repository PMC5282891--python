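# Methods

## Scope and model

`lncfeather` reimplements a stringent lncRNA identification pipeline for
stranded RNA-seq assemblies of embryonic skin: six libraries covering two
dorsal skin regions (anterior AD, posterior PD) at three embryonic
incubation days (E8, E9, E12). The pipeline's inputs are products of
upstream tools — assembled transcript models (GTF), per-library FPKM, and
per-transcript coding-potential scores — because read mapping, assembly and
the external classifiers (CPC, PLEK, profile-HMM domain scans) are not the
subject of the package; their outputs are consumed as tables.

All coordinates are 0-based half-open internally. GTF converts at the I/O
boundary; BED and bedGraph pass through. Strand is `+`, `-` or `.`
(unknown); unknown strand is never coerced because the first discovery
filter is defined on it.

## Discovery cascade

1. **Strand filter.** Isotigs without strand information are removed.
2. **Annotation partition.** An isotig is "annotated" iff ≥ 1 bp of its
   exons overlaps ≥ 1 bp of an annotated exon *on the same strand*. The
   same-strand, exon-level reading is deliberate: a strand-blind or
   gene-span-level filter would eliminate the antisense and intronic
   lncRNAs the rest of the pipeline is designed to find.
3. **Merging.** Unannotated isotigs sharing ≥ 1 exonic base on one
   chromosome and strand are merged single-linkage; the merged exon
   structure is the base union of members. Exon-base (not span) overlap is
   used so transcripts interleaving inside a long intron are not fused.
   Single-member groups keep their isotig id, which makes discovery
   idempotent; fusions get sequential `RT` ids. Because merged transcripts
   have no FPKM row of their own, their per-library value is the maximum
   over members (a conservative proxy for requantification; `sum` is
   available).
4. **Length/expression filter.** Removal is strict: mature length
   (Σ exon lengths, not genomic span) < 200 nt, or FPKM below 1 in every
   library. A transcript with max FPKM exactly 1 is kept.
5. **Novelty.** Overlap (≥ 1 bp, same strand) with a known-ncRNA catalog
   labels a transcript "known"; the label never removes anything. The
   criterion is treated as labeling because a removal reading would
   contradict the catalog-recorded transcripts that downstream stages keep.

## Coding-potential consensus

Noncoding calls are strict: CPC-style score < −0.5, PLEK-style score
< −0.5, and domain exclusion only at E < 10⁻⁴ (a missing E-value means no
hit and is retained; E exactly 10⁻⁴ is retained). The boundary direction at
exactly −0.5 is not prescribed anywhere; the strict `<` is fixed here for
determinism. Missing scores raise rather than silently passing. The
consensus is the exact three-way intersection; it is monotone in every
cutoff. A naive fallback scorer is included as plumbing:
`2·(longest complete ATG→stop ORF length / transcript length) − 1` over the
three forward frames, −1 when no complete ORF exists.

## Positional classification

Precedence lncNAT ≻ intronic ≻ lincRNA:

* **lncNAT** — ≥ 1 bp exonic overlap with a coding exon on the opposite
  strand (the most specific signal, tested first).
* **intronic** — the whole exon set inside a single intron of one coding
  gene, no coding-exon overlap on either strand. Containment is accepted on
  either strand by default; `intronic_same_strand_only=True` restricts to
  the host strand, and an intron-contained antisense transcript then falls
  to lincRNA.
* **lincRNA** — no overlap with any coding gene span.

Transcripts matching none of the three (straddling a gene boundary without
exonic overlap) go to intronic when the majority of their exonic bases fall
inside a gene span, else lincRNA. This fallback is an artifact decision for
a case the definitions leave open. The three classes partition the input,
and the assignment is invariant under flipping every strand.

## Feature statistics

* Lengths are mature lengths; the median of an even-sized group is the mean
  of the central pair.
* Mean conservation averages per-base scores over *scored exonic bases
  only*; unscored bases are ignored, and a transcript with no scored base
  is missing (excluded from group means), not zero.
* TE overlap is the fraction of transcripts sharing ≥ 1 exonic base with
  any repeat interval, strand-blind (repeat annotations carry no usable
  strand).
* The per-transcript expression statistic is the max over libraries
  (consistent with the discovery filter); mean-over-libraries is a flag.
* Jensen–Shannon specificity: the expression vector is collapsed to
  condition means (regions {AD, PD} or stages {E8, E9, E12}) and normalised
  to a probability vector p; for condition t with unit vector e_t,
  `score_t = 1 − sqrt(JSD(p, e_t))` with base-2 logs, and the transcript
  score is `max_t score_t`. Scores live in [0, 1] and reach 1 iff
  expression is confined to one condition. Condition-mean vectors are the
  default; per-library probability vectors are a flag. All-zero vectors are
  missing, not 0.
* Group comparisons use a two-sided two-sample t-test, Student's by
  default, Welch behind a flag.

## Co-expression clustering

Expressed transcripts (FPKM > 1, strict, in ≥ 1 library) are z-scaled per
transcript across the six libraries with the population sd (divisor n;
sample sd behind a flag); constant profiles map to all-zero rows with a
warning. The distance is 1 − Pearson correlation of the scaled profiles
(Euclidean optional). On population-z rows Pearson r is the normalised dot
product, which keeps formerly constant rows well defined (r = 0). Trees use
the WPGMA rule d(k, i∪j) = (d(k,i) + d(k,j))/2 via
`scipy.cluster.hierarchy.linkage(method="weighted")`; flat clusters are the
components after severing merges strictly above the cut (default 0.69,
interpreted on the correlation-distance scale — the original scale is not
recorded anywhere, so recovering any particular cluster count on real data
is not a contract of the package). Minimum-distance ties follow the linkage
implementation's deterministic ordering. Labels are letters in order of
first appearance, so runs are reproducible given input order.

## Differential expression

For a comparison scheme (two disjoint library groups), the per-transcript
signal is M = log2((mean_a + c)/(mean_b + c)) with pseudocount c = 0.5, and
D = |mean_a − mean_b|. The regional schemes pool consecutive stage pairs
(E8A+E9A vs E8P+E9P; E9A+E12A vs E9P+E12P); temporal schemes compare stage
pairs within a region. The null cloud pools one (M₀, D₀) point per
transcript per within-region library pair — libraries of one region act as
replicates. The probability of differential expression is the fraction of
null points strictly dominated by the signal, q = P(|M₀| < |M| and D₀ < D),
and q > 0.7 defines a call. This dominance probability is a deliberately
simple, exactly enumerable stand-in for a kernel-smoothed noise-distribution
odds; an externally computed q table can be plugged in unchanged
(`--external-q`). q is monotone in |M| and D, and swapping the groups
negates M while preserving D and q.

Because the null pairs span different stages, real stage-driven variation
inflates the null cloud; this mirrors the replicate-pooling design it
emulates and is the main source of conservatism in the calls.

## Enrichment and candidate selection

Per cluster, each term present in the cluster is tested one-sided for
over-representation against the expressed background:
p = P(X ≥ k) with X hypergeometric(N, K, n), BH-adjusted across the
cluster's terms; significance requires p < 0.01 *and* FDR < 0.05.
One-sidedness is the standard enrichment convention.

Cross-species similarity is an exact k-mer seed (k = 11) with ungapped
extension: a hit exists iff some diagonal window of exactly 50 nt contains
a seed and ≥ ⌈0.8·50⌉ matches; the reported hit greedily extends that
window while identity stays ≥ 0.8, optionally on both strands. The
fixed-length detection rule keeps the implementation provably identical to
a brute-force all-window oracle. The thresholds are artifact defaults — no
algorithm or cutoffs are prescribed for this step. Chromosome matching maps
the query chromosome through a user-supplied homology table.

A candidate lncRNA must satisfy all three criteria: membership in a
selected cluster, a regional DE call in ≥ 1 scheme, and ≥ 1 cross-species
hit on the homologous chromosome. The selected clusters are an input: the
filtering that picks biologically interesting clusters from enrichment
output is interpretation, not computation, and stays outside the package.

## Synthetic data

The generator emulates the study design, not its sequences: random-base
chromosomes (default 3 × 500 kb), 30 multi-exon coding genes (4–10 exons of
80–300 bp, introns 100–800 bp, first intron ≥ 400 bp to host intronic
plants), and planted isotigs written against the exact predicates the
pipeline tests: lincRNAs avoid every gene span; intronic lncRNAs sit inside
a first intron with 20 bp margins; lncNATs cover host exons 2–3 antisense;
coding fragments do the same sense (and are therefore removed at the
annotation partition); decoys are unstranded, short (< 200 nt) or
low-expression (< 1 FPKM everywhere, enforced after noise). Defaults plant
20/8/8 lncRNAs, 10 coding fragments and 6 of each decoy, with 30 % of
lncRNAs entered in the known-ncRNA catalog.

Expression: four planted cluster templates over the six libraries — three
stage-peaked and region-balanced, one region-biased (AD-high), which plays
the role of the regionally associated cluster from which candidates are
drawn. Pairwise correlation distances between the z-scaled templates are
≥ 1.0, comfortably above the 0.69 cut, so the noise-free tree cut recovers
the planted partition exactly. Per-transcript abundance is log-normal
(median 20 FPKM, ln-sd 0.5); noise is multiplicative log-normal
parameterised by a CV (default 0.3; 0 for exact-recovery checks).
Explicitly planted DE transcripts (balanced clusters) have their AD
libraries scaled so the pooled AD/PD mean ratio is exactly 2^de_log2fc
before noise; members of the region-biased cluster get the fold change
multiplied on top of their template bias and are recorded as DE too, since
that keeps their two-level profile shape (and hence their cluster) intact.
Coding scores are planted cleanly on the noncoding side for every lncRNA
and decoy and on the coding side (with strong domain hits) for coding
fragments. Second-species homologs are mutated copies (4 % substitutions)
of designated candidate sequences on homologous chromosomes, plus controls:
a wrong-chromosome homolog, a matched homolog for a non-DE non-selected
lncRNA, and unrelated random targets.

The DE benchmark (`generate_de_benchmark`) is flat-profiled: 200
transcripts, log-normal baselines (ln-sd 0.8), 25 % DE at log2FC 2, CV 0.3
noise. With these conditions the q > 0.7 call reaches sensitivity ≈ 0.95–1.0
at a false-positive rate ≈ 0.05–0.11 depending on seed; the false positives
come from the known abundance-dependence of dominance counting (high-
abundance transcripts dominate much of the null cloud on D alone).

What the generator does **not** emulate: realistic nucleotide composition,
splice-isoform complexity, count-level sampling noise, between-replicate
library-size effects, or real conservation structure (scores are uniform
random per interval). Passing the planted-truth tests therefore shows the
predicates and statistics are implemented as specified — it does not
validate performance on real transcriptomes.

## Numerical choices and limitations

* Thresholds are strict inequalities exactly where stated above; each is a
  config field with the published value as default.
* Everything is deterministic given a seed: randomness flows from one
  `numpy` Generator per generator stage, no global state.
* Fixture sizes (3 × 500 kb, 64 isotigs, 200-transcript DE benchmark) keep
  a full pipeline run under a second while leaving every stage non-trivial.
* The paper-scale catalog numbers (thousands of transcripts, specific
  class splits) depend on the real sequencing data and external classifier
  outputs and are out of reach of a synthetic rebuild; the package
  guarantees the partition identities and recovery properties instead.
* Duplicate transcript ids across chromosomes are a hard error; the
  pipeline assumes globally unique ids.
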