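"""Discovery cascade: strand filter, annotation partition, merging,
length/expression filter, novelty labels, accounting and idempotence."""

import numpy as np
import pandas as pd
import pytest

from lncfeather import transcript_discovery as td
from lncfeather.io_formats import (
    ExpressionTable,
    LabeledInterval,
    TranscriptModel,
    ValidationError,
)

META = {"L1": ("AD", "E8"), "L2": ("PD", "E8")}


def tm(tid, exons, strand="+", chrom="chr1", biotype="unannotated"):
    return TranscriptModel(tid, tid, chrom, strand, tuple(exons), biotype)


def expr_for(models, values):
    df = pd.DataFrame(values, index=[m.transcript_id for m in models],
                      columns=list(META))
    return ExpressionTable(df, dict(META))


class TestStrandFilter:
    def test_unknown_strand_removed(self):
        kept, removed = td.filter_stranded([tm("a", [(0, 300)], strand=".")])
        assert kept == [] and len(removed) == 1

    def test_empty_input(self):
        assert td.filter_stranded([]) == ([], [])

    def test_counts(self):
        models = [tm(f"t{i}", [(i * 1000, i * 1000 + 100)],
                     strand="." if i < 2 else "+") for i in range(5)]
        kept, removed = td.filter_stranded(models)
        assert (len(kept), len(removed)) == (3, 2)


class TestAnnotationPartition:
    REF = [tm("ref", [(100, 200), (300, 400)], strand="+",
              biotype="protein_coding")]

    def test_antisense_isotig_is_unannotated(self):
        annotated, unannotated = td.partition_by_annotation(
            [tm("a", [(150, 450)], strand="-")], self.REF)
        assert annotated == [] and len(unannotated) == 1

    def test_single_base_same_strand_overlap_is_annotated(self):
        annotated, _ = td.partition_by_annotation(
            [tm("a", [(199, 500)], strand="+")], self.REF)
        assert len(annotated) == 1

    def test_intron_contained_same_strand_is_unannotated(self):
        _, unannotated = td.partition_by_annotation(
            [tm("a", [(210, 290)], strand="+")], self.REF)
        assert len(unannotated) == 1

    def test_reference_without_exons_rejected(self):
        with pytest.raises(ValidationError):
            td.partition_by_annotation([tm("a", [(0, 300)])], [])


class TestMerge:
    def test_disjoint_exons_not_merged(self):
        merged = td.merge_isotigs([tm("a", [(0, 100)]), tm("b", [(200, 300)])])
        assert len(merged) == 2

    def test_single_linkage_chain_merges_transitively(self):
        merged = td.merge_isotigs([
            tm("a", [(0, 100)]), tm("b", [(50, 200)]), tm("c", [(150, 260)])])
        assert len(merged) == 1
        assert set(merged[0].members) == {"a", "b", "c"}
        assert merged[0].exons == ((0, 260),)

    def test_opposite_strands_never_merge(self):
        merged = td.merge_isotigs([tm("a", [(0, 100)], "+"),
                                   tm("b", [(0, 100)], "-")])
        assert len(merged) == 2

    def test_interleaved_exons_without_shared_bases_stay_separate(self):
        merged = td.merge_isotigs([
            tm("a", [(0, 100), (500, 600)]), tm("b", [(200, 300), (700, 800)])])
        assert len(merged) == 2

    def test_matches_union_find_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            isotigs = []
            for i in range(n):
                start = int(rng.integers(0, 500))
                isotigs.append(tm(f"t{i}", [(start, start + int(rng.integers(20, 150)))],
                                  strand="+" if rng.integers(0, 2) else "-"))
            merged = td.merge_isotigs(isotigs)
            got = {frozenset(m.members) for m in merged}
            # oracle: naive O(n^2) union-find on pairwise exon-base overlap
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = isotigs[i], isotigs[j]
                    if a.strand != b.strand:
                        continue
                    if any(min(e1, e2) > max(s1, s2)
                           for s1, e1 in a.exons for s2, e2 in b.exons):
                        parent[find(i)] = find(j)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), set()).add(f"t{i}")
            assert got == {frozenset(g) for g in groups.values()}


class TestLengthExpressionFilter:
    def test_short_transcript_removed_despite_expression(self):
        models = [tm("a", [(0, 199)])]
        kept = td.filter_length_expression(models, expr_for(models, [[10.0, 10.0]]))
        assert kept == []

    def test_single_library_at_threshold_keeps(self):
        models = [tm("a", [(0, 200)])]
        kept = td.filter_length_expression(models, expr_for(models, [[0.9, 1.0]]))
        assert len(kept) == 1

    def test_silent_long_transcript_removed(self):
        models = [tm("a", [(0, 5000)])]
        kept = td.filter_length_expression(models, expr_for(models, [[0.0, 0.0]]))
        assert kept == []

    def test_missing_expression_is_an_error(self):
        models = [tm("a", [(0, 300)])]
        other = [tm("b", [(0, 300)])]
        with pytest.raises(KeyError):
            td.filter_length_expression(models, expr_for(other, [[1.0, 1.0]]))


class TestNovelty:
    def test_same_strand_catalog_overlap_is_known(self):
        catalog = [LabeledInterval("chr1", 0, 100, "NONC1", "+")]
        flags = td.label_novelty([tm("a", [(50, 300)], "+")], catalog)
        assert flags == {"a": "known"}

    def test_antisense_catalog_overlap_stays_novel(self):
        catalog = [LabeledInterval("chr1", 0, 100, "NONC1", "-")]
        flags = td.label_novelty([tm("a", [(50, 300)], "+")], catalog)
        assert flags == {"a": "novel"}

    def test_empty_catalog_all_novel(self):
        flags = td.label_novelty([tm("a", [(0, 300)])], [])
        assert set(flags.values()) == {"novel"}

    def test_partition_counts(self, rng):
        catalog = [LabeledInterval("chr1", i * 1000, i * 1000 + 100, f"N{i}", "+")
                   for i in range(3)]
        models = [tm(f"t{i}", [(i * 1000 + 50, i * 1000 + 400)], "+")
                  for i in range(10)]
        flags = td.label_novelty(models, catalog)
        assert sum(v == "known" for v in flags.values()) == 3
        assert sum(v == "novel" for v in flags.values()) == 7


class TestCascade:
    def test_accounting_identities_hold(self, discovery_result):
        _, _, report = discovery_result
        report.check()

    def test_idempotent_on_own_output(self, clean_fixture, discovery_result):
        fx = clean_fixture
        retained, expr, _ = discovery_result
        again, _, report2 = td.run_discovery(
            retained, fx.genome.annotation, expr, fx.genome.catalog)
        assert {m.transcript_id for m in again} == {m.transcript_id for m in retained}
        assert report2.removed_unstranded == 0
        assert report2.annotated == 0

    def test_noise_free_retained_equals_planted_lncrnas(
            self, clean_fixture, discovery_result):
        fx = clean_fixture
        retained, _, report = discovery_result
        assert {m.transcript_id for m in retained} == fx.truth.lncrna_ids()
        known = {t for t, v in report.novelty.items() if v == "known"}
        assert known == fx.truth.known
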