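"""Feature statistics: lengths, conservation, TE overlap, expression, JS."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncfeather import feature_stats as fs
from lncfeather.io_formats import (
    ConservationTrack,
    ExpressionTable,
    LabeledInterval,
    TranscriptModel,
    ValidationError,
)

META = {"E8A": ("AD", "E8"), "E9A": ("AD", "E9"), "E12A": ("AD", "E12"),
        "E8P": ("PD", "E8"), "E9P": ("PD", "E9"), "E12P": ("PD", "E12")}
REGION_PART = {"AD": [0, 1, 2], "PD": [3, 4, 5]}


def tm(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(tid, tid, chrom, strand, tuple(exons))


class TestLengthExon:
    def test_median_and_mean(self):
        group = [tm("a", [(0, 100)]), tm("b", [(0, 200)]), tm("c", [(0, 300)])]
        assert fs.length_exon_summary(group) == (200.0, 200.0, 1.0)

    def test_even_n_median_is_central_pair_mean(self):
        group = [tm("a", [(0, 100)]), tm("b", [(0, 400)])]
        med, mean, _ = fs.length_exon_summary(group)
        assert med == 250.0 and mean == 250.0

    def test_exon_count(self):
        (_, _, mean_ex) = fs.length_exon_summary([tm("a", [(0, 10), (20, 30)])])
        assert mean_ex == 2.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            fs.length_exon_summary([])


class TestConservation:
    def test_constant_track_mean_is_constant(self):
        track = ConservationTrack.from_intervals([("chr1", 0, 1000, 0.5)])
        assert fs.mean_conservation(tm("a", [(10, 60), (100, 200)]), track) == 0.5

    def test_unscored_bases_ignored(self):
        track = ConservationTrack.from_intervals(
            [("chr1", 0, 1, 0.2), ("chr1", 1, 2, 0.4)])
        got = fs.mean_conservation(tm("a", [(0, 12)]), track)
        assert got == pytest.approx(0.3)

    def test_fully_unscored_transcript_is_missing(self):
        track = ConservationTrack.from_intervals([("chr2", 0, 100, 0.9)])
        assert fs.mean_conservation(tm("a", [(0, 50)]), track) is None

    def test_matches_per_base_oracle_on_random_tracks(self, rng):
        for _ in range(100):
            scores = np.full(300, np.nan)
            rows = []
            pos = 0
            while pos < 280:
                length = int(rng.integers(5, 30))
                if rng.uniform() < 0.6:
                    v = round(float(rng.uniform(0, 1)), 3)
                    rows.append(("chr1", pos, pos + length, v))
                    scores[pos: pos + length] = v
                pos += length + int(rng.integers(0, 10))
            track = ConservationTrack.from_intervals(rows)
            s = int(rng.integers(0, 250))
            model = tm("a", [(s, s + int(rng.integers(5, 50)))])
            base = scores[model.exons[0][0]: model.exons[0][1]]
            expected = None if np.isnan(base).all() else float(np.nanmean(base))
            got = fs.mean_conservation(model, track)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)


class TestTeOverlap:
    def test_no_repeats_zero(self):
        assert fs.te_overlap_fraction([tm("a", [(0, 100)])], []) == 0.0

    def test_all_overlapping_one(self):
        reps = [LabeledInterval("chr1", 0, 1000, "LINE")]
        assert fs.te_overlap_fraction([tm("a", [(0, 100)]),
                                       tm("b", [(500, 700)])], reps) == 1.0

    def test_single_base_overlap_counts(self):
        reps = [LabeledInterval("chr1", 99, 100, "SINE")]
        models = [tm(f"t{i}", [(i * 1000, i * 1000 + 100)]) for i in range(5)]
        reps.append(LabeledInterval("chr1", 1099, 1100, "DNA"))
        assert fs.te_overlap_fraction(models, reps) == pytest.approx(0.4)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(100):
            reps = []
            mask = np.zeros(2000, dtype=bool)
            for _r in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, 1900))
                e = s + int(rng.integers(1, 100))
                reps.append(LabeledInterval("chr1", s, e, "SINE"))
                mask[s:e] = True
            models = []
            expected_hits = 0
            for i in range(int(rng.integers(1, 8))):
                s = int(rng.integers(0, 1900))
                e = s + int(rng.integers(1, 100))
                models.append(tm(f"t{i}", [(s, e)]))
                expected_hits += bool(mask[s:e].any())
            got = fs.te_overlap_fraction(models, reps)
            assert got == pytest.approx(expected_hits / len(models))


class TestExpressionSummary:
    def _expr(self, rows, ids):
        return ExpressionTable(
            pd.DataFrame(rows, index=ids, columns=list(META)), dict(META))

    def test_max_statistic(self):
        expr = self._expr([[0, 0, 0, 0, 0, 2]], ["a"])
        assert fs.expression_summary(["a"], expr) == (2.0, 2.0)

    def test_median_mean_over_group(self):
        expr = self._expr([[1, 0, 0, 0, 0, 0], [3, 0, 0, 0, 0, 0]], ["a", "b"])
        assert fs.expression_summary(["a", "b"], expr) == (2.0, 2.0)

    def test_missing_transcript_rejected(self):
        expr = self._expr([[1, 1, 1, 1, 1, 1]], ["a"])
        with pytest.raises(KeyError):
            fs.expression_summary(["zz"], expr)


class TestJsSpecificity:
    def test_confined_to_one_condition_scores_one(self):
        assert fs.js_specificity([2, 3, 1, 0, 0, 0], REGION_PART) == pytest.approx(1.0)

    def test_uniform_two_condition_closed_form(self):
        expected = 1.0 - math.sqrt(0.31127812445913283)
        got = fs.js_specificity([1, 1, 1, 1, 1, 1], REGION_PART)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_condition_permutation_invariance(self):
        a = fs.js_specificity([5, 5, 5, 1, 1, 1], REGION_PART)
        b = fs.js_specificity([1, 1, 1, 5, 5, 5], REGION_PART)
        assert a == pytest.approx(b)

    def test_all_zero_vector_is_missing(self):
        assert fs.js_specificity([0, 0, 0, 0, 0, 0], REGION_PART) is None

    def test_negative_expression_rejected(self):
        with pytest.raises(ValidationError):
            fs.js_specificity([-1, 0, 0, 0, 0, 0], REGION_PART)

    @given(st.lists(st.floats(0, 1e4), min_size=6, max_size=6))
    def test_score_bounded_in_unit_interval(self, vec):
        got = fs.js_specificity(vec, REGION_PART)
        if got is not None:
            assert -1e-12 <= got <= 1 + 1e-12

    def test_concentration_monotonicity(self):
        scores = []
        for w in (1.0, 2.0, 5.0, 20.0):
            scores.append(fs.js_specificity([w, w, w, 1, 1, 1], REGION_PART))
        assert scores == sorted(scores)

    def test_matches_direct_entropy_oracle(self, rng):
        def h(p):
            p = p[p > 0]
            return float(-(p * np.log2(p)).sum())

        for _ in range(100):
            vec = rng.uniform(0, 10, size=6)
            means = np.array([vec[:3].mean(), vec[3:].mean()])
            p = means / means.sum()
            best = -np.inf
            for e in (np.array([1.0, 0.0]), np.array([0.0, 1.0])):
                m = 0.5 * (p + e)
                jsd = h(m) - 0.5 * (h(p) + h(e))
                best = max(best, 1 - math.sqrt(max(jsd, 0)))
            assert fs.js_specificity(vec, REGION_PART) == pytest.approx(best)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        assert fs.group_compare([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_separation_tiny_p(self):
        assert fs.group_compare([0, 0, 0, 0], [1, 1, 1, 1]) < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            fs.group_compare([1], [1, 2])

    def test_matches_textbook_student_t(self, rng):
        from scipy.stats import t as tdist

        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(3, 10)))
            b = rng.normal(0.5, 1, size=int(rng.integers(3, 10)))
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            tval = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * tdist.sf(abs(tval), na + nb - 2)
            assert fs.group_compare(a, b) == pytest.approx(p)
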