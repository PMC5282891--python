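"""Enrichment (Fisher/BH), cross-species similarity, candidate selection."""

import math

import numpy as np
import pytest

from lncfeather import enrichment_candidates as ec
from lncfeather.io_formats import ValidationError


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for i in range(k, min(n, K) + 1):
        total += (math.comb(K, i) * math.comb(N - K, n - i)) / math.comb(N, n)
    return total


def bh_oracle(pvals):
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * n / (rank + 1))
        adj[i] = running
    return adj


class TestFisher:
    def test_term_covering_background_has_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        terms = {g: {"T"} for g in bg}
        res = ec.fisher_enrichment(bg[:5], bg, terms)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_exact_tail_example(self):
        bg = [f"g{i}" for i in range(100)]
        terms = {g: {"T"} for g in bg[:10]}
        cluster = bg[:5] + bg[50:55]  # k = 5, n = 10, K = 10, N = 100
        res = ec.fisher_enrichment(cluster, bg, terms)
        row = res[res["term"] == "T"].iloc[0]
        assert (row["k"], row["n"], row["K"], row["N"]) == (5, 10, 10, 100)
        assert row["p"] == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10))

    def test_random_tables_match_tail_sum(self, rng):
        for _ in range(100):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            bg = [f"g{i}" for i in range(N)]
            carriers = set(rng.choice(bg, size=K, replace=False))
            cluster = list(rng.choice(bg, size=n, replace=False))
            k = len(carriers & set(cluster))
            if k == 0:
                continue
            terms = {g: {"T"} for g in carriers}
            res = ec.fisher_enrichment(cluster, bg, terms)
            row = res[res["term"] == "T"].iloc[0]
            assert row["p"] == pytest.approx(hypergeom_tail_oracle(k, N, K, n))

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            ec.fisher_enrichment(["x"], ["a", "b"], {})

    def test_significance_conjunction(self):
        bg = [f"g{i}" for i in range(200)]
        terms = {g: {"STRONG"} for g in bg[:10]}
        res = ec.fisher_enrichment(bg[:10], bg, terms)
        row = res.iloc[0]
        assert row["p"] < 0.01 and row["fdr"] < 0.05 and bool(row["significant"])


class TestBenjaminiHochberg:
    def test_library_adjustment_matches_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 20)))
            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, bh_oracle(list(p)))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, size=15)
        adj = bh_oracle(list(p))
        assert all(a >= r - 1e-15 for a, r in zip(adj, p))


def similarity_oracle(q, t, k=11, min_length=50, min_identity=0.8):
    """Brute force over every diagonal and every fixed-length window."""
    need = math.ceil(min_identity * min_length)
    for diag in range(-(len(t) - 1), len(q)):
        lo = max(0, diag)
        hi = min(len(q), len(t) + diag)
        if hi - lo < min_length:
            continue
        match = [q[x] == t[x - diag] for x in range(lo, hi)]
        for w0 in range(0, len(match) - min_length + 1):
            window = match[w0: w0 + min_length]
            if sum(window) < need:
                continue
            run = 0
            for m in window:
                run = run + 1 if m else 0
                if run >= k:
                    return True
        # windows checked
    return False


class TestCrossSpecies:
    def test_identical_sequences_full_length_hit(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        hits = ec.cross_species_hits(
            {"q": seq}, {"q": "chr1"}, {"t": seq}, {"t": "chr1"})
        (h,) = hits
        assert h.identity == 1.0 and h.length == 200 and h.chrom_match

    def test_reverse_complement_found_on_minus(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        hits = ec.cross_species_hits(
            {"q": seq}, {"q": "chr1"},
            {"t": ec.reverse_complement(seq)}, {"t": "chr1"})
        (h,) = hits
        assert h.strand == "-"

    def test_both_strands_off_misses_reverse(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        hits = ec.cross_species_hits(
            {"q": seq}, {"q": "chr1"},
            {"t": ec.reverse_complement(seq)}, {"t": "chr1"},
            both_strands=False)
        assert hits == []

    def test_homology_map_controls_chrom_match(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        hits = ec.cross_species_hits(
            {"q": seq}, {"q": "chr1"}, {"t": seq}, {"t": "gchr1"},
            homology_map={"chr1": "gchr1"})
        assert hits[0].chrom_match
        hits = ec.cross_species_hits(
            {"q": seq}, {"q": "chr1"}, {"t": seq}, {"t": "gchr2"},
            homology_map={"chr1": "gchr1"})
        assert not hits[0].chrom_match

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValidationError):
            ec.cross_species_hits({"q": "ACGU" * 30}, {}, {"t": "ACGT" * 30}, {})

    def test_detection_matches_exhaustive_oracle(self, rng):
        bases = list("ACGT")
        n_checked = 0
        for _ in range(100):
            q = "".join(rng.choice(bases, size=int(rng.integers(60, 120))))
            if rng.uniform() < 0.5:
                # derive the target from the query so hits actually occur
                t = list(q[int(rng.integers(0, 10)):])
                for i in range(len(t)):
                    if rng.uniform() < float(rng.choice([0.02, 0.1, 0.3])):
                        t[i] = bases[int(rng.integers(0, 4))]
                t = "".join(t)
            else:
                t = "".join(rng.choice(bases, size=int(rng.integers(60, 120))))
            got = bool(ec.cross_species_hits(
                {"q": q}, {"q": "c"}, {"t": t}, {"t": "c"}, both_strands=False))
            expected = similarity_oracle(q, t)
            assert got == expected
            n_checked += 1
        assert n_checked == 100


class TestSelectCandidates:
    HITS = [
        ec.SimilarityHit("a", "t1", 100, 0.95, "+", True),
        ec.SimilarityHit("c", "t2", 80, 0.9, "+", True),
        ec.SimilarityHit("d", "t3", 80, 0.9, "+", False),
    ]
    CLUSTERS = {"a": "F", "b": "F", "c": "B", "d": "F"}

    def test_conjunction_of_three_criteria(self):
        rep = ec.select_candidates(
            ["a", "b", "c", "d"], self.CLUSTERS, ["F"], ["a", "b", "d"], self.HITS)
        assert bool(rep.loc["a", "candidate"])
        # b: no hit; c: wrong cluster and not DE; d: hit without chrom match
        assert not rep.loc["b", "candidate"]
        assert not rep.loc["c", "candidate"]
        assert not rep.loc["d", "candidate"]
        assert bool(rep.loc["d", "has_hit"]) and not bool(rep.loc["d", "chrom_matched_hit"])

    def test_empty_selected_clusters_yield_none(self):
        rep = ec.select_candidates(["a"], self.CLUSTERS, [], ["a"], self.HITS)
        assert not rep["candidate"].any()

    def test_missing_cluster_assignment_rejected(self):
        with pytest.raises(ValidationError):
            ec.select_candidates(["zz"], self.CLUSTERS, ["F"], [], [])

    def test_set_algebra_oracle(self, rng):
        ids = [f"x{i}" for i in range(40)]
        for _ in range(50):
            clusters = {t: rng.choice(["F", "G", "H"]) for t in ids}
            de = set(rng.choice(ids, size=15, replace=False))
            hit_ids = set(rng.choice(ids, size=10, replace=False))
            hits = [ec.SimilarityHit(t, "t", 60, 0.9, "+", bool(rng.integers(0, 2)))
                    for t in hit_ids]
            rep = ec.select_candidates(ids, clusters, ["F", "G"], de, hits)
            matched = {h.query_id for h in hits if h.chrom_match}
            expected = {t for t in ids
                        if clusters[t] in {"F", "G"} and t in de and t in matched}
            assert set(rep.index[rep["candidate"]]) == expected
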