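import itertools

import numpy as np
import pytest

from glyzip.core import ProteinRecord
from glyzip.redundancy import (
    RedundancyReason,
    dedupe,
    mark_redundant,
    pairwise_identity,
    redundancy_table,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_identity_4col(a: str, b: str) -> float:
    """Exhaustive oracle for length-4 vs length-<=4 alignments: enumerate all
    monotone gap placements and take the best score under match +1,
    mismatch 0, gap -1; identity = matches / columns of the best-scoring
    alignment (ties resolved toward max identity)."""
    best = None
    la, lb = len(a), len(b)
    ncols = la + lb  # upper bound
    for cols in range(max(la, lb), ncols + 1):
        for a_pos in itertools.combinations(range(cols), la):
            for b_pos in itertools.combinations(range(cols), lb):
                matches = mismatches = 0
                used = {}
                for i, c in enumerate(a_pos):
                    used[c] = a[i]
                pair_cols = 0
                for j, c in enumerate(b_pos):
                    if c in used:
                        pair_cols += 1
                        if used[c] == b[j]:
                            matches += 1
                        else:
                            mismatches += 1
                gaps = cols - pair_cols
                if pair_cols + gaps != cols:
                    continue
                score = matches - gaps
                ident = 100.0 * matches / cols
                key = (score, ident)
                if best is None or key > best:
                    best = key
    return best[1]


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKTAYI", "MKTAYI") == 100.0

    def test_three_of_four(self):
        assert pairwise_identity("AAAA", "AAAT") == 75.0

    def test_length_mismatch(self):
        # best alignment has 2 matches over 4 columns
        assert pairwise_identity("AAAA", "AA") == 50.0

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 12)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 12)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AAAA")

    def test_small_cases_match_enumeration_oracle(self):
        cases = ["AAAA", "AAAT", "ACGT", "AA", "TTTT", "ACAC"]
        for a in cases:
            for b in cases:
                got = pairwise_identity(a, b)
                want = oracle_identity_4col(a, b)
                assert got == pytest.approx(want), (a, b)


def _recs(*specs):
    return [ProteinRecord(uid, seq, organism=org) for uid, seq, org in specs]


class TestMarkRedundant:
    def test_identical_same_organism(self):
        recs = _recs(("A1", "MKTAYIAKQR", "org"), ("A2", "MKTAYIAKQR", "org"))
        rep = mark_redundant(recs)
        assert len(rep.clusters) == 1
        assert rep.clusters[0].reason is RedundancyReason.IDENTICAL
        assert rep.clusters[0].representative == "A1"
        assert rep.n_kept == 1 and rep.n_removed == 1

    def test_identical_different_organisms_kept(self):
        recs = _recs(("A1", "MKTAYIAKQR", "org_x"), ("A2", "MKTAYIAKQR", "org_y"))
        rep = mark_redundant(recs)
        assert rep.clusters == [] and rep.n_kept == 2

    def test_same_uniprot_id(self):
        recs = _recs(("A1", "MKTAYIAKQR", "org"), ("A1", "MKTAYIAKQC", "org"))
        rep = mark_redundant(recs)
        assert len(rep.clusters) == 1
        assert rep.clusters[0].reason is RedundancyReason.SAME_UNIPROT

    def test_planted_variant_cluster_single_linkage(self, rng):
        base = "".join(rng.choice(list(AA), size=120))
        variants = []
        for v in range(3):
            seq = list(base)
            for p in rng.choice(120, size=3, replace=False):
                seq[p] = "W" if seq[p] != "W" else "Y"
            variants.append("".join(seq))
        recs = _recs(
            ("B1", base, "org"),
            ("B2", variants[0], "org"),
            ("B3", variants[1], "org"),
            ("B4", variants[2], "org"),
        )
        # oracle: all-pairs identity matrix + connected components at >= 95
        ids = [r.uniprot_id for r in recs]
        seqs = {r.uniprot_id: r.sequence for r in recs}
        adj = {i: set() for i in ids}
        for x, y in itertools.combinations(ids, 2):
            if pairwise_identity(seqs[x], seqs[y]) >= 95:
                adj[x].add(y)
                adj[y].add(x)
        seen, comps = set(), []
        for i in ids:
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                j = stack.pop()
                if j in comp:
                    continue
                comp.add(j)
                stack.extend(adj[j])
            seen |= comp
            if len(comp) > 1:
                comps.append(comp)
        rep = mark_redundant(recs)
        assert {frozenset(c.members) for c in rep.clusters} == {
            frozenset(c) for c in comps
        }
        assert rep.n_kept == len(recs) - sum(len(c) - 1 for c in comps)

    def test_conservation_invariant(self, rng):
        recs = [
            ProteinRecord(
                f"R{i}",
                "".join(rng.choice(list(AA), size=40)),
                organism=f"org_{i % 3}",
            )
            for i in range(20)
        ]
        recs.append(ProteinRecord("R99", recs[0].sequence, organism="org_0"))
        rep = mark_redundant(recs)
        assert rep.n_input == rep.n_kept + rep.n_removed == len(recs)

    def test_group_size_guard(self):
        recs = _recs(("A1", "MKTA", "org"), ("A2", "MKTC", "org"))
        with pytest.raises(ValueError, match="max_group_size"):
            mark_redundant(recs, max_group_size=1)

    def test_threshold_monotonicity(self, rng):
        base = "".join(rng.choice(list(AA), size=60))
        recs = []
        for i in range(6):
            seq = list(base)
            for p in rng.choice(60, size=i * 2, replace=False):
                seq[p] = "W" if seq[p] != "W" else "Y"
            recs.append(ProteinRecord(f"T{i}", "".join(seq), organism="org"))
        kept = []
        for thr in (99, 95, 90, 80, 50):
            rep = mark_redundant(recs, identity_threshold=thr)
            kept.append(rep.n_kept)
        assert kept == sorted(kept, reverse=True)


class TestDedupe:
    def test_arithmetic_from_report(self, rng):
        recs = [
            ProteinRecord(f"D{i}", "".join(rng.choice(list(AA), size=30)), organism="o")
            for i in range(6)
        ]
        recs += [
            ProteinRecord("D90", recs[0].sequence, organism="o"),
            ProteinRecord("D91", recs[1].sequence, organism="o"),
            ProteinRecord("D92", recs[2].sequence, organism="o"),
            ProteinRecord("D93", recs[3].sequence, organism="o"),
        ]
        rep = mark_redundant(recs)
        kept = dedupe(recs, rep)
        assert len(recs) == 10 and len(rep.clusters) == 4
        assert len(kept) == 6

    def test_noop_without_clusters(self, toy_records):
        rep = mark_redundant(toy_records)
        assert dedupe(toy_records, rep) == toy_records

    def test_total_collapse(self):
        recs = _recs(*((f"C{i}", "MKTAYIAKQR", "org") for i in range(5)))
        rep = mark_redundant(recs)
        kept = dedupe(recs, rep)
        assert len(kept) == 1 and kept[0].uniprot_id == "C0"

    def test_idempotent(self, rng):
        recs = [
            ProteinRecord(f"I{i}", "".join(rng.choice(list(AA), size=25)), organism="o")
            for i in range(8)
        ]
        recs.append(ProteinRecord("I50", recs[0].sequence, organism="o"))
        once = dedupe(recs, mark_redundant(recs))
        twice = dedupe(once, mark_redundant(once))
        assert twice == once

    def test_mismatched_report(self, toy_records):
        rep = mark_redundant(toy_records)
        with pytest.raises(ValueError, match="mismatch"):
            dedupe(toy_records[:2], rep)

    def test_annotated_table_flags(self):
        recs = _recs(("A1", "MKTAYIAKQR", "org"), ("A2", "MKTAYIAKQR", "org"))
        rep = mark_redundant(recs)
        table = redundancy_table(recs, rep)
        assert list(table["redundant"]) == [False, True]
        assert list(table["representative_flag"]) == [True, False]
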