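"""RBH families, dating, conservation categories and share arithmetic."""

import numpy as np
import pytest

from lncevo.formats import AlignmentHit
from lncevo.orthology import (
    OrthologFamily,
    OrthologPair,
    age_class_summary,
    assign_branch_point,
    best_hits,
    categorize_focal,
    conserved_fraction_per_species,
    count_families_per_branch,
    date_families,
    reciprocal_best_hits,
    round_half_up,
    single_linkage_families,
)


def hit(q, s, evalue=1e-20, bitscore=100.0):
    return AlignmentHit(
        query_id=q, subject_id=s, pct_identity=90.0, aln_length=100,
        mismatches=10, gap_opens=0, q_start=0, q_end=100, s_start=0, s_end=100,
        strand="+", evalue=evalue, bitscore=bitscore,
    )


SPECIES = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "c1": "C"}


class TestBestHits:
    def test_min_evalue_wins(self):
        best = best_hits([hit("a1", "b1", 1e-20), hit("a1", "b2", 1e-8)], SPECIES)
        assert best[(("A", "a1"), "B")] == ("B", "b1")

    def test_threshold_discards(self):
        assert best_hits([hit("a1", "b1", 1e-4)], SPECIES) == {}

    def test_tie_broken_by_bitscore_then_id(self):
        best = best_hits(
            [hit("a1", "b2", 1e-20, 150.0), hit("a1", "b1", 1e-20, 180.0)], SPECIES
        )
        assert best[(("A", "a1"), "B")] == ("B", "b1")
        best = best_hits(
            [hit("a1", "b2", 1e-20, 150.0), hit("a1", "b1", 1e-20, 150.0)], SPECIES
        )
        assert best[(("A", "a1"), "B")] == ("B", "b1")  # lexicographic

    def test_within_species_hits_ignored(self):
        assert best_hits([hit("a1", "a2")], SPECIES) == {}


class TestReciprocalBestHits:
    def test_mutual_bests_pair(self):
        best = best_hits([hit("a1", "b2"), hit("b2", "a1")], SPECIES)
        (pair,) = reciprocal_best_hits(best)
        assert {pair.gene_a, pair.gene_b} == {("A", "a1"), ("B", "b2")}

    def test_one_directional_best_is_not_a_pair(self):
        best = best_hits(
            [hit("a1", "b2"), hit("b2", "a3", 1e-30), hit("b2", "a1", 1e-10)],
            SPECIES,
        )
        assert reciprocal_best_hits(best) == []

    def test_three_species_triangle(self):
        hits = []
        for x, y in [("a1", "b1"), ("b1", "c1"), ("a1", "c1")]:
            hits += [hit(x, y), hit(y, x)]
        pairs = reciprocal_best_hits(best_hits(hits, SPECIES))
        assert len(pairs) == 3

    def test_symmetric_under_input_order(self):
        hits = [hit("a1", "b1"), hit("b1", "a1"), hit("a1", "c1"), hit("c1", "a1")]
        p1 = reciprocal_best_hits(best_hits(hits, SPECIES))
        p2 = reciprocal_best_hits(best_hits(hits[::-1], SPECIES))
        assert p1 == p2


class TestSingleLinkage:
    def test_transitive_linkage(self):
        pairs = [
            OrthologPair(("A", "a"), ("B", "b")),
            OrthologPair(("B", "b"), ("C", "c")),
        ]
        (fam,) = single_linkage_families(pairs)
        assert fam.members == frozenset({("A", "a"), ("B", "b"), ("C", "c")})

    def test_disjoint_pairs_make_two_families(self):
        pairs = [
            OrthologPair(("A", "a"), ("B", "b")),
            OrthologPair(("C", "c"), ("D", "d")),
        ]
        assert len(single_linkage_families(pairs)) == 2

    def test_matches_union_find_oracle(self):
        """Random pair graphs over <= 25 genes equal brute-force union-find."""
        rng = np.random.default_rng(3)
        species = [f"S{i}" for i in range(5)]
        for _ in range(25):
            genes = [
                (species[int(rng.integers(0, 5))], f"g{i}")
                for i in range(int(rng.integers(4, 26)))
            ]
            pairs = []
            for _ in range(int(rng.integers(1, 31))):
                i, j = rng.integers(0, len(genes), size=2)
                if genes[int(i)][0] != genes[int(j)][0]:
                    pairs.append(OrthologPair(genes[int(i)], genes[int(j)]))
            if not pairs:
                continue
            # independent union-find oracle
            parent = {}

            def find(x):
                parent.setdefault(x, x)
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for p in pairs:
                ra, rb = find(p.gene_a), find(p.gene_b)
                if ra != rb:
                    parent[ra] = rb
            oracle = {}
            for p in pairs:
                for g in (p.gene_a, p.gene_b):
                    oracle.setdefault(find(g), set()).add(g)
            expected = {frozenset(v) for v in oracle.values()}
            got = {f.members for f in single_linkage_families(pairs)}
            assert got == expected


class TestBranchPoints:
    def test_mrca_of_sister_pair(self, toy_tree):
        fam = OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")}))
        leafset, age = assign_branch_point(fam, toy_tree)
        assert leafset == ("A", "B")
        assert age == pytest.approx(10.0)

    def test_mrca_spanning_root(self, toy_tree):
        fam = OrthologFamily("F1", frozenset({("A", "x"), ("C", "z")}))
        leafset, age = assign_branch_point(fam, toy_tree)
        assert leafset == ("A", "B", "C")
        assert age == pytest.approx(100.0)

    def test_missing_species_named_in_error(self, toy_tree):
        fam = OrthologFamily("F1", frozenset({("A", "x"), ("X", "z")}))
        with pytest.raises(KeyError, match="X"):
            assign_branch_point(fam, toy_tree)

    def test_adding_species_never_decreases_age(self, toy_tree):
        small = OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")}))
        big = OrthologFamily("F2", frozenset({("A", "x"), ("B", "y"), ("C", "z")}))
        _, age_small = assign_branch_point(small, toy_tree)
        _, age_big = assign_branch_point(big, toy_tree)
        assert age_big >= age_small

    def test_per_branch_counts_recover_planting(self, toy_tree):
        fams = [
            OrthologFamily(f"F{i}", frozenset({("A", f"x{i}"), ("B", f"y{i}")}))
            for i in range(3)
        ] + [
            OrthologFamily("F9", frozenset({("A", "x9"), ("C", "z9")})),
        ]
        date_families(fams, toy_tree)
        counts = count_families_per_branch(fams, toy_tree)
        assert counts == {("A", "B"): 3, ("A", "B", "C"): 1}
        assert sum(counts.values()) == len(fams)


class TestAgeClassSummary:
    def test_cumulative_counts_and_shares(self, toy_tree):
        fams = [
            OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")})),  # age 10
            OrthologFamily("F2", frozenset({("A", "p"), ("C", "q"), ("B", "r")})),  # 100
        ]
        date_families(fams, toy_tree)
        df = age_class_summary(fams, thresholds=[50])
        row = df.iloc[0]
        assert row.n_families == 1 and row.n_lncRNAs == 3
        assert row.family_share_pct == 50.0
        assert row.lncRNA_share_pct == 60.0

    def test_all_young_families_give_zero_rows(self, toy_tree):
        fams = [OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")}))]
        date_families(fams, toy_tree)
        df = age_class_summary(fams, thresholds=[50, 100])
        assert (df.n_families == 0).all() and (df.family_share_pct == 0).all()

    def test_single_old_family_is_total(self, toy_tree):
        fams = [OrthologFamily("F1", frozenset({("A", "x"), ("C", "y")}))]
        date_families(fams, toy_tree)
        df = age_class_summary(fams, thresholds=[50])
        assert df.iloc[0].family_share_pct == 100.0


class TestCategorizeFocal:
    CATS = [
        ("AD", {"A", "B"}),
        ("BC", {"A", "B", "C"}),
    ]

    def test_smallest_containing_clade_wins(self, toy_tree):
        fam = OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")}))
        labels = categorize_focal([fam], toy_tree, self.CATS, "A", ["x", "z"])
        assert labels == {"x": "AD", "z": "non_conserved"}

    def test_root_family_gets_deepest_label(self, toy_tree):
        fam = OrthologFamily("F1", frozenset({("A", "x"), ("C", "y")}))
        labels = categorize_focal([fam], toy_tree, self.CATS, "A", ["x"])
        assert labels == {"x": "BC"}

    def test_non_nested_config_rejected(self, toy_tree):
        bad = [("AD", {"A", "B"}), ("XX", {"A", "C"})]
        with pytest.raises(ValueError, match="nested"):
            categorize_focal([], toy_tree, bad, "A", [])

    def test_monotone_in_mrca_depth(self, toy_tree):
        """A family with an ancestral MRCA never gets a shallower label."""
        shallow = OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")}))
        deep = OrthologFamily("F2", frozenset({("A", "p"), ("C", "q")}))
        labels = categorize_focal(
            [shallow, deep], toy_tree, self.CATS, "A", ["x", "p"]
        )
        order = {"AD": 0, "BC": 1}
        assert order[labels["p"]] >= order[labels["x"]]


class TestConservedFraction:
    def test_fraction_arithmetic(self):
        fams = [OrthologFamily("F1", frozenset({("A", "x"), ("B", "y")}))]
        out = conserved_fraction_per_species(fams, {"A": 4, "B": 3})
        assert out == {"A": 25.0, "B": round_half_up(100 / 3, 2)}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            conserved_fraction_per_species([], {"A": 0})

    @pytest.mark.parametrize(
        "num,den,nd,expected",
        [(25.486, 1, 2, 25.49), (6.789, 1, 2, 6.79), (84.437, 1, 1, 84.4),
         (6.8548, 1, 2, 6.85), (2.675, 1, 2, 2.68)],
    )
    def test_half_up_rounding(self, num, den, nd, expected):
        assert round_half_up(num / den, nd) == expected
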