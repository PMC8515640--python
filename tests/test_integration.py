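"""Catalogue building: filtering, hit clustering, scoring, merging."""

import numpy as np
import pytest

from lncevo.formats import AlignmentHit, TranscriptRecord
from lncevo.integration import (
    HitCluster,
    PlacedLocus,
    cluster_hits,
    filter_transcripts,
    merge_redundant,
    score_cluster,
    select_optimal_clusters,
)


def make_hit(
    qs, qe, ss, se, tid="t1", chrom="chr1", pident=95.0, evalue=1e-30, strand="+"
):
    return AlignmentHit(
        query_id=tid,
        subject_id=chrom,
        pct_identity=pident,
        aln_length=qe - qs,
        mismatches=0,
        gap_opens=0,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        strand=strand,
        evalue=evalue,
        bitscore=2.0 * (qe - qs),
    )


def make_locus(start, end, tid="t", chrom="chr1", strand="+", exons=None):
    return PlacedLocus(
        transcript_id=tid, chrom=chrom, strand=strand,
        exons=exons or [(start, end)],
    )


class TestFilterTranscripts:
    @pytest.mark.parametrize(
        "length,coding,kept",
        [
            (200, None, False),  # strict > 200 nt
            (201, False, True),
            (500, True, False),
            (500, None, True),  # missing verdict passes through
        ],
    )
    def test_length_and_coding_rules(self, length, coding, kept):
        rec = TranscriptRecord("t", "sp", "A" * length, coding_flag=coding)
        assert (rec in filter_transcripts([rec])) is kept


class TestClusterHits:
    def test_gap_at_most_4000_joins(self):
        hits = [make_hit(0, 500, 0, 500), make_hit(500, 1100, 4400, 5000)]
        assert len(cluster_hits(hits)) == 1  # gap 3900

    def test_gap_over_4000_splits(self):
        hits = [make_hit(0, 500, 0, 500), make_hit(500, 900, 4600, 5000)]
        assert len(cluster_hits(hits)) == 2  # gap 4100

    def test_chromosomes_never_mix(self):
        hits = [make_hit(0, 100, 0, 100, chrom="chr1"),
                make_hit(0, 100, 0, 100, chrom="chr2")]
        clusters = cluster_hits(hits)
        assert len(clusters) == 2
        assert {c.chrom for c in clusters} == {"chr1", "chr2"}

    def test_strands_never_mix(self):
        hits = [make_hit(0, 100, 0, 100), make_hit(0, 100, 50, 150, strand="-")]
        assert len(cluster_hits(hits)) == 2

    def test_matches_brute_force_components(self):
        """For small hit sets, clustering equals connected components under
        the relation "same chrom/strand and gap <= max_gap in sort order"."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(1, 21))
            hits = []
            for _ in range(n):
                s = int(rng.integers(0, 30000))
                e = s + int(rng.integers(50, 2000))
                chrom = f"chr{rng.integers(1, 3)}"
                strand = "+" if rng.random() < 0.7 else "-"
                hits.append(make_hit(0, e - s, s, e, chrom=chrom, strand=strand))
            clusters = cluster_hits(hits, max_gap=4000)
            # oracle: sweep each (chrom, strand) group independently
            expected = 0
            for key in {(h.subject_id, h.strand) for h in hits}:
                grp = sorted(
                    [h for h in hits if (h.subject_id, h.strand) == key],
                    key=lambda h: (h.s_start, h.s_end),
                )
                comps, reach = 1, grp[0].s_end
                for h in grp[1:]:
                    if h.s_start - reach > 4000:
                        comps += 1
                        reach = h.s_end
                    else:
                        reach = max(reach, h.s_end)
                expected += comps
            assert len(clusters) == expected
            assert sum(len(c.members) for c in clusters) == n

    def test_mixed_transcripts_rejected(self):
        hits = [make_hit(0, 100, 0, 100, tid="a"), make_hit(0, 100, 0, 100, tid="b")]
        with pytest.raises(ValueError, match="one transcript"):
            cluster_hits(hits)


class TestScoreCluster:
    def test_overlapping_fragments_counted_once(self):
        hits = [make_hit(0, 400, 0, 400), make_hit(300, 700, 1000, 1400)]
        c = HitCluster("t1", "chr1", "+", hits)
        cov, _ = score_cluster(c, 1000)
        assert cov == pytest.approx(0.70)

    def test_weighted_identity_is_length_weighted(self):
        hits = [
            make_hit(0, 100, 0, 100, pident=90.0),
            make_hit(100, 400, 100, 400, pident=80.0),
        ]
        c = HitCluster("t1", "chr1", "+", hits)
        _, wid = score_cluster(c, 400)
        assert wid == pytest.approx(82.5)

    def test_full_length_perfect_hit(self):
        c = HitCluster("t1", "chr1", "+", [make_hit(0, 500, 0, 500, pident=95.0)])
        assert score_cluster(c, 500) == (pytest.approx(1.0), pytest.approx(95.0))

    def test_coverage_capped_at_one(self):
        hits = [make_hit(0, 400, 0, 400), make_hit(100, 400, 500, 800)]
        c = HitCluster("t1", "chr1", "+", hits)
        cov, _ = score_cluster(c, 400)
        assert cov <= 1.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_cluster(HitCluster("t1", "chr1", "+", []), 100)


def scored_cluster(cov, wid, tid="t1", chrom="chr1", ss=0, se=1000):
    c = HitCluster(tid, chrom, "+", [make_hit(0, se - ss, ss, se)])
    c.effective_coverage = cov
    c.weighted_identity = wid
    return c


class TestSelectOptimal:
    def test_identity_takes_precedence_over_coverage(self):
        a = scored_cluster(0.75, 85.0)
        b = scored_cluster(0.90, 82.0, chrom="chr2")
        (locus,) = select_optimal_clusters([a, b])
        assert locus.chrom == "chr1"

    def test_thresholds_are_strict(self):
        assert select_optimal_clusters([scored_cluster(0.70, 90.0)]) == []
        assert select_optimal_clusters([scored_cluster(0.90, 80.0)]) == []

    def test_tied_optima_become_paralogs(self):
        a = scored_cluster(0.90, 85.0, ss=0, se=1000)
        b = scored_cluster(0.90, 85.0, chrom="chr2", ss=5000, se=6000)
        loci = select_optimal_clusters([a, b])
        assert len(loci) == 2
        assert all(l.is_paralog_copy for l in loci)

    def test_single_winner_not_flagged_paralog(self):
        (locus,) = select_optimal_clusters([scored_cluster(0.9, 90.0)])
        assert not locus.is_paralog_copy


class TestMergeRedundant:
    def test_high_overlap_merges(self):
        a = make_locus(100, 1001, tid="a")
        b = make_locus(150, 1051, tid="b")
        merged = merge_redundant([a, b])  # overlap 851 of shorter 901 = 94.5%
        assert len(merged) == 1
        assert merged[0].member_transcript_ids == frozenset({"a", "b"})

    def test_low_overlap_does_not_merge(self):
        a = make_locus(100, 1001, tid="a")
        b = make_locus(500, 1401, tid="b")  # overlap 501 = 55.6%
        assert len(merge_redundant([a, b])) == 2

    def test_exons_are_union(self):
        a = make_locus(0, 0, tid="a", exons=[(0, 100), (200, 300)])
        b = make_locus(0, 0, tid="b", exons=[(50, 150), (200, 320)])
        (m,) = merge_redundant([a, b])
        assert m.exons == [(0, 150), (200, 320)]

    def test_identical_duplicates_collapse_with_sources(self):
        a = make_locus(0, 900, tid="a")
        b = make_locus(0, 900, tid="b")
        (m,) = merge_redundant(
            [a, b],
            sources={"a": frozenset({"DB1"}), "b": frozenset({"DB2"})},
        )
        assert m.sources == frozenset({"DB1", "DB2"})

    def test_single_linkage_chains(self):
        # a~b and b~c merge all three even though a,c overlap < 80%
        a = make_locus(0, 1000, tid="a")
        b = make_locus(150, 1150, tid="b")
        c = make_locus(300, 1300, tid="c")
        (m,) = merge_redundant([a, b, c])
        assert m.member_transcript_ids == frozenset({"a", "b", "c"})

    def test_no_locus_lost_or_duplicated(self):
        rng = np.random.default_rng(1)
        loci = []
        for i in range(40):
            s = int(rng.integers(0, 20000))
            loci.append(make_locus(s, s + int(rng.integers(300, 1500)), tid=f"t{i}"))
        merged = merge_redundant(loci)
        members = [t for m in merged for t in m.member_transcript_ids]
        assert sorted(members) == sorted(l.transcript_id for l in loci)

    def test_representative_is_longest_member(self):
        a = make_locus(0, 900, tid="a")
        b = make_locus(0, 901, tid="b")
        (m,) = merge_redundant([a, b], sequences={"a": "A" * 500, "b": "A" * 700})
        assert m.representative_id == "b"
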