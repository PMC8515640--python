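"""Building a non-redundant, genome-placed lncRNA catalogue.

Per-species transcript sets collected from several source databases overlap
heavily.  Each transcript is placed on its genome from its alignment hit
table: hit fragments within 4 kb of each other on one chromosome/strand are
clustered, each cluster is scored by *effective coverage* (union of query
intervals over query length) and *weighted identity* (alignment-length
weighted mean of fragment identities), and the optimal cluster — highest
weighted identity, then highest coverage, among clusters exceeding 70 %
coverage and 80 % identity — becomes the transcript's placement.  Multiple
tied optimal clusters are paralogous copies.  Placements on one
chromosome/strand whose spans overlap by more than 80 % of the shorter span
are merged (single linkage) into one theoretical lncRNA carrying the union
of the member exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentHit, TranscriptRecord

__all__ = [
    "HitCluster",
    "PlacedLocus",
    "MergedLncRNA",
    "filter_transcripts",
    "cluster_hits",
    "score_cluster",
    "select_optimal_clusters",
    "merge_redundant",
    "place_transcripts",
    "build_catalogue",
    "fuse_intervals",
]

_TIE_TOL = 1e-9


def fuse_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Fuse overlapping or touching half-open intervals into a disjoint sorted list."""
    ivs = sorted(intervals)
    fused: list[tuple[int, int]] = []
    for start, end in ivs:
        if fused and start <= fused[-1][1]:
            fused[-1] = (fused[-1][0], max(fused[-1][1], end))
        else:
            fused.append((start, end))
    return fused


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in fuse_intervals(intervals))


@dataclass
class HitCluster:
    """A group of alignment fragments of one transcript on one chrom/strand."""

    transcript_id: str
    chrom: str
    strand: str
    members: list[AlignmentHit]
    effective_coverage: float | None = None
    weighted_identity: float | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(h.s_start for h in self.members),
            max(h.s_end for h in self.members),
        )


@dataclass
class PlacedLocus:
    """A transcript's accepted genomic placement with fused exon intervals."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    is_paralog_copy: bool = False
    effective_coverage: float | None = None
    weighted_identity: float | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class MergedLncRNA:
    """One non-redundant catalogue entry: the exon union of redundant placements."""

    merged_id: str
    member_transcript_ids: frozenset
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sources: frozenset = frozenset()
    representative_sequence: str | None = None
    representative_id: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


def filter_transcripts(
    records: Iterable[TranscriptRecord], min_length: int = 200
) -> list[TranscriptRecord]:
    """Keep transcripts longer than ``min_length`` nt and not flagged coding.

    The coding verdict is external (e.g. CPC2); records without one pass
    through unfiltered.
    """
    return [
        r
        for r in records
        if r.length > min_length and r.coding_flag is not True
    ]


def cluster_hits(
    hits: Sequence[AlignmentHit], max_gap: int = 4000
) -> list[HitCluster]:
    """Cluster one transcript's genome hits into candidate loci.

    Hits are partitioned by (chromosome, strand), sorted by subject start
    and split wherever the gap to the running subject end exceeds
    ``max_gap`` (4 kb by default — the scale of plant introns).
    """
    if not hits:
        return []
    tids = {h.query_id for h in hits}
    if len(tids) != 1:
        raise ValueError(f"cluster_hits expects hits of one transcript, got {sorted(tids)}")
    (tid,) = tids
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    clusters: list[HitCluster] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda h: (h.s_start, h.s_end))
        current: list[AlignmentHit] = [members[0]]
        reach = members[0].s_end
        for h in members[1:]:
            if h.s_start - reach > max_gap:
                clusters.append(HitCluster(tid, chrom, strand, current))
                current = [h]
                reach = h.s_end
            else:
                current.append(h)
                reach = max(reach, h.s_end)
        clusters.append(HitCluster(tid, chrom, strand, current))
    return clusters


def score_cluster(
    cluster: HitCluster, query_length: int
) -> tuple[float, float]:
    """Score a cluster by effective coverage and weighted identity.

    Effective coverage is the length of the *union* of member query
    intervals divided by the query length (overlapping fragments are not
    double-counted, so coverage never exceeds 1).  Weighted identity is the
    alignment-length weighted mean of fragment percent identities.  Both
    values are stored on the cluster and returned.
    """
    if not cluster.members:
        raise ValueError("cannot score an empty cluster")
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    covered = _union_length((h.q_start, h.q_end) for h in cluster.members)
    coverage = min(covered / query_length, 1.0)
    total_len = sum(h.aln_length for h in cluster.members)
    wid = sum(h.pct_identity * h.aln_length for h in cluster.members) / total_len
    cluster.effective_coverage = coverage
    cluster.weighted_identity = wid
    return coverage, wid


def select_optimal_clusters(
    clusters: Sequence[HitCluster],
    min_coverage: float = 0.70,
    min_identity: float = 80.0,
) -> list[PlacedLocus]:
    """Pick a transcript's optimal cluster(s) and turn them into placements.

    Candidates must exceed both thresholds strictly.  Among survivors the
    optimum has the highest weighted identity and, at equal identity, the
    highest effective coverage.  Every cluster tied with the optimum on
    both scores becomes a placement; ties mark paralogous copies.  With no
    survivor the transcript is unplaced and an empty list is returned.
    """
    scored = [
        c
        for c in clusters
        if c.effective_coverage is not None and c.weighted_identity is not None
    ]
    if len(scored) != len(clusters):
        raise ValueError("select_optimal_clusters requires scored clusters")
    survivors = [
        c
        for c in scored
        if c.effective_coverage > min_coverage and c.weighted_identity > min_identity
    ]
    if not survivors:
        return []
    best = max(
        survivors, key=lambda c: (c.weighted_identity, c.effective_coverage)
    )
    ties = [
        c
        for c in survivors
        if abs(c.weighted_identity - best.weighted_identity) <= _TIE_TOL
        and abs(c.effective_coverage - best.effective_coverage) <= _TIE_TOL
    ]
    paralog = len(ties) > 1
    loci = []
    for c in ties:
        exons = fuse_intervals((h.s_start, h.s_end) for h in c.members)
        loci.append(
            PlacedLocus(
                transcript_id=c.transcript_id,
                chrom=c.chrom,
                strand=c.strand,
                exons=exons,
                is_paralog_copy=paralog,
                effective_coverage=c.effective_coverage,
                weighted_identity=c.weighted_identity,
            )
        )
    return loci


def _span_overlap(a: PlacedLocus, b: PlacedLocus) -> int:
    return max(0, min(a.span[1], b.span[1]) - max(a.span[0], b.span[0]))


def _exon_overlap(a: PlacedLocus, b: PlacedLocus) -> int:
    total = 0
    for sa, ea in a.exons:
        for sb, eb in b.exons:
            total += max(0, min(ea, eb) - max(sa, sb))
    return total


def _redundant(a: PlacedLocus, b: PlacedLocus, overlap_frac: float, mode: str) -> bool:
    if mode == "span":
        ov = _span_overlap(a, b)
        shorter = min(a.span_length, b.span_length)
    elif mode == "exon":
        ov = _exon_overlap(a, b)
        shorter = min(
            _union_length(a.exons), _union_length(b.exons)
        )
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return shorter > 0 and ov > overlap_frac * shorter


def merge_redundant(
    loci: Sequence[PlacedLocus],
    overlap_frac: float = 0.80,
    mode: str = "span",
    sequences: Mapping[str, str] | None = None,
    sources: Mapping[str, frozenset] | None = None,
) -> list[MergedLncRNA]:
    """Merge redundant placements into non-redundant theoretical lncRNAs.

    Two placements on the same chromosome and strand are redundant when
    their overlap exceeds ``overlap_frac`` of the shorter one; redundancy
    is closed under single linkage.  Overlap is measured on genomic spans
    by default (``mode='exon'`` measures exon-union overlap instead).  Each
    component yields one record with the fused exon union; when
    ``sequences`` is given the longest member's sequence is kept as
    representative.
    """
    groups: dict[tuple[str, str], list[PlacedLocus]] = {}
    for locus in loci:
        groups.setdefault((locus.chrom, locus.strand), []).append(locus)
    merged: list[MergedLncRNA] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda l: (l.span, l.transcript_id))
        # single-linkage components via interval sweep + union-find on sorted order
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].span[0] >= members[i].span[1]:
                    break
                if _redundant(members[i], members[j], overlap_frac, mode):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        comps: dict[int, list[PlacedLocus]] = {}
        for i, locus in enumerate(members):
            comps.setdefault(find(i), []).append(locus)
        for root in sorted(comps):
            comp = comps[root]
            exons = fuse_intervals(iv for l in comp for iv in l.exons)
            tids = frozenset(l.transcript_id for l in comp)
            rep_id = rep_seq = None
            if sequences is not None:
                with_seq = [t for t in tids if t in sequences]
                if with_seq:
                    # longest member; ties go to the lexicographically first id
                    rep_id = sorted(with_seq, key=lambda t: (-len(sequences[t]), t))[0]
                    rep_seq = sequences[rep_id]
            src = frozenset()
            if sources is not None:
                for t in tids:
                    src |= sources.get(t, frozenset())
            merged.append(
                MergedLncRNA(
                    merged_id="",  # assigned below, deterministic over full output
                    member_transcript_ids=tids,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    sources=src,
                    representative_sequence=rep_seq,
                    representative_id=rep_id,
                )
            )
    merged.sort(key=lambda m: (m.chrom, m.strand, m.span, sorted(m.member_transcript_ids)))
    for i, m in enumerate(merged, start=1):
        m.merged_id = f"MLNC{i:05d}"
    return merged


def place_transcripts(
    records: Sequence[TranscriptRecord],
    hits: Sequence[AlignmentHit],
    max_gap: int = 4000,
    min_coverage: float = 0.70,
    min_identity: float = 80.0,
) -> tuple[list[PlacedLocus], list[str]]:
    """Place each transcript on the genome from its hit table.

    Returns accepted placements and the ids of unplaced (rejected)
    transcripts.
    """
    hits_by_tid: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        hits_by_tid.setdefault(h.query_id, []).append(h)
    placed: list[PlacedLocus] = []
    rejected: list[str] = []
    for rec in records:
        own = hits_by_tid.get(rec.transcript_id, [])
        clusters = cluster_hits(own, max_gap=max_gap)
        for c in clusters:
            score_cluster(c, rec.length)
        loci = select_optimal_clusters(
            clusters, min_coverage=min_coverage, min_identity=min_identity
        )
        if loci:
            placed.extend(loci)
        else:
            rejected.append(rec.transcript_id)
    return placed, rejected


def build_catalogue(
    records: Sequence[TranscriptRecord],
    hits: Sequence[AlignmentHit],
    min_length: int = 200,
    max_gap: int = 4000,
    min_coverage: float = 0.70,
    min_identity: float = 80.0,
    overlap_frac: float = 0.80,
    overlap_mode: str = "span",
) -> tuple[list[MergedLncRNA], list[str]]:
    """Full per-species integration: filter, place, merge.

    Returns the non-redundant catalogue and the reject log (filtered-out or
    unplaced transcript ids).
    """
    kept = filter_transcripts(records, min_length=min_length)
    kept_ids = {r.transcript_id for r in kept}
    dropped = [r.transcript_id for r in records if r.transcript_id not in kept_ids]
    placed, unplaced = place_transcripts(
        kept, hits, max_gap=max_gap, min_coverage=min_coverage, min_identity=min_identity
    )
    sequences = {r.transcript_id: r.sequence for r in kept}
    sources = {r.transcript_id: r.sources for r in kept}
    catalogue = merge_redundant(
        placed,
        overlap_frac=overlap_frac,
        mode=overlap_mode,
        sequences=sequences,
        sources=sources,
    )
    return catalogue, dropped + unplaced
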