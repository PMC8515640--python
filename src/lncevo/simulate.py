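"""Synthetic pipeline inputs with planted, machine-readable truth.

Every external input the pipeline consumes can be generated here with a
known ground truth, so each stage — and the full run — is testable
without any database download or external aligner:

* **families** — ancestral sequences are planted at chosen nodes of a
  dated species tree and evolved down the subtree by per-branch
  substitution (no indels, so identity and coverage stay analytically
  predictable); orphan sequences are drawn i.i.d. per species.
* **hits** — an aligner stand-in emits 12-column tabular rows for the true
  homolog pairs, with identity equal to the observed sequence identity and
  an E-value that is a fixed monotone function of identity x length (only
  its ordering matters downstream), plus optional spurious low-identity
  rows.
* **redundancy** — each locus is re-emitted under 2–4 database labels with
  subject-coordinate jitter below 5 % of its length, together with
  transcript-vs-genome hit rows, to exercise placement and merging.
* **expression** — constitutive genes fluctuate log-normally around a
  common background; tissue-specific genes put one tissue at
  ``signal_ratio`` x background with only a small leakage elsewhere.
* **GO** — terms are painted on random gene sets; designated neighbour
  sets can be over-painted so the hypergeometric tests should fire.

All randomness flows from a single integer seed; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .formats import (
    TISSUES,
    AlignmentHit,
    ExpressionTable,
    SampleRecord,
    SpeciesTree,
    TranscriptRecord,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "make_tree",
    "simulate_families",
    "simulate_hits",
    "simulate_redundancy",
    "simulate_expression",
    "simulate_go",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study conditions.

    25 species spanning 180 Myr, 50 planted orthologous families, nine
    tissues sampled as 5 biological x 2 technical replicates (90 samples),
    and 500 genes in the expression design.
    """

    seed: int = 1
    # tree / families
    n_species: int = 25
    tree_newick: str | None = None
    tree_depth_myr: float = 180.0
    n_families: int = 50
    sub_rate_per_myr: float = 0.0005
    family_length_range: tuple[int, int] = (201, 2000)
    n_orphans_per_species: int = 10
    orphan_length_range: tuple[int, int] = (201, 2000)
    # hits
    spurious_hit_rate: float = 0.05
    # redundancy / genome placement
    min_duplicates: int = 2
    max_duplicates: int = 4
    jitter_frac: float = 0.03
    locus_gap: int = 10000
    split_hsp_fraction: float = 0.3
    intron_gap: int = 500
    # expression
    n_expression_genes: int = 500
    specific_fraction: float = 0.3
    n_bio_reps: int = 5
    n_tech_reps: int = 2
    background_fpkm: float = 5.0
    signal_ratio: float = 20.0
    leakage: float = 0.02
    noise_sigma: float = 0.10
    tech_sigma: float = 0.05
    # GO
    n_go_terms: int = 20
    go_paint_prob: float = 0.1
    planted_paint_fraction: float = 0.9


@dataclass
class PlantedTruth:
    """Ground truth of everything the generator planted."""

    families: dict = field(default_factory=dict)  # fam_id -> frozenset[(species, id)]
    family_leafset: dict = field(default_factory=dict)  # fam_id -> tuple of species
    duplicate_groups: dict = field(default_factory=dict)  # species -> [frozenset ids]
    tissue_class: dict = field(default_factory=dict)  # gene -> tissue | "constitutive"
    planted_terms: dict = field(default_factory=dict)  # term -> frozenset genes


# ---------------------------------------------------------------------------
# tree


def make_tree(config: SimulationConfig) -> SpeciesTree:
    """The species tree of the simulation: given newick, or a random Yule tree
    rescaled so the root age equals ``tree_depth_myr``."""
    from .formats import read_newick_dated

    if config.tree_newick is not None:
        return read_newick_dated(config.tree_newick)
    from dendropy.simulate import treesim

    rng = random.Random(config.seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:02d}"
    # rescale root-to-deepest-leaf distance to the requested span
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    scale = config.tree_depth_myr / max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, always to a different base."""
    out = seq.copy()
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def simulate_families(
    config: SimulationConfig,
    tree: SpeciesTree | None = None,
) -> tuple[SpeciesTree, dict[str, list[TranscriptRecord]], PlantedTruth]:
    """Plant orthologous families on the tree and evolve their sequences.

    Each family gets an ancestral sequence at a planted internal node and
    one descendant copy per leaf of that subtree; the per-branch
    substitution probability is ``sub_rate_per_myr x branch length`` and
    must stay below saturation (0.75).  Orphans are i.i.d. random
    sequences with no homolog anywhere.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = make_tree(config)
    internal = tree.internal_nodes()
    truth = PlantedTruth()
    records: dict[str, list[TranscriptRecord]] = {
        leaf: [] for leaf in sorted(tree.leaf_names)
    }

    for edge_node in tree.tree.preorder_node_iter():
        if edge_node.edge.length is not None:
            p = config.sub_rate_per_myr * edge_node.edge.length
            if p > 0.75:
                raise ValueError(
                    f"substitution probability {p:.3f} on a branch exceeds 0.75 "
                    "(saturation); lower sub_rate_per_myr"
                )

    lo, hi = config.family_length_range
    for i in range(1, config.n_families + 1):
        fam_id = f"FAM{i:05d}"
        node = internal[int(rng.integers(0, len(internal)))]
        length = int(rng.integers(lo, hi + 1))
        ancestral = _random_seq(rng, length)
        members: list[tuple[str, str]] = []

        def descend(n, seq) -> None:
            for child in n.child_nodes():
                p = config.sub_rate_per_myr * (child.edge.length or 0.0)
                child_seq = _mutate(seq, p, rng)
                if child.is_leaf():
                    species = child.taxon.label
                    tid = f"{species}_F{i:03d}"
                    records[species].append(
                        TranscriptRecord(
                            transcript_id=tid,
                            species=species,
                            sequence=_to_str(child_seq),
                            sources=frozenset({"DB1"}),
                        )
                    )
                    members.append((species, tid))
                else:
                    descend(child, child_seq)

        descend(node, ancestral)
        truth.families[fam_id] = frozenset(members)
        truth.family_leafset[fam_id] = tree.leafset(node)

    olo, ohi = config.orphan_length_range
    for species in sorted(tree.leaf_names):
        for j in range(1, config.n_orphans_per_species + 1):
            length = int(rng.integers(olo, ohi + 1))
            records[species].append(
                TranscriptRecord(
                    transcript_id=f"{species}_O{j:03d}",
                    species=species,
                    sequence=_to_str(_random_seq(rng, length)),
                    sources=frozenset({"DB1"}),
                )
            )
    return tree, records, truth


# ---------------------------------------------------------------------------
# hits (aligner stand-in)

_EXP_CAP = 180.0


def _evalue(identity: float, length: int) -> float:
    """Fixed monotone map: better identity x length => smaller E-value.

    The exponent is rounded to an integer so the value survives tabular
    serialisation exactly; ties are resolved downstream by bitscore.
    """
    exponent = min(round((identity / 100.0) * length / 5.0), _EXP_CAP)
    return 10.0 ** (-exponent)


def _hamming(a: str, b: str) -> int:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((xa != xb).sum())


def simulate_hits(
    records_by_species: Mapping[str, Sequence[TranscriptRecord]],
    truth: PlantedTruth,
    spurious_rate: float = 0.0,
    seed: int = 1,
) -> list[AlignmentHit]:
    """Cross-species hit rows for every true homolog pair, both directions.

    Identity is 100 x (1 - observed divergence); spurious single-direction
    low-identity rows are added at ``spurious_rate`` per true pair.
    """
    rng = np.random.default_rng(seed)
    seq_of = {
        r.transcript_id: r.sequence
        for recs in records_by_species.values()
        for r in recs
    }
    hits: list[AlignmentHit] = []
    true_pairs = 0
    for fam_id in sorted(truth.families):
        members = sorted(truth.families[fam_id])
        for ia in range(len(members)):
            for ib in range(ia + 1, len(members)):
                (sp_a, id_a), (sp_b, id_b) = members[ia], members[ib]
                if sp_a == sp_b:
                    continue
                true_pairs += 1
                seq_a, seq_b = seq_of[id_a], seq_of[id_b]
                length = len(seq_a)
                mism = _hamming(seq_a, seq_b)
                identity = round(100.0 * (1.0 - mism / length), 2)
                ev = _evalue(identity, length)
                bs = round(2.0 * identity / 100.0 * length, 1)
                for qid, sid in ((id_a, id_b), (id_b, id_a)):
                    hits.append(
                        AlignmentHit(
                            query_id=qid,
                            subject_id=sid,
                            pct_identity=identity,
                            aln_length=length,
                            mismatches=mism,
                            gap_opens=0,
                            q_start=0,
                            q_end=length,
                            s_start=0,
                            s_end=length,
                            strand="+",
                            evalue=ev,
                            bitscore=bs,
                        )
                    )
    if spurious_rate > 0 and true_pairs > 0:
        all_ids = sorted(seq_of)
        species_of = {
            r.transcript_id: r.species
            for recs in records_by_species.values()
            for r in recs
        }
        n_spurious = int(rng.binomial(true_pairs, spurious_rate))
        for _ in range(n_spurious):
            qid, sid = rng.choice(all_ids, size=2, replace=False)
            if species_of[qid] == species_of[sid]:
                continue
            length = min(len(seq_of[qid]), len(seq_of[sid])) // 2
            length = max(length, 30)
            identity = round(float(rng.uniform(60.0, 70.0)), 2)
            hits.append(
                AlignmentHit(
                    query_id=str(qid),
                    subject_id=str(sid),
                    pct_identity=identity,
                    aln_length=length,
                    mismatches=int(length * (1 - identity / 100.0)),
                    gap_opens=0,
                    q_start=0,
                    q_end=length,
                    s_start=0,
                    s_end=length,
                    strand="+",
                    evalue=1e-6,
                    bitscore=round(0.5 * length, 1),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# redundancy / genome placement


def simulate_redundancy(
    records: Sequence[TranscriptRecord],
    config: SimulationConfig,
    seed: int = 1,
) -> tuple[list[TranscriptRecord], list[AlignmentHit], list[frozenset]]:
    """Re-emit each transcript under several database labels with jitter.

    Each input record becomes one genomic locus on a virtual chromosome;
    2–4 copies of it (distinct ids, distinct source labels, identical
    sequence) each receive transcript-vs-genome hit rows whose subject
    coordinates are jittered by less than ``jitter_frac`` of the locus
    length.  A fraction of copies is split into two HSPs separated by an
    intron-sized gap to exercise hit clustering.  Returns the duplicated
    records, the genome hit table and the planted duplicate groups.
    """
    rng = np.random.default_rng(seed)
    out_records: list[TranscriptRecord] = []
    out_hits: list[AlignmentHit] = []
    groups: list[frozenset] = []
    pos = 0
    chrom = "chr1"
    for rec in records:
        length = rec.length
        locus_start = pos
        pos += length + config.locus_gap
        n_dup = int(rng.integers(config.min_duplicates, config.max_duplicates + 1))
        ids = [rec.transcript_id] + [
            f"{rec.transcript_id}.d{k}" for k in range(2, n_dup + 1)
        ]
        groups.append(frozenset(ids))
        for k, tid in enumerate(ids):
            out_records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    species=rec.species,
                    sequence=rec.sequence,
                    sources=frozenset({f"DB{k + 1}"}),
                )
            )
            max_jit = max(1, int(config.jitter_frac * length))
            jit = int(rng.integers(-max_jit, max_jit + 1))
            start = max(0, locus_start + jit)
            identity = round(float(rng.uniform(98.5, 100.0)), 2)
            split = rng.random() < config.split_hsp_fraction and length >= 80
            if split:
                cut = length // 2
                pieces = [
                    (0, cut, start, start + cut),
                    (cut, length, start + cut + config.intron_gap,
                     start + length + config.intron_gap),
                ]
            else:
                pieces = [(0, length, start, start + length)]
            for qs, qe, ss, se in pieces:
                plen = qe - qs
                out_hits.append(
                    AlignmentHit(
                        query_id=tid,
                        subject_id=chrom,
                        pct_identity=identity,
                        aln_length=plen,
                        mismatches=int(plen * (1 - identity / 100.0)),
                        gap_opens=0,
                        q_start=qs,
                        q_end=qe,
                        s_start=ss,
                        s_end=se,
                        strand="+",
                        evalue=_evalue(identity, plen),
                        bitscore=round(2.0 * identity / 100.0 * plen, 1),
                    )
                )
    return out_records, out_hits, groups


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[ExpressionTable, list[SampleRecord], dict[str, str]]:
    """Nine-tissue expression with planted specific and constitutive genes.

    Constitutive genes fluctuate log-normally (sigma ``noise_sigma``)
    around ``background_fpkm`` in every tissue; a ``specific_fraction`` of
    genes instead expresses one tissue at ``signal_ratio`` x background
    with ``leakage`` x background elsewhere.  Technical replicates add a
    smaller log-normal wobble around each biological-replicate mean.
    Truth maps each gene to its planted tissue or "constitutive".
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed if seed is None else seed)
    if genes is None:
        genes = [f"g{i:04d}" for i in range(1, config.n_expression_genes + 1)]
    genes = list(genes)
    samples = [
        SampleRecord(
            sample_id=f"{tissue}_b{b}_t{r}", tissue=tissue, bio_rep=b, tech_rep=r
        )
        for tissue in TISSUES
        for b in range(1, config.n_bio_reps + 1)
        for r in range(1, config.n_tech_reps + 1)
    ]
    truth: dict[str, str] = {}
    n_specific = int(round(config.specific_fraction * len(genes)))
    specific_idx = set(
        rng.choice(len(genes), size=n_specific, replace=False).tolist()
    )
    tissue_of: dict[int, str] = {}
    for gi in sorted(specific_idx):
        tissue_of[gi] = TISSUES[int(rng.integers(0, len(TISSUES)))]

    data = np.zeros((len(genes), len(samples)))
    col_of = {s.sample_id: j for j, s in enumerate(samples)}
    for gi, gene in enumerate(genes):
        if gi in specific_idx:
            truth[gene] = tissue_of[gi]
        else:
            truth[gene] = "constitutive"
        for tissue in TISSUES:
            if gi in specific_idx:
                mu = (
                    config.signal_ratio * config.background_fpkm
                    if tissue == tissue_of[gi]
                    else config.leakage * config.background_fpkm
                )
            else:
                mu = config.background_fpkm
            for b in range(1, config.n_bio_reps + 1):
                bio = mu * float(rng.lognormal(0.0, config.noise_sigma))
                for r in range(1, config.n_tech_reps + 1):
                    val = bio * float(rng.lognormal(0.0, config.tech_sigma))
                    data[gi, col_of[f"{tissue}_b{b}_t{r}"]] = val
    matrix = pd.DataFrame(data, index=genes, columns=[s.sample_id for s in samples])
    return ExpressionTable(values=matrix), samples, truth


# ---------------------------------------------------------------------------
# GO associations


def simulate_go(
    genes: Sequence[str],
    n_terms: int = 20,
    paint_prob: float = 0.1,
    planted: Mapping[str, Iterable[str]] | None = None,
    paint_fraction: float = 0.9,
    seed: int = 1,
) -> tuple[dict[str, frozenset], PlantedTruth]:
    """Paint GO BP terms on random gene sets, with optional planted sets.

    ``planted`` maps a term id to genes that must be over-painted with it:
    ``paint_fraction`` of each planted set receives the term regardless of
    the background painting, so hypergeometric tests against the
    background should recover exactly these terms.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    assoc: dict[str, set[str]] = {g: set() for g in genes}
    for term in terms:
        mask = rng.random(len(genes)) < paint_prob
        for g, hit in zip(genes, mask):
            if hit:
                assoc[g].add(term)
    truth = PlantedTruth()
    if planted:
        for term, target in planted.items():
            target = [g for g in target if g in assoc]
            n_paint = max(1, int(round(paint_fraction * len(target))))
            chosen = list(
                rng.choice(target, size=min(n_paint, len(target)), replace=False)
            )
            for g in chosen:
                assoc[g].add(term)
            truth.planted_terms[term] = frozenset(chosen)
    out = {g: frozenset(t) for g, t in assoc.items() if t}
    return out, truth
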