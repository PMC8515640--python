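"""Readers and writers for the external formats the pipeline touches.

All genomic and alignment coordinates are **0-based, half-open** everywhere
inside the package.  Conversion from/to the 1-based inclusive convention of
BLAST tabular output happens only here, at the parse/serialise boundary, so
there is a single place to audit off-by-one errors.  Minus-strand subject
hits (reported by BLAST with ``sstart > send``) are normalised on read to
``start < end`` plus a strand flag, which keeps interval arithmetic uniform
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TISSUES",
    "TranscriptRecord",
    "AlignmentHit",
    "SampleRecord",
    "ExpressionTable",
    "GOAssociation",
    "SpeciesTree",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "read_fasta_manifest",
    "read_hits_tabular",
    "write_hits_tabular",
    "read_newick_dated",
    "read_expression",
    "write_expression",
    "read_go_associations",
    "write_go_associations",
]

#: Fixed vocabulary and ordering of the nine tissues of the expression design.
TISSUES = (
    "leaf",
    "cotyledons",
    "floral_bud",
    "seedling",
    "seed",
    "root",
    "endosperm",
    "inflorescence",
    "silique",
)

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TranscriptRecord:
    """One lncRNA sequence with species and source-database provenance."""

    transcript_id: str
    species: str
    sequence: str
    sources: frozenset = frozenset()
    coding_flag: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in sequence of {self.transcript_id}"
            )
        if not self.sequence:
            raise ValueError(f"empty sequence: {self.transcript_id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment fragment (HSP) in internal coordinates.

    ``q_start:q_end`` and ``s_start:s_end`` are 0-based half-open with
    ``start < end`` on both axes; minus-strand subject placement is carried
    by ``strand`` alone.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval {self.q_start}:{self.q_end}")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad subject interval {self.s_start}:{self.s_end}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One RNA-seq sample: tissue plus biological and technical replicate."""

    sample_id: str
    tissue: str
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue {self.tissue!r} for sample {self.sample_id}; "
                f"expected one of {TISSUES}"
            )


@dataclass
class ExpressionTable:
    """FPKM matrix (genes x samples) with a per-gene kind label.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns; ``gene_kind`` maps gene id -> 'coding' | 'lncRNA'.
    """

    values: "pandas.DataFrame"  # noqa: F821 - documented type without import cycle
    gene_kind: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class GOAssociation:
    gene_id: str
    terms: frozenset


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path,
    species: str = "unknown",
    source: str | None = None,
) -> list[TranscriptRecord]:
    """Read a FASTA file into transcript records.

    Species and source-database labels come from the caller (normally via a
    manifest, see :func:`read_fasta_manifest`) rather than from header
    parsing heuristics.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    sources = frozenset([source]) if source else frozenset()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence: {rec.id}")
        records.append(
            TranscriptRecord(
                transcript_id=rec.id, species=species, sequence=seq, sources=sources
            )
        )
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_manifest(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a sidecar manifest: tab-separated (species, fasta path, source_db)."""
    rows: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        rows.append((parts[0], parts[1], parts[2]))
    return rows


def read_fasta_manifest(path: str | Path) -> list[TranscriptRecord]:
    """Read every FASTA listed in a manifest, labelling provenance per row.

    Transcript ids must be unique within a species; the same id appearing
    under several source databases has its source sets merged.
    """
    base = Path(path).parent
    by_key: dict[tuple[str, str], TranscriptRecord] = {}
    for species, fasta_path, source in read_manifest(path):
        p = Path(fasta_path)
        if not p.is_absolute():
            p = base / p
        for rec in read_fasta(p, species=species, source=source):
            key = (species, rec.transcript_id)
            if key in by_key:
                prev = by_key[key]
                if prev.sequence != rec.sequence:
                    raise ValueError(
                        f"conflicting sequences for {rec.transcript_id} in {species}"
                    )
                by_key[key] = TranscriptRecord(
                    transcript_id=rec.transcript_id,
                    species=species,
                    sequence=rec.sequence,
                    sources=prev.sources | rec.sources,
                    coding_flag=prev.coding_flag,
                )
            else:
                by_key[key] = rec
    return list(by_key.values())


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt-6 dialect)

_HITS_COLUMNS = 12


def read_hits_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST tabular hit file.

    Input coordinates are 1-based inclusive; rows whose subject coordinates
    are reversed (``sstart > send``) are minus-strand and are normalised to
    ``start < end`` with ``strand='-'``.
    """
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != _HITS_COLUMNS:
            raise ValueError(
                f"{path}:{lineno}: expected {_HITS_COLUMNS} columns, got {len(parts)}"
            )
        try:
            (qid, sid, pident, alen, mism, gaps,
             qs, qe, ss, se, ev, bs) = parts
            pident_f = float(pident)
            alen_i, mism_i, gaps_i = int(alen), int(mism), int(gaps)
            qs_i, qe_i, ss_i, se_i = int(qs), int(qe), int(ss), int(se)
            ev_f, bs_f = float(ev), float(bs)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        strand = "+"
        if ss_i > se_i:
            strand = "-"
            ss_i, se_i = se_i, ss_i
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=sid,
                pct_identity=pident_f,
                aln_length=alen_i,
                mismatches=mism_i,
                gap_opens=gaps_i,
                q_start=qs_i - 1,
                q_end=qe_i,
                s_start=ss_i - 1,
                s_end=se_i,
                strand=strand,
                evalue=ev_f,
                bitscore=bs_f,
            )
        )
    return hits


def _fmt(x: float) -> str:
    return f"{x:g}"


def hit_to_tabular_row(hit: AlignmentHit) -> str:
    """Serialise one hit back to the 1-based inclusive tabular convention."""
    if hit.strand == "+":
        ss, se = hit.s_start + 1, hit.s_end
    else:
        ss, se = hit.s_end, hit.s_start + 1
    fields = [
        hit.query_id,
        hit.subject_id,
        _fmt(hit.pct_identity),
        str(hit.aln_length),
        str(hit.mismatches),
        str(hit.gap_opens),
        str(hit.q_start + 1),
        str(hit.q_end),
        str(ss),
        str(se),
        _fmt(hit.evalue),
        _fmt(hit.bitscore),
    ]
    return "\t".join(fields)


def write_hits_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    Path(path).write_text("".join(hit_to_tabular_row(h) + "\n" for h in hits))


# ---------------------------------------------------------------------------
# Dated species tree


class SpeciesTree:
    """A rooted, dated species tree with per-node ages in Myr.

    The age of a node is the maximum path length (sum of branch lengths)
    from the node down to any descendant leaf; leaves have age 0 and ages
    are non-decreasing towards the root.  Near-ultrametric input (the usual
    state of dated-tree exports) is accepted; leaf depths differing by more
    than a relative 1e-6 trigger a warning, not an error.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self.leaf_names = frozenset(labels)
        root = tree.seed_node
        if len(root.child_nodes()) > 2 and len(labels) > 2:
            raise ValueError(
                "root has more than two children: tree appears unrooted"
            )
        self._ages: dict[dendropy.Node, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._ages[node] = 0.0
            else:
                self._ages[node] = max(
                    self._ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
                )
        depths = [self._leaf_depth(leaf) for leaf in tree.leaf_node_iter()]
        if len(depths) > 1 and max(depths) > 0:
            if (max(depths) - min(depths)) / max(depths) > 1e-6:
                warnings.warn(
                    "tree is not ultrametric; node ages use the maximum "
                    "root-to-leaf path",
                    stacklevel=2,
                )

    def _leaf_depth(self, leaf: dendropy.Node) -> float:
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    @property
    def root_age(self) -> float:
        return self._ages[self.tree.seed_node]

    def node_age(self, node: dendropy.Node) -> float:
        return self._ages[node]

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        """MRCA by intersecting leaf-to-root ancestor paths."""
        species = sorted(set(species))
        missing = [s for s in species if s not in self.leaf_names]
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        leaf_by_label = {
            leaf.taxon.label: leaf for leaf in self.tree.leaf_node_iter()
        }
        paths = []
        for s in species:
            node, path = leaf_by_label[s], []
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(path)
        if len(paths) == 1:
            return paths[0][0]
        common = set(paths[0])
        for path in paths[1:]:
            common &= set(path)
        # the first common node walking up from any leaf is the MRCA
        for node in paths[0]:
            if node in common:
                return node
        raise ValueError(f"no MRCA found for {species}")  # pragma: no cover

    def leafset(self, node: dendropy.Node) -> tuple[str, ...]:
        """Sorted tuple of leaf labels below a node — a stable node key."""
        if node.is_leaf():
            return (node.taxon.label,)
        return tuple(sorted(l.taxon.label for l in node.leaf_iter()))

    def internal_nodes(self) -> list[dendropy.Node]:
        return [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]


def read_newick_dated(source: str | Path) -> SpeciesTree:
    """Read a rooted newick tree with branch lengths in Myr.

    ``source`` may be a path or a newick string.
    """
    text = str(source)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels in tree: {exc}") from None
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet


def read_expression(
    path_matrix: str | Path,
    path_samples: str | Path,
    gene_kind: Mapping[str, str] | None = None,
) -> tuple[ExpressionTable, list[SampleRecord]]:
    """Read a genes x samples FPKM TSV and its sample sheet, cross-validated.

    The sample sheet is a TSV with header ``sample_id  tissue  bio_rep
    tech_rep``; every matrix column must appear in the sheet.
    """
    import pandas as pd

    matrix = pd.read_csv(path_matrix, sep="\t", index_col=0)
    sheet = pd.read_csv(path_samples, sep="\t")
    required = {"sample_id", "tissue", "bio_rep", "tech_rep"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    samples = [
        SampleRecord(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            bio_rep=int(r.bio_rep),
            tech_rep=int(r.tech_rep),
        )
        for r in sheet.itertuples()
    ]
    keys = [(s.tissue, s.bio_rep, s.tech_rep) for s in samples]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (tissue, bio_rep, tech_rep) in sample sheet")
    known = {s.sample_id for s in samples}
    missing = [c for c in matrix.columns if c not in known]
    if missing:
        raise ValueError(f"samples in matrix missing from sheet: {missing}")
    if (matrix.values < 0).any():
        raise ValueError("negative expression value in matrix")
    table = ExpressionTable(values=matrix, gene_kind=dict(gene_kind or {}))
    return table, samples


def write_expression(
    table: ExpressionTable, path_matrix: str | Path
) -> None:
    table.values.to_csv(path_matrix, sep="\t")


# ---------------------------------------------------------------------------
# GO associations

import re

_GO_RE = re.compile(r"^GO:\d{7}$")


def read_go_associations(path: str | Path) -> list[GOAssociation]:
    """Read a two-column (gene, GO term) TSV, aggregating rows per gene."""
    terms_by_gene: dict[str, set[str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        gene, term = parts
        if not _GO_RE.match(term):
            raise ValueError(f"{path}:{lineno}: malformed GO term {term!r}")
        if gene not in terms_by_gene:
            terms_by_gene[gene] = set()
            order.append(gene)
        terms_by_gene[gene].add(term)
    return [GOAssociation(g, frozenset(terms_by_gene[g])) for g in order]


def write_go_associations(
    associations: Iterable[GOAssociation] | Mapping[str, Iterable[str]],
    path: str | Path,
) -> None:
    lines = []
    items: Sequence
    if isinstance(associations, Mapping):
        items = [(g, sorted(t)) for g, t in associations.items()]
    else:
        items = [(a.gene_id, sorted(a.terms)) for a in associations]
    for gene, terms in items:
        for term in terms:
            lines.append(f"{gene}\t{term}\n")
    Path(path).write_text("".join(lines))


def associations_to_dict(
    associations: Iterable[GOAssociation] | Mapping[str, Iterable[str]],
) -> dict[str, frozenset]:
    """Normalise associations to a gene -> frozenset-of-terms mapping."""
    if isinstance(associations, Mapping):
        return {g: frozenset(t) for g, t in associations.items()}
    return {a.gene_id: frozenset(a.terms) for a in associations}
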