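"""Orthologous lncRNA families: RBH pairs, single-linkage clustering, dating.

Cross-species alignment hits (E <= 1e-5) give directed best hits per
(query gene, target species); reciprocal best hits are treated as
orthologous pairs, and connected components of the pair graph under
single linkage form families.  Each family is dated by the age of the
most recent common ancestor (MRCA) of its species set on a dated species
tree — the smallest clade that contains every species in the family.
Focal-species lncRNAs are then labelled with conservation categories by
the smallest configured clade containing their family's branch point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .formats import AlignmentHit, SpeciesTree

__all__ = [
    "OrthologPair",
    "OrthologFamily",
    "best_hits",
    "reciprocal_best_hits",
    "single_linkage_families",
    "assign_branch_point",
    "date_families",
    "count_families_per_branch",
    "age_class_summary",
    "categorize_focal",
    "conserved_fraction_per_species",
    "round_half_up",
]

Gene = tuple[str, str]  # (species, gene id)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (half-up)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit gene pair between two species (canonical order)."""

    gene_a: Gene
    gene_b: Gene

    def __post_init__(self) -> None:
        if self.gene_a[0] == self.gene_b[0]:
            raise ValueError("ortholog pair must span two species")
        if self.gene_b < self.gene_a:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)


@dataclass
class OrthologFamily:
    family_id: str
    members: frozenset  # of Gene
    branch_leafset: tuple[str, ...] | None = None
    age: float | None = None

    @property
    def species_set(self) -> frozenset:
        return frozenset(s for s, _ in self.members)


def best_hits(
    hits: Iterable[AlignmentHit],
    species_of: Mapping[str, str],
    max_evalue: float = 1e-5,
) -> dict[tuple[Gene, str], Gene]:
    """Directed best hit per (query gene, target species).

    Hits above the E-value threshold are discarded.  Ties are broken by
    lowest E-value, then highest bitscore, then lexicographic subject id —
    a deterministic total order.  Within-species hits are ignored
    (orthology only).
    """
    best: dict[tuple[Gene, str], tuple[float, float, str]] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        qsp = species_of.get(h.query_id)
        ssp = species_of.get(h.subject_id)
        if qsp is None or ssp is None:
            raise KeyError(
                f"unknown species for {h.query_id if qsp is None else h.subject_id}"
            )
        if qsp == ssp:
            continue
        key = ((qsp, h.query_id), ssp)
        cand = (h.evalue, -h.bitscore, h.subject_id)
        if key not in best or cand < best[key]:
            best[key] = cand
    return {key: (key[1], sid) for key, (_, _, sid) in best.items()}


def reciprocal_best_hits(
    best: Mapping[tuple[Gene, str], Gene]
) -> list[OrthologPair]:
    """Pairs (a, b) where a's best hit in b's species is b and vice versa."""
    pairs: set[OrthologPair] = set()
    for (gene_a, target_sp), gene_b in best.items():
        back = best.get((gene_b, gene_a[0]))
        if back == gene_a:
            pairs.add(OrthologPair(gene_a, gene_b))
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def single_linkage_families(pairs: Iterable[OrthologPair]) -> list[OrthologFamily]:
    """Families = connected components of the RBH pair graph.

    Genes in no pair form no family.  Multi-copy genes from one species
    that single linkage pulls into one component are kept (they remain
    distinguishable by gene id).
    """
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.gene_a, p.gene_b)
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
    )
    return [
        OrthologFamily(family_id=f"FAM{i:05d}", members=frozenset(comp))
        for i, comp in enumerate(components, start=1)
    ]


def assign_branch_point(
    family: OrthologFamily, tree: SpeciesTree
) -> tuple[tuple[str, ...], float]:
    """Date a family at the MRCA of its species set.

    Returns the MRCA's leaf set (a stable node key) and its age in Myr;
    both are also stored on the family.  A species missing from the tree
    raises with the species named.
    """
    try:
        node = tree.mrca(family.species_set)
    except KeyError as exc:
        raise KeyError(f"family {family.family_id}: {exc}") from None
    leafset = tree.leafset(node)
    age = tree.node_age(node)
    family.branch_leafset = leafset
    family.age = age
    return leafset, age


def date_families(
    families: Sequence[OrthologFamily], tree: SpeciesTree
) -> list[OrthologFamily]:
    for fam in families:
        assign_branch_point(fam, tree)
    return list(families)


def count_families_per_branch(
    families: Iterable[OrthologFamily], tree: SpeciesTree
) -> dict[tuple[str, ...], int]:
    """Number of families whose branch point is each tree node.

    Keys are node leaf sets (sorted label tuples); counts sum to the number
    of families.
    """
    counts: dict[tuple[str, ...], int] = {}
    for fam in families:
        if fam.branch_leafset is None:
            assign_branch_point(fam, tree)
        counts[fam.branch_leafset] = counts.get(fam.branch_leafset, 0) + 1
    return counts


def age_class_summary(
    families: Sequence[OrthologFamily],
    thresholds: Sequence[float] = (50.0, 100.0, 150.0, 180.0),
    ndigits: int = 2,
) -> "pandas.DataFrame":  # noqa: F821
    """Cumulative counts of families (and their lncRNAs) older than each threshold.

    Shares are percentages of all families / of all in-family lncRNAs,
    rounded half-up at ``ndigits`` decimals.
    """
    import pandas as pd

    undated = [f.family_id for f in families if f.age is None]
    if undated:
        raise ValueError(f"families not dated: {undated[:3]}")
    total_fams = len(families)
    total_lnc = sum(len(f.members) for f in families)
    rows = []
    for thr in thresholds:
        old = [f for f in families if f.age > thr]
        n_fam = len(old)
        n_lnc = sum(len(f.members) for f in old)
        rows.append(
            {
                "age_gt_myr": thr,
                "n_families": n_fam,
                "family_share_pct": round_half_up(100.0 * n_fam / total_fams, ndigits)
                if total_fams
                else 0.0,
                "n_lncRNAs": n_lnc,
                "lncRNA_share_pct": round_half_up(100.0 * n_lnc / total_lnc, ndigits)
                if total_lnc
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _validate_nested(categories: Sequence[tuple[str, frozenset]]) -> None:
    for (la, a), (lb, b) in zip(categories, categories[1:]):
        if not a < b:
            raise ValueError(
                f"category clades must be strictly nested: {la!r} is not "
                f"a proper subset of {lb!r}"
            )


def categorize_focal(
    families: Sequence[OrthologFamily],
    tree: SpeciesTree,
    categories: Sequence[tuple[str, Iterable[str]]],
    focal_species: str,
    focal_ids: Iterable[str],
    non_conserved_label: str = "non_conserved",
) -> dict[str, str]:
    """Label each focal-species lncRNA with a conservation category.

    ``categories`` is an ordered list of (label, clade species set) from the
    smallest clade outwards (e.g. genus, family, class, all angiosperms);
    clades must be strictly nested and each must contain the focal species.
    A lncRNA in no family is non-conserved; otherwise it takes the label of
    the smallest clade containing its family's branch point.
    """
    cats = [(label, frozenset(sp)) for label, sp in categories]
    _validate_nested(cats)
    for label, clade in cats:
        if focal_species not in clade:
            raise ValueError(f"category {label!r} does not contain {focal_species!r}")
    label_by_gene: dict[str, str] = {}
    for fam in families:
        if fam.branch_leafset is None:
            assign_branch_point(fam, tree)
        leafset = frozenset(fam.branch_leafset)
        fam_label = None
        for label, clade in cats:
            if leafset <= clade:
                fam_label = label
                break
        if fam_label is None:
            raise ValueError(
                f"family {fam.family_id} branch point {sorted(leafset)} exceeds "
                "the largest configured clade"
            )
        for species, gene_id in fam.members:
            if species == focal_species:
                label_by_gene[gene_id] = fam_label
    return {
        gid: label_by_gene.get(gid, non_conserved_label) for gid in focal_ids
    }


def conserved_fraction_per_species(
    families: Iterable[OrthologFamily],
    totals: Mapping[str, int],
    ndigits: int = 2,
) -> dict[str, float]:
    """Percent of each species' catalogued lncRNAs that are in any family."""
    conserved: dict[str, set[str]] = {}
    for fam in families:
        for species, gene_id in fam.members:
            conserved.setdefault(species, set()).add(gene_id)
    out: dict[str, float] = {}
    for species, total in totals.items():
        if total <= 0:
            raise ValueError(f"species {species!r} has zero lncRNAs")
        n = len(conserved.get(species, ()))
        out[species] = round_half_up(100.0 * n / total, ndigits)
    return out
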