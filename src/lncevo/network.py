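"""Coding–lncRNA co-expression network and hypergeometric GO tests.

Edges are Spearman correlations between the expression profiles of gene
pairs (restricted to high-variation genes).  The two-sided P-value comes
from the Fisher transformation, ``z = atanh(rho)``, with the normal
statistic ``z * sqrt(n - 3)``.  P-values are Bonferroni-corrected within
each gene's family of candidate pairs, and an edge is kept only when the
adjusted P from *both* endpoints is <= 0.05 (the conservative reading of a
per-gene correction).

GO biological-process annotation of a lncRNA is neighbour voting: for each
term carried by its immediate coding neighbours, an upper-tail
hypergeometric test asks whether the neighbours are enriched for the term
relative to the network; terms with P < alpha are assigned.  Set
enrichment of a study list against a population uses the same upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .formats import associations_to_dict
from .orthology import round_half_up

__all__ = [
    "CoexpressionEdge",
    "GOTermTest",
    "spearman_rho",
    "fisher_pvalue",
    "bonferroni_per_gene",
    "build_network",
    "edges_to_graph",
    "edge_type_counts",
    "hypergeom_upper",
    "annotate_lncrna_go",
    "go_enrichment",
]


@dataclass
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    rho: float
    p_raw: float
    p_adj_a: float | None = None
    p_adj_b: float | None = None
    kept: bool = False


@dataclass(frozen=True)
class GOTermTest:
    """One hypergeometric test record (population N, successes M, draws n, hits k)."""

    subject: str
    term: str
    N: int
    M: int
    n: int
    k: int
    p: float


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks.

    Returns NaN for constant vectors (the pair is skipped downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("vectors must have equal length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def fisher_pvalue(rho: float, n: int, spearman_variance: bool = False) -> float:
    """Two-sided P-value for a correlation via the Fisher transformation.

    The statistic is ``atanh(rho) * sqrt(n - 3)`` against a standard
    normal; ``spearman_variance=True`` uses the Spearman-specific variance
    1.06/(n-3) instead of 1/(n-3).  |rho| = 1 returns 0 (the limit).
    """
    if n <= 3:
        raise ValueError("n must exceed 3 for the Fisher transformation")
    if math.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    z = math.atanh(rho)
    scale = math.sqrt(1.06 / (n - 3)) if spearman_variance else math.sqrt(1.0 / (n - 3))
    statistic = z / scale
    return float(2.0 * stats.norm.sf(abs(statistic)))


def bonferroni_per_gene(
    edges: Sequence[CoexpressionEdge], alpha: float = 0.05
) -> list[CoexpressionEdge]:
    """Adjust raw P-values within each gene's family of candidate pairs.

    Each raw P is multiplied by the number of candidate pairs of its
    endpoint gene (capped at 1); the edge is kept iff the adjusted values
    from both endpoints are <= ``alpha``.
    """
    m: dict[str, int] = {}
    for e in edges:
        m[e.gene_a] = m.get(e.gene_a, 0) + 1
        m[e.gene_b] = m.get(e.gene_b, 0) + 1
    for e in edges:
        e.p_adj_a = min(1.0, e.p_raw * m[e.gene_a])
        e.p_adj_b = min(1.0, e.p_raw * m[e.gene_b])
        e.kept = max(e.p_adj_a, e.p_adj_b) <= alpha and not math.isnan(e.p_raw)
    return list(edges)


def build_network(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    spearman_variance: bool = False,
) -> list[CoexpressionEdge]:
    """All-pairs Spearman network over the rows of ``matrix`` (genes x samples).

    Computes mid-ranks per gene once and correlates them in one matrix
    product, then applies :func:`fisher_pvalue` and
    :func:`bonferroni_per_gene`.  Pairs involving a constant gene are
    skipped.  Iteration order is the row order of ``matrix``, so identical
    input yields an identical edge list.
    """
    genes = list(matrix.index)
    values = matrix.to_numpy(dtype=float)
    n_samples = values.shape[1]
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    constant = np.all(values == values[:, [0]], axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    # vectorised Fisher-transform P-values for the whole matrix
    scale = math.sqrt((1.06 if spearman_variance else 1.0) / (n_samples - 3))
    clipped = np.clip(corr, -1.0, 1.0)
    saturated = np.abs(clipped) >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.where(saturated, 0.0, clipped))
    pmat = 2.0 * stats.norm.sf(np.abs(z) / scale)
    pmat[saturated] = 0.0
    edges: list[CoexpressionEdge] = []
    for i in range(len(genes)):
        if constant[i]:
            continue
        for j in range(i + 1, len(genes)):
            if constant[j]:
                continue
            edges.append(
                CoexpressionEdge(genes[i], genes[j], float(corr[i, j]), float(pmat[i, j]))
            )
    return bonferroni_per_gene(edges, alpha=alpha)


def edges_to_graph(edges: Iterable[CoexpressionEdge]) -> nx.Graph:
    """Graph of kept edges only."""
    g = nx.Graph()
    for e in edges:
        if e.kept:
            g.add_edge(e.gene_a, e.gene_b, rho=e.rho, p_raw=e.p_raw)
    return g


def edge_type_counts(
    edges: Iterable[CoexpressionEdge],
    gene_kind: Mapping[str, str],
    ndigits: int = 2,
) -> pd.DataFrame:
    """Counts and percent shares of kept edges by endpoint kinds.

    Rows: coding-coding, coding-lncRNA, lncRNA-lncRNA; shares are half-up
    rounded percentages of the kept-edge total.
    """
    counts = {"coding-coding": 0, "coding-lncRNA": 0, "lncRNA-lncRNA": 0}
    for e in edges:
        if not e.kept:
            continue
        kinds = sorted((gene_kind[e.gene_a], gene_kind[e.gene_b]))
        if kinds == ["coding", "coding"]:
            counts["coding-coding"] += 1
        elif kinds == ["coding", "lncRNA"]:
            counts["coding-lncRNA"] += 1
        else:
            counts["lncRNA-lncRNA"] += 1
    total = sum(counts.values())
    rows = [
        {
            "edge_type": k,
            "count": v,
            "share_pct": round_half_up(100.0 * v / total, ndigits) if total else 0.0,
        }
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)


def hypergeom_upper(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a population
    of ``N`` with ``M`` successes.  ``k = 0`` is the certain event (P = 1).
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"infeasible hypergeometric parameters N={N} M={M} n={n}")
    if not (0 <= k <= min(n, M)):
        raise ValueError(f"infeasible k={k} for M={M}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def annotate_lncrna_go(
    graph: nx.Graph,
    lncrna_ids: Iterable[str],
    associations,
    alpha: float = 0.05,
) -> list[GOTermTest]:
    """Neighbour-voting GO annotation of lncRNAs in the network.

    For each lncRNA and each term carried by its immediate neighbours:
    N = genes in the network, M = network genes carrying the term,
    n = the lncRNA's immediate neighbours, k = neighbours carrying the
    term; the term is assigned when the upper-tail P < ``alpha``.
    Isolated lncRNAs simply receive no annotation.
    """
    assoc = associations_to_dict(associations)
    N = graph.number_of_nodes()
    genes_with_term: dict[str, int] = {}
    for g in graph.nodes:
        for t in assoc.get(g, ()):
            genes_with_term[t] = genes_with_term.get(t, 0) + 1
    assigned: list[GOTermTest] = []
    for lnc in sorted(set(lncrna_ids)):
        if lnc not in graph:
            continue
        neighbors = sorted(graph.neighbors(lnc))
        n = len(neighbors)
        terms = sorted({t for nb in neighbors for t in assoc.get(nb, ())})
        for term in terms:
            M = genes_with_term[term]
            k = sum(1 for nb in neighbors if term in assoc.get(nb, ()))
            p = hypergeom_upper(N, M, n, k)
            if p < alpha:
                assigned.append(GOTermTest(lnc, term, N, M, n, k, p))
    return assigned


def go_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    associations,
    alpha: float = 0.05,
) -> list[GOTermTest]:
    """Hypergeometric term enrichment of a study set within a population.

    N = annotated population genes, M = population genes with the term,
    n = annotated study genes, k = study genes with the term.  Terms with
    P < ``alpha`` are returned sorted by P then term id.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    assoc = associations_to_dict(associations)
    pop_ann = {g for g in population if assoc.get(g)}
    study_ann = {g for g in study if assoc.get(g)}
    N, n = len(pop_ann), len(study_ann)
    results: list[GOTermTest] = []
    terms = sorted({t for g in study_ann for t in assoc[g]})
    for term in terms:
        M = sum(1 for g in pop_ann if term in assoc[g])
        k = sum(1 for g in study_ann if term in assoc[g])
        p = hypergeom_upper(N, M, n, k)
        if p < alpha:
            results.append(GOTermTest("study", term, N, M, n, k, p))
    return sorted(results, key=lambda r: (r.p, r.term))
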