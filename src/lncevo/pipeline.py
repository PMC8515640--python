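"""End-to-end orchestration of the synthetic study.

``run_all`` executes the pipeline stages in order — simulate inputs,
integrate per-species catalogues, build and date orthologous families,
compute expression profiles, build the co-expression network, annotate and
enrich GO terms, and write the summary report — logging parameters and
per-stage progress.  Stage outputs live in per-stage subdirectories of the
output directory; a stage whose ``_done`` marker exists is reloaded from
its files on rerun instead of being recomputed (the pipeline is
deterministic under a fixed seed, so reload and recompute agree).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import expression as expr
from . import integration, network, orthology, report, simulate
from .formats import (
    TISSUES,
    ExpressionTable,
    SpeciesTree,
    write_expression,
    write_fasta,
    write_go_associations,
    write_hits_tabular,
)

__all__ = ["run_all", "default_categories", "write_catalogue", "write_families"]

log = logging.getLogger("lncevo")


def write_catalogue(catalogue, path: Path) -> None:
    rows = []
    for m in catalogue:
        rows.append(
            {
                "merged_id": m.merged_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "span_start": m.span[0],
                "span_end": m.span[1],
                "exons": ";".join(f"{s}-{e}" for s, e in m.exons),
                "members": ";".join(sorted(m.member_transcript_ids)),
                "sources": ";".join(sorted(m.sources)),
                "representative_id": m.representative_id or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_families(families, path: Path) -> None:
    rows = []
    for f in families:
        rows.append(
            {
                "family_id": f.family_id,
                "members": ";".join(f"{sp}|{gid}" for sp, gid in sorted(f.members)),
                "branch_leafset": ",".join(f.branch_leafset or ()),
                "age_myr": f.age,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_categories(
    tree: SpeciesTree, focal_species: str
) -> list[tuple[str, frozenset]]:
    """Nested conservation categories from the focal leaf's ancestors.

    One category per ancestor node on the path from the focal leaf to the
    root, smallest clade first, labelled ``clade_01`` (shallowest) upward.
    """
    node = None
    for leaf in tree.tree.leaf_node_iter():
        if leaf.taxon.label == focal_species:
            node = leaf
            break
    if node is None:
        raise KeyError(f"focal species {focal_species!r} not in tree")
    clades: list[frozenset] = []
    anc = node.parent_node
    while anc is not None:
        leafset = frozenset(tree.leafset(anc))
        if not clades or leafset != clades[-1]:
            clades.append(leafset)
        anc = anc.parent_node
    return [(f"clade_{i:02d}", c) for i, c in enumerate(clades, start=1)]


def _stage(out: Path, name: str):
    d = out / name
    d.mkdir(parents=True, exist_ok=True)
    return d, d / "_done"


def run_all(
    config: simulate.SimulationConfig,
    out_dir: str | Path,
    focal_species: str | None = None,
    resume: bool = True,
) -> dict:
    """Run every stage on synthetic inputs; returns the artifact dictionary.

    The returned dict carries the tree, per-species catalogues, dated
    families, expression profiles, kept network edges, GO results and the
    summary tables, plus the planted truth for comparison.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_all(config, out, focal_species, resume, t0)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_all(config, out, focal_species, resume, t0):
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )

    # -- stage 1: simulate all inputs -------------------------------------
    sim_dir, sim_done = _stage(out, "simulate")
    tree, base_records, truth = simulate.simulate_families(config)
    log.info("simulate: %d species, %d families", len(base_records), len(truth.families))
    cross_hits = simulate.simulate_hits(
        base_records, truth, spurious_rate=config.spurious_hit_rate, seed=config.seed + 1
    )
    db_records: dict[str, list] = {}
    genome_hits: dict[str, list] = {}
    for k, species in enumerate(sorted(base_records)):
        recs, ghits, groups = simulate.simulate_redundancy(
            base_records[species], config, seed=config.seed + 100 + k
        )
        db_records[species] = recs
        genome_hits[species] = ghits
        truth.duplicate_groups[species] = groups
    if not (resume and sim_done.exists()):
        tree.tree.write(path=str(sim_dir / "species_tree.nwk"), schema="newick")
        manifest_lines = []
        for species in sorted(db_records):
            fa = sim_dir / f"{species}.fasta"
            write_fasta(db_records[species], fa)
            write_hits_tabular(genome_hits[species], sim_dir / f"{species}.genome_hits.tsv")
            manifest_lines.append(f"{species}\t{fa.name}\tDB1\n")
        (sim_dir / "manifest.tsv").write_text("".join(manifest_lines))
        write_hits_tabular(cross_hits, sim_dir / "cross_species_hits.tsv")
        sim_done.touch()

    # -- stage 2: per-species integration ---------------------------------
    int_dir, int_done = _stage(out, "integrate")
    catalogues: dict[str, list] = {}
    rejects: dict[str, list] = {}
    for species in sorted(db_records):
        catalogue, rejected = integration.build_catalogue(
            db_records[species], genome_hits[species]
        )
        catalogues[species] = catalogue
        rejects[species] = rejected
        if not (resume and int_done.exists()):
            write_catalogue(catalogue, int_dir / f"{species}.catalogue.tsv")
            (int_dir / f"{species}.rejected.txt").write_text(
                "".join(f"{t}\n" for t in rejected)
            )
    int_done.touch()
    log.info(
        "integrate: %d merged loci across %d species",
        sum(len(c) for c in catalogues.values()),
        len(catalogues),
    )

    # -- stage 3: orthologous families ------------------------------------
    fam_dir, fam_done = _stage(out, "families")
    species_of = {
        r.transcript_id: r.species
        for recs in base_records.values()
        for r in recs
    }
    best = orthology.best_hits(cross_hits, species_of)
    pairs = orthology.reciprocal_best_hits(best)
    families = orthology.single_linkage_families(pairs)
    orthology.date_families(families, tree)
    branch_counts = orthology.count_families_per_branch(families, tree)
    totals = {sp: len(cat) for sp, cat in catalogues.items()}
    conserved_pct = orthology.conserved_fraction_per_species(families, totals)
    age_summary = orthology.age_class_summary(families)
    if not (resume and fam_done.exists()):
        write_families(families, fam_dir / "families.tsv")
        age_summary.to_csv(fam_dir / "age_classes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"branch": ",".join(k), "n_families": v}
                for k, v in sorted(branch_counts.items())
            ]
        ).to_csv(fam_dir / "branch_counts.tsv", sep="\t", index=False)
        fam_done.touch()
    log.info("families: %d families from %d RBH pairs", len(families), len(pairs))

    # -- stage 4: focal categories ----------------------------------------
    focal = focal_species or sorted(base_records)[0]
    categories = default_categories(tree, focal)
    focal_ids = sorted(
        m.representative_id or m.merged_id for m in catalogues[focal]
    )
    labels = orthology.categorize_focal(families, tree, categories, focal, focal_ids)
    deepest = [lab for lab, _ in categories][-2:]
    pool = {lab: "ultra" for lab in deepest} if len(categories) > 2 else None
    cat_summary = report.category_summary(labels, pool=pool)

    # -- stage 5: expression ----------------------------------------------
    expr_dir, expr_done = _stage(out, "expression")
    focal_lnc = focal_ids[: config.n_expression_genes // 5]
    n_coding = config.n_expression_genes - len(focal_lnc)
    coding_genes = [f"cg{i:04d}" for i in range(1, n_coding + 1)]
    genes = coding_genes + focal_lnc
    table, samples, expr_truth = simulate.simulate_expression(
        config, genes=genes, seed=config.seed + 2
    )
    table.gene_kind = {
        g: ("coding" if g in set(coding_genes) else "lncRNA") for g in genes
    }
    profiles = expr.profile_table(table, samples)
    if not (resume and expr_done.exists()):
        write_expression(table, expr_dir / "matrix.tsv")
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "tissue": s.tissue,
                    "bio_rep": s.bio_rep,
                    "tech_rep": s.tech_rep,
                }
                for s in samples
            ]
        ).to_csv(expr_dir / "samples.tsv", sep="\t", index=False)
        profiles.to_csv(expr_dir / "profiles.tsv", sep="\t")
        expr_done.touch()
    log.info("expression: %d genes profiled", len(profiles))

    # -- stage 6: network + GO --------------------------------------------
    net_dir, net_done = _stage(out, "network")
    normalized = expr.upper_quartile_normalize(table)
    keep = expr.high_variation_filter(normalized)
    matrix = normalized.values.loc[sorted(keep)]
    edges = network.build_network(matrix)
    graph = network.edges_to_graph(edges)
    type_counts = network.edge_type_counts(edges, table.gene_kind)
    lnc_in_net = [g for g in graph.nodes if table.gene_kind.get(g) == "lncRNA"]
    planted_go: dict[str, list[str]] = {}
    term_i = 900
    for lnc in sorted(lnc_in_net):
        neighbors = [
            g for g in graph.neighbors(lnc) if table.gene_kind.get(g) == "coding"
        ]
        if len(neighbors) >= 5 and len(planted_go) < 3:
            term_i += 1
            planted_go[f"GO:{term_i:07d}"] = neighbors
    assoc, go_truth = simulate.simulate_go(
        coding_genes,
        n_terms=config.n_go_terms,
        paint_prob=config.go_paint_prob,
        planted=planted_go,
        paint_fraction=config.planted_paint_fraction,
        seed=config.seed + 3,
    )
    annotations = network.annotate_lncrna_go(graph, lnc_in_net, assoc)
    # enrichment: specifically-expressed coding genes of one tissue vs all coding
    study = [
        g
        for g in coding_genes
        if g in profiles.index and profiles.loc[g, "tissue_class"] == TISSUES[0]
    ]
    enrichment = (
        network.go_enrichment(study, coding_genes, assoc) if study else []
    )
    if not (resume and net_done.exists()):
        pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "rho": e.rho,
                    "p_raw": e.p_raw,
                    "p_adj_a": e.p_adj_a,
                    "p_adj_b": e.p_adj_b,
                }
                for e in edges
                if e.kept
            ]
        ).to_csv(net_dir / "edges.tsv", sep="\t", index=False)
        type_counts.to_csv(net_dir / "edge_types.tsv", sep="\t", index=False)
        write_go_associations(assoc, net_dir / "go_associations.tsv")
        pd.DataFrame(
            [dataclasses.asdict(a) for a in annotations]
        ).to_csv(net_dir / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in enrichment]
        ).to_csv(net_dir / "enrichment.tsv", sep="\t", index=False)
        net_done.touch()
    log.info(
        "network: %d kept edges, %d lncRNA annotations",
        sum(e.kept for e in edges),
        len(annotations),
    )

    # -- stage 7: report ---------------------------------------------------
    rep_dir, _ = _stage(out, "report")
    per_species = {
        sp: {
            "collected": len(db_records[sp]),
            "unique": len(catalogues[sp]),
        }
        for sp in catalogues
    }
    cat_table = report.catalogue_summary(per_species)
    cat_table.to_csv(rep_dir / "catalogue_summary.tsv", sep="\t", index=False)
    cat_summary.to_csv(rep_dir / "category_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"species": sp, "conserved_pct": v} for sp, v in sorted(conserved_pct.items())]
    ).to_csv(rep_dir / "conserved_per_species.tsv", sep="\t", index=False)
    log.info("pipeline finished in %.1f s", time.time() - t0)

    return {
        "tree": tree,
        "truth": truth,
        "expression_truth": expr_truth,
        "go_truth": go_truth,
        "planted_go": planted_go,
        "catalogues": catalogues,
        "rejects": rejects,
        "families": families,
        "branch_counts": branch_counts,
        "conserved_pct": conserved_pct,
        "age_summary": age_summary,
        "labels": labels,
        "category_summary": cat_summary,
        "catalogue_summary": cat_table,
        "profiles": profiles,
        "edges": edges,
        "graph": graph,
        "annotations": annotations,
        "enrichment": enrichment,
        "elapsed_s": time.time() - t0,
    }
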