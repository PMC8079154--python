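"""MEGAN-style lowest-common-ancestor (LCA) taxonomic assignment.

Each gene's homology hits are filtered by score, E-value and a top-percent
band around the best hit, and the gene is then placed at the deepest
taxonomy node whose subtree accounts for at least ``lca_percent`` of the
retained hits' taxa.  Multiple hits to the same subject taxon count once,
so a single over-represented subject genome cannot dominate the vote.

Default parameters are the published MEGAN settings (Min Score 50, Max
Expected 1e-4, Top Percent 20, Min Support Percent 0.1, Min Support 1,
LCA percent 90).  MEGAN's Min Complexity pre-filter is a sequence-level
concern; this pipeline never sees sequences, so an optional per-query
low-complexity mask may be supplied and is otherwise logged as skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .core_io import (UNASSIGNED, GeneCatalog, HitTable, LcaConfig,
                      ScreenConfig, TaxonomyTree)

logger = logging.getLogger("kleptoscreen.lca")


@dataclass
class LcaAssignment:
    gene_id: str
    assigned_taxon_id: str  # a tree node or UNASSIGNED
    n_hits_retained: int
    support_fraction: float


@dataclass
class GeneContentCounts:
    """Per-scaffold counts of taxonomically classified genes."""
    n_bacterial: int = 0
    n_lophotrochozoan: int = 0
    n_other: int = 0

    def as_tuple(self):
        return (self.n_bacterial, self.n_lophotrochozoan, self.n_other)


def _lca_cfg(cfg) -> LcaConfig:
    return cfg.lca if isinstance(cfg, ScreenConfig) else cfg


def retain_hits(hits: HitTable, cfg) -> HitTable:
    """Filter one query's hits by Min Score, Max Expected and Top Percent.

    Top Percent applies to the bit score, measured against the best hit
    surviving the first two filters: a hit is kept when its bit score is at
    least ``(1 - top_percent/100)`` times the best retained bit score.
    """
    c = _lca_cfg(cfg)
    queries = {r.query_id for r in hits}
    if len(queries) > 1:
        raise ValueError(f"retain_hits expects hits of a single query, got {sorted(queries)}")
    survivors = [r for r in hits
                 if r.bit_score >= c.min_score and r.e_value <= c.max_expected]
    if not survivors:
        return HitTable()
    cutoff = (1.0 - c.top_percent / 100.0) * max(r.bit_score for r in survivors)
    return HitTable(r for r in survivors if r.bit_score >= cutoff)


def assign_lca(hits: HitTable, tree: TaxonomyTree, cfg) -> LcaAssignment:
    """Assign one gene to the deepest node supported by its retained hits.

    The assigned node is the deepest node whose subtree contains at least
    ``lca_percent/100`` of the retained hits' distinct taxa; equally deep
    qualifying nodes are resolved to their LCA, which makes the result
    independent of hit order.  A gene with no retained hits (or fewer than
    ``min_support``) is UNASSIGNED.
    """
    c = _lca_cfg(cfg)
    gene_id = hits[0].query_id if len(hits) else ""
    retained = retain_hits(hits, cfg) if len(hits) else HitTable()
    if len(retained) < max(c.min_support, 1):
        return LcaAssignment(gene_id, UNASSIGNED, len(retained), 0.0)
    taxa = {r.subject_taxon_id for r in retained}
    for t in taxa:
        if t not in tree:
            raise KeyError(f"hit taxon {t!r} absent from the taxonomy tree")
    n = len(taxa)
    need = c.lca_percent / 100.0
    # Candidate nodes are ancestors of hit taxa (support is 0 elsewhere).
    candidates: dict[str, int] = {}
    for t in taxa:
        for node in tree.path_to_root(t):
            candidates[node] = candidates.get(node, 0) + 1
    qualifying = [node for node, k in candidates.items() if k / n >= need]
    if not qualifying:
        return LcaAssignment(gene_id, UNASSIGNED, len(retained), 0.0)
    best_depth = max(tree.depth(q) for q in qualifying)
    deepest = [q for q in qualifying if tree.depth(q) == best_depth]
    node = deepest[0] if len(deepest) == 1 else tree.lca(deepest)
    return LcaAssignment(gene_id, node, len(retained), candidates[node] / n)


def lca_scan(
    hits: HitTable,
    tree: TaxonomyTree,
    cfg,
    gene_ids: Optional[Iterable[str]] = None,
    low_complexity: Optional[Mapping[str, bool]] = None,
) -> dict[str, LcaAssignment]:
    """Assign every gene in ``hits`` (plus optional hit-less ``gene_ids``).

    Min Support Percent is applied across the whole run, MEGAN-style: any
    taxon assigned fewer than ``min_support_percent`` % of all assigned
    genes has those genes demoted to UNASSIGNED.
    """
    c = _lca_cfg(cfg)
    if low_complexity is None:
        logger.debug("no low-complexity mask supplied; Min Complexity filter skipped")
        low_complexity = {}
    by_query = hits.by_query()
    all_ids = list(by_query)
    if gene_ids is not None:
        present = set(all_ids)
        all_ids += [g for g in gene_ids if g not in present]
    out: dict[str, LcaAssignment] = {}
    for gid in all_ids:
        if low_complexity.get(gid, False):
            out[gid] = LcaAssignment(gid, UNASSIGNED, 0, 0.0)
            continue
        gene_hits = by_query.get(gid, HitTable())
        if len(gene_hits) == 0:
            out[gid] = LcaAssignment(gid, UNASSIGNED, 0, 0.0)
        else:
            out[gid] = assign_lca(gene_hits, tree, cfg)
    # Run-level Min Support Percent, MEGAN-style: a gene assigned to a taxon
    # whose subtree holds fewer than min_support_percent % of all assigned
    # genes is pushed up to the nearest ancestor with enough support (the
    # root always qualifies, so no gene is lost to this rule).
    assigned = [a for a in out.values() if a.assigned_taxon_id != UNASSIGNED]
    if assigned and c.min_support_percent > 0:
        cumulative: dict[str, int] = {}
        for a in assigned:
            for node in tree.path_to_root(a.assigned_taxon_id):
                cumulative[node] = cumulative.get(node, 0) + 1
        floor = c.min_support_percent / 100.0 * len(assigned)
        for a in assigned:
            if cumulative[a.assigned_taxon_id] >= floor:
                continue
            for node in tree.path_to_root(a.assigned_taxon_id):
                if cumulative[node] >= floor:
                    logger.debug("pushing %s up from %s to %s (min support percent)",
                                 a.gene_id, a.assigned_taxon_id, node)
                    out[a.gene_id] = LcaAssignment(
                        a.gene_id, node, a.n_hits_retained, a.support_fraction)
                    break
    return out


def classify_scaffold_gene_content(
    assignments: Mapping[str, LcaAssignment],
    catalog: GeneCatalog,
    tree: TaxonomyTree,
) -> dict[str, GeneContentCounts]:
    """Count bacterial / lophotrochozoan / other genes per scaffold.

    A gene is bacterial when its assigned node lies within the prokaryote
    group's bacterial subtree (the ``bacteria`` group when the tree defines
    one, otherwise the whole prokaryote group); lophotrochozoan when within
    the lophotrochozoa group.  UNASSIGNED genes count toward nothing.
    """
    bacterial_group = "bacteria" if "bacteria" in tree.groups else "prokaryote"
    counts: dict[str, GeneContentCounts] = {}
    for gene in catalog:
        cc = counts.setdefault(gene.scaffold_id, GeneContentCounts())
        a = assignments.get(gene.gene_id)
        if a is None or a.assigned_taxon_id == UNASSIGNED:
            continue
        node = a.assigned_taxon_id
        if tree.in_group(node, bacterial_group):
            cc.n_bacterial += 1
        elif tree.in_group(node, "lophotrochozoa"):
            cc.n_lophotrochozoan += 1
        else:
            cc.n_other += 1
    return counts


def write_lca_table(assignments: Mapping[str, LcaAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tassigned_taxon_id\tn_hits_retained\tsupport_fraction\n")
        for a in assignments.values():
            fh.write(f"{a.gene_id}\t{a.assigned_taxon_id}\t{a.n_hits_retained}"
                     f"\t{repr(a.support_fraction)}\n")
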