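"""Alien-index style HGT screening from bit-score differences.

For each gene the *h-index* is the bit-score difference between its best
prokaryote and best eukaryote hits, and the *hA-index* is the difference
between its best algal and best lophotrochozoan (host) hits.  Under the
donor-minus-host convention a strongly positive index means the gene looks
far more like the donor lineage than the host, flagging it as an HGT
candidate; the conventional threshold magnitude is 100 bits.

A group with no hit contributes the configured ``missing_group_bits``
(default 0), the usual alien-index practice: a gene with only algal hits
then receives a large positive hA.  Indices are computed from the raw hit
table — no LCA-style pre-filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .core_io import HgtIndexConfig, HitTable, ScreenConfig, TaxonomyTree

GROUP_PAIRS = {
    "h": ("prokaryote", "eukaryote"),
    "hA": ("algae", "lophotrochozoa"),
}


@dataclass
class HgtIndexResult:
    gene_id: str
    best_bits: dict[str, float] = field(default_factory=dict)
    h_index: float = 0.0
    hA_index: float = 0.0
    h_candidate: bool = False
    hA_candidate: bool = False
    no_hits: bool = False


def _idx_cfg(cfg) -> HgtIndexConfig:
    return cfg.hgt_index if isinstance(cfg, ScreenConfig) else cfg


def best_bits_by_group(hits: HitTable, tree: TaxonomyTree, missing: float = 0.0) -> dict[str, float]:
    """Best bit score per taxonomic group (``missing`` where a group has no hit)."""
    groups = ("prokaryote", "eukaryote", "algae", "lophotrochozoa")
    best = {g: missing for g in groups}
    found = {g: False for g in groups}
    for r in hits:
        if r.subject_taxon_id not in tree:
            raise KeyError(f"hit taxon {r.subject_taxon_id!r} absent from the taxonomy tree")
        for g in groups:
            if tree.in_group(r.subject_taxon_id, g):
                if not found[g] or r.bit_score > best[g]:
                    best[g] = r.bit_score
                    found[g] = True
    return best


def compute_indices(hits: HitTable, tree: TaxonomyTree, cfg) -> HgtIndexResult:
    """Compute h and hA for one gene's hit table."""
    c = _idx_cfg(cfg)
    queries = {r.query_id for r in hits}
    if len(queries) > 1:
        raise ValueError(f"compute_indices expects a single query, got {sorted(queries)}")
    gene_id = hits[0].query_id if len(hits) else ""
    best = best_bits_by_group(hits, tree, c.missing_group_bits)
    sign = 1.0 if c.sign == "donor-host" else -1.0
    h = sign * (best["prokaryote"] - best["eukaryote"])
    hA = sign * (best["algae"] - best["lophotrochozoa"])
    return HgtIndexResult(
        gene_id=gene_id,
        best_bits=best,
        h_index=h,
        hA_index=hA,
        h_candidate=h >= c.threshold,
        hA_candidate=hA >= c.threshold,
        no_hits=len(hits) == 0,
    )


def index_scan(
    hits: HitTable,
    tree: TaxonomyTree,
    cfg,
    gene_ids=None,
) -> tuple[dict[str, HgtIndexResult], list[HgtIndexResult]]:
    """Compute indices for every gene; return (per-gene results, candidates).

    ``gene_ids`` optionally lists genes that must appear even without hits
    (reported with both indices at the missing-group value and flagged
    ``no_hits``).  The candidate list contains every gene whose hA index
    meets the threshold, sorted by hA descending (ties by gene id).
    """
    c = _idx_cfg(cfg)
    by_query = hits.by_query()
    all_ids = list(by_query)
    if gene_ids is not None:
        present = set(all_ids)
        all_ids += [g for g in gene_ids if g not in present]
    results: dict[str, HgtIndexResult] = {}
    for gid in all_ids:
        gene_hits = by_query.get(gid)
        if gene_hits is None or len(gene_hits) == 0:
            results[gid] = HgtIndexResult(gene_id=gid, best_bits={}, no_hits=True)
        else:
            results[gid] = compute_indices(gene_hits, tree, cfg)
    candidates = sorted(
        (r for r in results.values() if r.hA_candidate),
        key=lambda r: (-r.hA_index, r.gene_id))
    return results, candidates


def write_index_table(results: Mapping[str, HgtIndexResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\th_index\thA_index\th_candidate\thA_candidate\tno_hits\n")
        for r in results.values():
            fh.write(f"{r.gene_id}\t{repr(r.h_index)}\t{repr(r.hA_index)}"
                     f"\t{int(r.h_candidate)}\t{int(r.hA_candidate)}\t{int(r.no_hits)}\n")
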