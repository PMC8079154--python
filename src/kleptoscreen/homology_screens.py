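"""Genome-level and read-level homology screens.

The genome-level screen decides whether an algal query has a *credible*
locus in the host assembly: a hit must cover more than 60% of the query
and carry a normalised alignment score (raw alignment score divided by
aligned length, in bp) above 2.  A companion tblastn-style screen accepts
hits below E-value 1e-4 (strict).

The read-level screen compares length-normalised read-hit counts (TPM) of
an algal query set against host single-copy control genes with Welch's
t-test; individual algal queries whose TPM exceeds a flag threshold are
annotated for follow-up, and can be explained away when most of their
reads also hit a host homolog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core_io import (AlignScreenConfig, HitRecord, HitTable,
                      ReadScreenConfig, ScreenConfig)
from .physiology_stats import WelchResult, welch_t_test


@dataclass
class AlignmentVerdict:
    query_id: str
    n_hits_total: int
    n_hits_credible: int
    best_hit: Optional[HitRecord]
    credible: bool


@dataclass
class NormalizedCount:
    query_id: str
    query_length: int
    raw_reads: int
    tpm: float


@dataclass
class ReadScreenResult:
    welch: WelchResult
    flagged_queries: list[str]


def _align_cfg(cfg) -> AlignScreenConfig:
    return cfg.align_screen if isinstance(cfg, ScreenConfig) else cfg


def _read_cfg(cfg) -> ReadScreenConfig:
    return cfg.read_screen if isinstance(cfg, ScreenConfig) else cfg


def _hit_is_credible(r: HitRecord, c: AlignScreenConfig) -> bool:
    if r.raw_score is None:
        raise ValueError(
            f"hit {r.query_id}->{r.subject_id}: raw alignment score absent; "
            "the alignment screen needs a raw-score-bearing dialect")
    coverage = r.query_coverage
    norm_score = r.raw_score / r.alignment_length
    return coverage > c.min_query_coverage and norm_score > c.min_norm_score


def screen_alignment_hits(hits: HitTable, cfg,
                          query_ids: Optional[Iterable[str]] = None) -> dict[str, AlignmentVerdict]:
    """Coverage + normalised-score credibility screen, one verdict per query.

    Both thresholds are strict: coverage must exceed ``min_query_coverage``
    and raw_score/alignment_length must exceed ``min_norm_score``.
    """
    c = _align_cfg(cfg)
    by_query = hits.by_query()
    all_ids = list(by_query)
    if query_ids is not None:
        present = set(all_ids)
        all_ids += [q for q in query_ids if q not in present]
    out: dict[str, AlignmentVerdict] = {}
    for qid in all_ids:
        qhits = by_query.get(qid, HitTable())
        credible_hits = [r for r in qhits if _hit_is_credible(r, c)]
        best = max(credible_hits, key=lambda r: r.bit_score, default=None)
        out[qid] = AlignmentVerdict(
            query_id=qid,
            n_hits_total=len(qhits),
            n_hits_credible=len(credible_hits),
            best_hit=best,
            credible=len(credible_hits) >= 1,
        )
    return out


def screen_tblastn_hits(hits: HitTable, cfg,
                        query_ids: Optional[Iterable[str]] = None) -> dict[str, AlignmentVerdict]:
    """E-value-only reliability screen: a hit is credible iff E < max_evalue (strict)."""
    c = _align_cfg(cfg)
    by_query = hits.by_query()
    all_ids = list(by_query)
    if query_ids is not None:
        present = set(all_ids)
        all_ids += [q for q in query_ids if q not in present]
    out: dict[str, AlignmentVerdict] = {}
    for qid in all_ids:
        qhits = by_query.get(qid, HitTable())
        credible_hits = [r for r in qhits if r.e_value < c.max_evalue]
        best = max(credible_hits, key=lambda r: r.bit_score, default=None)
        out[qid] = AlignmentVerdict(
            query_id=qid,
            n_hits_total=len(qhits),
            n_hits_credible=len(credible_hits),
            best_hit=best,
            credible=len(credible_hits) >= 1,
        )
    return out


def compute_tpm(
    read_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library_total_reads: Optional[float] = None,
) -> list[NormalizedCount]:
    """Transcripts-per-kilobase-million normalisation of read-hit counts.

    The default denominator is the query universe itself (the keys of
    ``read_counts``): rate_q = count_q / (length_q/1000) and
    tpm_q = rate_q / sum(rates) * 1e6, so TPMs sum to 1e6 whenever any read
    maps.  When ``library_total_reads`` is given, the per-million factor is
    the total library size instead (tpm_q = rate_q / (library_total/1e6)),
    the scale on which per-query counts are comparable across libraries.
    """
    rates: dict[str, float] = {}
    for qid, count in read_counts.items():
        if qid not in lengths:
            raise KeyError(f"no length for query {qid!r}")
        length = lengths[qid]
        if length <= 0:
            raise ValueError(f"query {qid!r} has non-positive length {length}")
        if count < 0:
            raise ValueError(f"query {qid!r} has negative read count {count}")
        rates[qid] = count / (length / 1000.0)
    if library_total_reads is not None:
        if library_total_reads <= 0:
            raise ValueError("library_total_reads must be positive")
        denom = library_total_reads / 1e6
        return [NormalizedCount(q, lengths[q], read_counts[q], rates[q] / denom)
                for q in read_counts]
    total = sum(rates.values())
    if total == 0.0:
        return [NormalizedCount(q, lengths[q], read_counts[q], 0.0)
                for q in read_counts]
    return [NormalizedCount(q, lengths[q], read_counts[q], rates[q] / total * 1e6)
            for q in read_counts]


def compare_read_sets(
    set_a: Sequence[NormalizedCount],
    set_control: Sequence[NormalizedCount],
    cfg,
) -> ReadScreenResult:
    """Welch-compare TPMs of a target query set against a control set.

    Queries of ``set_a`` whose TPM exceeds ``flag_tpm`` (strict >) are
    listed in ``flagged_queries``; flagging is an annotation for host-
    homolog follow-up, never an automatic HGT call.
    """
    c = _read_cfg(cfg)
    if len(set_a) < 2 or len(set_control) < 2:
        raise ValueError("each read set needs at least 2 queries for a variance")
    a = [nc.tpm for nc in set_a]
    b = [nc.tpm for nc in set_control]
    welch = welch_t_test(a, b)
    flagged = [nc.query_id for nc in set_a if nc.tpm > c.flag_tpm]
    return ReadScreenResult(welch=welch, flagged_queries=flagged)


def resolve_flagged_by_host_homolog(
    reads_hitting_query: Iterable[str],
    host_hits: HitTable,
    min_shared_fraction: float = 0.5,
) -> str:
    """Explain a flagged query by a host homolog sharing its reads.

    ``reads_hitting_query`` are read ids matching the flagged query;
    ``host_hits`` is a read-vs-host-gene hit table (query ids are read
    ids).  The query is ``host_homolog_explained`` when the fraction of its
    reads that also hit at least one host gene exceeds
    ``min_shared_fraction`` (strict >), else ``unexplained``.
    """
    reads = set(reads_hitting_query)
    if not reads:
        return "unexplained"
    host_read_ids = {r.query_id for r in host_hits}
    shared = len(reads & host_read_ids) / len(reads)
    return "host_homolog_explained" if shared > min_shared_fraction else "unexplained"


def write_verdict_table(verdicts: Mapping[str, AlignmentVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tn_hits_total\tn_hits_credible\tcredible\tbest_bit_score\n")
        for v in verdicts.values():
            best = repr(v.best_hit.bit_score) if v.best_hit is not None else "NA"
            fh.write(f"{v.query_id}\t{v.n_hits_total}\t{v.n_hits_credible}"
                     f"\t{int(v.credible)}\t{best}\n")
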