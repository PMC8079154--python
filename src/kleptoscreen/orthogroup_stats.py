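"""Orthogroup expansion Z-scores and Fisher-exact enrichment.

Lineage-specific gene-family expansion is scored per orthogroup as the
Z-score of the focal species' gene count against the count distribution
over all species (sample SD, n-1 denominator); an orthogroup is called
expanded when Z exceeds the threshold (strict >, default 2).

Enrichment of up-regulated genes within an orthogroup is tested with
Fisher's exact test on the 2x2 table (up-in-group, up-elsewhere,
not-up-in-group, not-up-elsewhere) against a configurable gene-model
background.  The implementation delegates to
:func:`scipy.stats.fisher_exact`; the two-sided p is the point-probability
(minimum-likelihood) sum, the common statistical-package convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DEGTable, ExpansionConfig, ScreenConfig, ValidationError

logger = logging.getLogger("kleptoscreen.orthogroups")


@dataclass
class ExpansionResult:
    orthogroup_id: str
    focal_species: str
    z: float
    expanded: bool


@dataclass
class EnrichmentResult:
    orthogroup_id: str
    k_up_in_group: int
    n_group: int
    K_up_total: int
    N_total: int
    odds_ratio: float
    p_value: float
    contains_up: bool = False
    enriched: bool = False


def _cfg(cfg) -> ExpansionConfig:
    return cfg.expansion if isinstance(cfg, ScreenConfig) else cfg


def expansion_zscore(matrix: pd.DataFrame, focal_species: str, cfg) -> list[ExpansionResult]:
    """Z-score of the focal species' gene count per orthogroup.

    The mean and sample SD are taken over all species columns (including
    the focal one by default; set ``include_focal=False`` to leave it
    out).  Rows with zero SD get z = 0 and are never called expanded.
    """
    c = _cfg(cfg)
    if focal_species not in matrix.columns:
        raise KeyError(f"focal species {focal_species!r} absent from the count matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 species columns for a Z-score")
    if c.include_focal:
        ref = matrix
    else:
        ref = matrix.drop(columns=[focal_species])
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    focal = matrix[focal_species].astype(float)
    out: list[ExpansionResult] = []
    for og in matrix.index:
        s = sd.loc[og]
        z = 0.0 if s == 0.0 else float((focal.loc[og] - mean.loc[og]) / s)
        out.append(ExpansionResult(
            orthogroup_id=str(og),
            focal_species=focal_species,
            z=z,
            expanded=bool(s > 0.0 and z > c.z_threshold),
        ))
    return out


def fisher_enrichment(
    k_up_in_group: int,
    n_group: int,
    K_up_total: int,
    N_total: int,
    sided: str = "two-sided",
    orthogroup_id: str = "",
) -> EnrichmentResult:
    """Fisher's exact test for enrichment of up-regulated genes in a group.

    2x2 table: a = up in group, b = up outside, c = not-up in group,
    d = not-up outside; margins fixed at (n_group, K_up_total, N_total).
    ``sided`` is "two-sided" (point-probability method) or "greater"
    (one-sided enrichment).  The odds ratio is the sample odds ratio
    a*d/(b*c), with infinity allowed.
    """
    a = k_up_in_group
    b = K_up_total - k_up_in_group
    c = n_group - k_up_in_group
    d = N_total - n_group - b
    if min(a, b, c, d) < 0 or n_group > N_total or K_up_total > N_total:
        raise ValidationError(
            f"impossible 2x2 table: k={k_up_in_group}, n_group={n_group}, "
            f"K_up_total={K_up_total}, N_total={N_total}")
    alternative = {"two-sided": "two-sided", "greater": "greater"}[sided]
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = math.inf if b * c == 0 and a * d > 0 else (
        a * d / (b * c) if b * c else math.nan if a * d == 0 else math.inf)
    return EnrichmentResult(
        orthogroup_id=orthogroup_id,
        k_up_in_group=a, n_group=n_group,
        K_up_total=K_up_total, N_total=N_total,
        odds_ratio=float(odds) if not math.isinf(odds) else math.inf,
        p_value=float(min(p, 1.0)),
    )


def enrichment_scan(
    matrix: pd.DataFrame,
    membership: Mapping[str, str],
    deg_table: DEGTable,
    expansion_results: list[ExpansionResult],
    cfg,
    focal_species: Optional[str] = None,
    background_n: Optional[int] = None,
) -> list[EnrichmentResult]:
    """Test every expanded orthogroup for enrichment of up-regulated genes.

    ``membership`` maps focal-species gene ids to orthogroup ids.  The
    group size n_group is the number of member genes of the orthogroup;
    the background N defaults to the total number of genes in
    ``membership`` (override with ``background_n``, e.g. all gene models).
    Genes in the DEG table absent from the membership are warned about and
    excluded.
    """
    c = _cfg(cfg)
    up_genes = deg_table.up_genes()
    unknown = up_genes - set(membership)
    if unknown:
        logger.warning("%d up-regulated genes absent from orthogroup membership; excluded",
                       len(unknown))
        up_genes = up_genes & set(membership)
    genes_by_og: dict[str, set[str]] = {}
    for gene, og in membership.items():
        genes_by_og.setdefault(og, set()).add(gene)
    N = background_n if background_n is not None else len(membership)
    K = len(up_genes)
    out: list[EnrichmentResult] = []
    for er in expansion_results:
        if not er.expanded:
            continue
        members = genes_by_og.get(er.orthogroup_id, set())
        k = len(members & up_genes)
        res = fisher_enrichment(k, len(members), K, N, sided=c.sided,
                                orthogroup_id=er.orthogroup_id)
        res.contains_up = k >= 1
        res.enriched = res.p_value < c.enrichment_alpha
        out.append(res)
    return out


def write_expansion_table(results: list[ExpansionResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tfocal_species\tz\texpanded\n")
        for r in results:
            fh.write(f"{r.orthogroup_id}\t{r.focal_species}\t{repr(r.z)}\t{int(r.expanded)}\n")


def write_enrichment_table(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tk_up_in_group\tn_group\tK_up_total\tN_total"
                 "\todds_ratio\tp_value\tcontains_up\tenriched\n")
        for r in results:
            fh.write(f"{r.orthogroup_id}\t{r.k_up_in_group}\t{r.n_group}"
                     f"\t{r.K_up_total}\t{r.N_total}\t{repr(r.odds_ratio)}"
                     f"\t{repr(r.p_value)}\t{int(r.contains_up)}\t{int(r.enriched)}\n")
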