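"""Assembly decontamination by gene content and coverage depth.

Two removal rules, both deliberately conservative so that horizontally
transferred genes on genuine nuclear scaffolds are never discarded:

* **bacterial contaminant** — a scaffold encoding two or more bacterial
  genes and not a single lophotrochozoan gene;
* **organelle-derived** — a scaffold whose best hit against an organelle
  reference (kleptoplast or mitochondrial DNA) scores above 1000 bits
  *and* whose read depth is at least ``organelle_min_depth_fold`` times
  the nuclear mean (computed two-pass, excluding bit-score-flagged
  scaffolds so organelle depths cannot inflate the baseline).  A bit-score
  pass without depth corroboration is reported as *ambiguous* and kept.

An orthogonal corroboration flag checks whether a scaffold's depth rises
two- to four-fold in a kleptoplast-rich tissue library relative to a
kleptoplast-poor one, the signature of kleptoplast DNA; library depths are
median-normalised first since raw library sizes differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core_io import DecontamConfig, HitTable, Scaffold, ScaffoldSet, ScreenConfig
from .taxonomy_lca import GeneContentCounts

logger = logging.getLogger("kleptoscreen.decontam")

NUCLEAR = "nuclear"
BACTERIAL = "bacterial_contaminant"
ORGANELLE = "organelle"
AMBIGUOUS = "ambiguous"


@dataclass
class ScaffoldVerdict:
    scaffold_id: str
    label: str
    n_bacterial_genes: int = 0
    n_loph_genes: int = 0
    best_organelle_bitscore: float = 0.0
    depth_fold_vs_nuclear_mean: Optional[float] = None
    tissue_depth_ratio: Optional[float] = None
    tissue_flag: Optional[str] = None


def _cfg(cfg) -> DecontamConfig:
    return cfg.decontam if isinstance(cfg, ScreenConfig) else cfg


def classify_bacterial(counts: GeneContentCounts, cfg) -> bool:
    """True iff the scaffold has >= min bacterial genes and <= max host genes."""
    c = _cfg(cfg)
    return (counts.n_bacterial >= c.min_bacterial_genes
            and counts.n_lophotrochozoan <= c.max_loph_genes)


def best_organelle_bitscores(organelle_hits: HitTable) -> dict[str, float]:
    """Best bit score per scaffold from a scaffold-vs-organelle-reference hit table."""
    best: dict[str, float] = {}
    for r in organelle_hits:
        if r.query_id not in best or r.bit_score > best[r.query_id]:
            best[r.query_id] = r.bit_score
    return best


def nuclear_mean_depth(scaffolds: ScaffoldSet,
                       bit_flagged: set[str]) -> Optional[float]:
    """Mean depth (over libraries and scaffolds) of non-bit-flagged scaffolds."""
    vals = [s.mean_depth() for s in scaffolds
            if s.scaffold_id not in bit_flagged and s.depth]
    return float(np.mean(vals)) if vals else None


def classify_organelle(
    scaffold: Scaffold,
    best_bitscore: float,
    nuclear_mean: Optional[float],
    cfg,
) -> tuple[str, Optional[float]]:
    """Organelle call for one scaffold: (label, depth fold vs nuclear mean).

    The bit-score rule is strict (> organelle_min_bitscore).  With depth
    data, the depth fold must also reach ``organelle_min_depth_fold``; a
    bit-score pass that fails the depth rule is ambiguous.  Without depth
    data the call falls back to bit-score-only mode with a warning.
    """
    c = _cfg(cfg)
    if not best_bitscore > c.organelle_min_bitscore:
        return NUCLEAR, None
    if nuclear_mean is None or not scaffold.depth or nuclear_mean == 0.0:
        logger.warning("scaffold %s: no depth data; organelle call from bit score only",
                       scaffold.scaffold_id)
        return ORGANELLE, None
    fold = scaffold.mean_depth() / nuclear_mean
    if fold >= c.organelle_min_depth_fold:
        return ORGANELLE, fold
    return AMBIGUOUS, fold


def tissue_ratio_check(
    depth_rich: float,
    depth_poor: float,
    rich_norm: float,
    poor_norm: float,
    cfg,
) -> tuple[Optional[float], Optional[str]]:
    """Kleptoplast corroboration from a rich/poor tissue depth ratio.

    Depths are normalised by their library's median before the ratio;
    the flag is ``consistent_with_kleptoplast`` when the normalised ratio
    lies in the closed interval [tissue_ratio_min, tissue_ratio_max].
    """
    c = _cfg(cfg)
    if poor_norm <= 0 or rich_norm <= 0:
        raise ValueError("library normalisation factors must be positive")
    if depth_poor <= 0:
        return None, None  # undefined ratio
    ratio = (depth_rich / rich_norm) / (depth_poor / poor_norm)
    if c.tissue_ratio_min <= ratio <= c.tissue_ratio_max:
        return ratio, "consistent_with_kleptoplast"
    return ratio, "not_consistent"


def classify_scaffolds(
    scaffolds: ScaffoldSet,
    gene_content: Mapping[str, GeneContentCounts],
    organelle_hits: HitTable,
    cfg,
    rich_library: Optional[str] = None,
    poor_library: Optional[str] = None,
) -> dict[str, ScaffoldVerdict]:
    """Full per-scaffold classification (bacterial > organelle > ambiguous > nuclear)."""
    c = _cfg(cfg)
    best_bits = best_organelle_bitscores(organelle_hits)
    bit_flagged = {sid for sid, b in best_bits.items() if b > c.organelle_min_bitscore}
    nuc_mean = nuclear_mean_depth(scaffolds, bit_flagged)
    # Library median normalisation for the tissue-ratio corroboration.
    rich_norm = poor_norm = None
    if rich_library is not None and poor_library is not None:
        rich_vals = [s.depth[rich_library] for s in scaffolds if rich_library in s.depth]
        poor_vals = [s.depth[poor_library] for s in scaffolds if poor_library in s.depth]
        if rich_vals and poor_vals:
            rich_norm = float(np.median(rich_vals))
            poor_norm = float(np.median(poor_vals))
    verdicts: dict[str, ScaffoldVerdict] = {}
    for s in scaffolds:
        counts = gene_content.get(s.scaffold_id, GeneContentCounts())
        v = ScaffoldVerdict(
            scaffold_id=s.scaffold_id,
            label=NUCLEAR,
            n_bacterial_genes=counts.n_bacterial,
            n_loph_genes=counts.n_lophotrochozoan,
            best_organelle_bitscore=best_bits.get(s.scaffold_id, 0.0),
        )
        if classify_bacterial(counts, cfg):
            v.label = BACTERIAL
        else:
            label, fold = classify_organelle(
                s, v.best_organelle_bitscore, nuc_mean, cfg)
            v.label = label
            v.depth_fold_vs_nuclear_mean = fold
            if (label in (ORGANELLE, AMBIGUOUS) and rich_norm and poor_norm
                    and rich_library in s.depth and poor_library in s.depth):
                ratio, flag = tissue_ratio_check(
                    s.depth[rich_library], s.depth[poor_library],
                    rich_norm, poor_norm, cfg)
                v.tissue_depth_ratio = ratio
                v.tissue_flag = flag
        verdicts[s.scaffold_id] = v
    return verdicts


def decontaminate(
    scaffolds: ScaffoldSet,
    verdicts: Mapping[str, ScaffoldVerdict],
) -> tuple[ScaffoldSet, ScaffoldSet, list[ScaffoldVerdict]]:
    """Split the assembly into retained and removed scaffolds.

    Only ``bacterial_contaminant`` and ``organelle`` labels are removed;
    ambiguous scaffolds are retained and listed in the report alongside
    every removal, with the evidence that produced each label.
    """
    retained, removed = ScaffoldSet(), ScaffoldSet()
    report: list[ScaffoldVerdict] = []
    for s in scaffolds:
        v = verdicts.get(s.scaffold_id)
        if v is None:
            raise KeyError(f"no verdict for scaffold {s.scaffold_id!r}")
        if v.label in (BACTERIAL, ORGANELLE):
            removed.add(s)
            report.append(v)
        else:
            retained.add(s)
            if v.label == AMBIGUOUS:
                report.append(v)
    return retained, removed, report


def write_verdict_report(verdicts: Mapping[str, ScaffoldVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tlabel\tn_bacterial_genes\tn_loph_genes"
                 "\tbest_organelle_bitscore\tdepth_fold\ttissue_ratio\ttissue_flag\n")
        for v in verdicts.values():
            fold = repr(v.depth_fold_vs_nuclear_mean) if v.depth_fold_vs_nuclear_mean is not None else "NA"
            ratio = repr(v.tissue_depth_ratio) if v.tissue_depth_ratio is not None else "NA"
            fh.write(f"{v.scaffold_id}\t{v.label}\t{v.n_bacterial_genes}"
                     f"\t{v.n_loph_genes}\t{repr(v.best_organelle_bitscore)}"
                     f"\t{fold}\t{ratio}\t{v.tissue_flag or 'NA'}\n")
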