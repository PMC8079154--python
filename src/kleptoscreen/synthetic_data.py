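"""Fully-labelled synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the screens assume, with
planted ground truth so recovery can be measured exactly:

* a host genome of nuclear scaffolds carrying genes of lophotrochozoan
  affinity, with a configurable number of planted algal-HGT genes placed
  *among* host genes (so decontamination must not remove them), bacterial
  contaminant scaffolds, and organelle-derived scaffolds;
* hit tables whose bit scores reflect donor affinity, synthesised from a
  raw-score model through the Karlin-Altschul conversion
  bits = (lambda*S - ln K)/ln 2;
* read-hit counts with the "rare algal reads vs abundant host single-copy
  reads" structure (negative-binomial, strongly overdispersed);
* per-scaffold depths for a kleptoplast-rich and a kleptoplast-poor
  library, with organelle scaffolds elevated and tissue-ratio structure;
* orthogroup count matrices with planted focal expansions and a DEG table
  with planted enrichment.

Every generator is fully deterministic under a fixed seed.  Sequences, when
requested, are random nucleotides — no stage reads sequence content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import (GeneCatalog, GeneModel, HitRecord, HitTable, Scaffold,
                      ScaffoldSet, TaxonomyTree, DEGRecord, DEGTable)

import pandas as pd

HOST = "host"
ALGAL_HGT = "algal_hgt"
BACTERIAL = "bacterial"
ORGANELLE_ORIGIN = "organelle"


# ---------------------------------------------------------------------------
# Truth labels
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Immutable-by-convention ground-truth labels of a simulated dataset."""
    gene_origin: dict[str, str] = field(default_factory=dict)
    scaffold_label: dict[str, str] = field(default_factory=dict)
    planted_expanded: set[str] = field(default_factory=set)
    planted_enriched: set[str] = field(default_factory=set)

    def genes_with_origin(self, origin: str) -> set[str]:
        return {g for g, o in self.gene_origin.items() if o == origin}

    def scaffolds_with_label(self, label: str) -> set[str]:
        return {s for s, l in self.scaffold_label.items() if l == label}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for g, o in self.gene_origin.items():
                fh.write(f"gene\t{g}\t{o}\n")
            for s, l in self.scaffold_label.items():
                fh.write(f"scaffold\t{s}\t{l}\n")
            for og in sorted(self.planted_expanded):
                fh.write(f"orthogroup\t{og}\texpanded\n")
            for og in sorted(self.planted_enriched):
                fh.write(f"orthogroup\t{og}\tenriched\n")


# ---------------------------------------------------------------------------
# Score model
# ---------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """Karlin-Altschul-style synthesis of bit scores from raw scores.

    ``lambda_`` and ``k_`` are the classic protein-search constants; the
    conversion bits = (lambda*S_raw - ln k_)/ln 2 is monotone in S_raw.
    A perfectly conserved alignment contributes
    ``bits_per_identical_residue`` bits per residue, scaled down by
    ``divergence_decay`` for realistic between-species divergence, plus
    Gaussian noise of SD ``noise_sd`` bits.
    """
    lambda_: float = 0.267
    k_: float = 0.041
    bits_per_identical_residue: float = 2.0
    divergence_decay: float = 0.9
    noise_sd: float = 25.0

    def validate(self) -> "ScoreModel":
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("lambda_ and k_ must be positive")
        if self.bits_per_identical_residue <= 0:
            raise ValueError("bits_per_identical_residue must be positive")
        if not 0 < self.divergence_decay <= 1:
            raise ValueError("divergence_decay must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return self

    def bits_from_raw(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k_)) / math.log(2.0)

    def raw_from_bits(self, bits: float) -> float:
        return (bits * math.log(2.0) + math.log(self.k_)) / self.lambda_


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

_SKELETON = [
    # (taxon_id, parent_id, name, groups seeded here)
    ("root", None, "cellular organisms", ()),
    ("Bacteria", "root", "Bacteria", ("prokaryote", "bacteria")),
    ("Eukaryota", "root", "Eukaryota", ("eukaryote",)),
    ("Viridiplantae", "Eukaryota", "green algae", ("algae",)),
    ("Opisthokonta", "Eukaryota", "Opisthokonta", ()),
    ("Metazoa", "Opisthokonta", "Metazoa", ()),
    ("Lophotrochozoa", "Metazoa", "Lophotrochozoa", ("lophotrochozoa",)),
    ("Mollusca", "Lophotrochozoa", "Mollusca", ()),
]


def simulate_taxonomy(n_taxa: int = 24, seed: int = 0) -> TaxonomyTree:
    """Random rooted taxonomy with the four required groups populated.

    A fixed 8-node skeleton (root, Bacteria, Eukaryota, Viridiplantae,
    Opisthokonta, Metazoa, Lophotrochozoa, Mollusca) is padded with random
    leaf taxa; the first three extra leaves guarantee at least one leaf in
    each donor/host group.
    """
    if n_taxa < 8:
        raise ValueError("n_taxa must be >= 8 (the skeleton size)")
    rng = np.random.default_rng(seed)
    parents: dict[str, Optional[str]] = {}
    names: dict[str, str] = {}
    groups: dict[str, set[str]] = {}
    for tid, parent, name, seeds in _SKELETON:
        parents[tid] = parent
        names[tid] = name
        for g in seeds:
            groups.setdefault(g, set()).add(tid)
    anchors = ["Bacteria", "Viridiplantae", "Mollusca"]
    attach_pool = ["Bacteria", "Viridiplantae", "Mollusca", "Lophotrochozoa",
                   "Opisthokonta", "Eukaryota", "Metazoa"]
    extra = n_taxa - len(_SKELETON)
    existing = list(parents)
    for i in range(extra):
        tid = f"t{i + 1:03d}"
        if i < len(anchors):
            parent = anchors[i]
        else:
            # Attach under a random existing node, weighted toward the pool
            # so the groups stay well populated.
            if rng.random() < 0.7:
                parent = attach_pool[rng.integers(len(attach_pool))]
            else:
                parent = existing[rng.integers(len(existing))]
        parents[tid] = parent
        names[tid] = f"taxon {tid}"
        existing.append(tid)
    return TaxonomyTree(parents, names, groups)


def group_leaf_taxa(tree: TaxonomyTree, group: str) -> list[str]:
    """Taxa of ``group``, preferring leaves (hit subjects are species-like)."""
    members = sorted(tree.group_taxa(group))
    leaves = [t for t in members if not tree.children(t)]
    return leaves if leaves else members


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SimGenomeConfig:
    """Shape of the synthetic assembly.

    Defaults give ~2,000+ host genes on 100 nuclear scaffolds with 20
    planted algal-HGT genes, 3 bacterial contaminant scaffolds and 2
    organelle scaffolds — a desk-scale miniature of a decontaminated
    mollusk assembly.
    """
    n_host_scaffolds: int = 100
    genes_per_scaffold: int = 21
    n_hgt: int = 20
    n_contaminant_scaffolds: int = 3
    genes_per_contaminant: int = 3
    n_organelle_scaffolds: int = 2
    min_gene_codons: int = 300
    max_gene_codons: int = 1000
    min_spacer_bp: int = 200
    max_spacer_bp: int = 1000
    organelle_scaffold_bp: int = 100_000
    with_sequence: bool = False


def _random_gene_span(rng, cfg: SimGenomeConfig, cursor: int) -> tuple[int, int, int]:
    codons = int(rng.integers(cfg.min_gene_codons, cfg.max_gene_codons + 1))
    spacer = int(rng.integers(cfg.min_spacer_bp, cfg.max_spacer_bp + 1))
    start = cursor + spacer
    end = start + codons * 3
    return start, end, end


def simulate_genome(cfg: SimGenomeConfig = SimGenomeConfig(),
                    seed: int = 0) -> tuple[ScaffoldSet, GeneCatalog, TruthTable]:
    """Simulate scaffolds + gene catalog + truth labels.

    Planted HGT genes occupy random gene slots on nuclear scaffolds among
    host genes; contaminant scaffolds carry only bacterial-origin genes;
    organelle scaffolds carry no gene models.
    """
    rng = np.random.default_rng(seed)
    total_slots = cfg.n_host_scaffolds * cfg.genes_per_scaffold
    if cfg.n_hgt > total_slots:
        raise ValueError(
            f"n_hgt={cfg.n_hgt} exceeds the {total_slots} nuclear gene slots")
    scaffolds = ScaffoldSet()
    catalog = GeneCatalog()
    truth = TruthTable()
    hgt_slots = set(rng.choice(total_slots, size=cfg.n_hgt, replace=False).tolist())
    slot = 0
    gene_no = 0
    for si in range(cfg.n_host_scaffolds):
        sid = f"scaf{si + 1:04d}"
        cursor = 0
        for _ in range(cfg.genes_per_scaffold):
            gene_no += 1
            gid = f"g{gene_no:06d}"
            start, end, cursor = _random_gene_span(rng, cfg, cursor)
            strand = "+" if rng.random() < 0.5 else "-"
            catalog.add(GeneModel(gid, sid, start, end, strand))
            truth.gene_origin[gid] = ALGAL_HGT if slot in hgt_slots else HOST
            slot += 1
        length = cursor + int(rng.integers(cfg.min_spacer_bp, cfg.max_spacer_bp + 1))
        scaffolds.add(_make_scaffold(sid, length, cfg, rng))
        truth.scaffold_label[sid] = "nuclear"
    for ci in range(cfg.n_contaminant_scaffolds):
        sid = f"ctg_bact{ci + 1:02d}"
        cursor = 0
        for _ in range(cfg.genes_per_contaminant):
            gene_no += 1
            gid = f"g{gene_no:06d}"
            start, end, cursor = _random_gene_span(rng, cfg, cursor)
            catalog.add(GeneModel(gid, sid, start, end, "+"))
            truth.gene_origin[gid] = BACTERIAL
        length = cursor + int(rng.integers(cfg.min_spacer_bp, cfg.max_spacer_bp + 1))
        scaffolds.add(_make_scaffold(sid, length, cfg, rng))
        truth.scaffold_label[sid] = "bacterial_contaminant"
    for oi in range(cfg.n_organelle_scaffolds):
        sid = f"ctg_org{oi + 1:02d}"
        scaffolds.add(_make_scaffold(sid, cfg.organelle_scaffold_bp, cfg, rng))
        truth.scaffold_label[sid] = "organelle"
    catalog.validate_against(scaffolds)
    return scaffolds, catalog, truth


def _make_scaffold(sid: str, length: int, cfg: SimGenomeConfig, rng) -> Scaffold:
    seq = None
    if cfg.with_sequence:
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return Scaffold(sid, length, sequence=seq)


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

_ORIGIN_GROUP = {HOST: "lophotrochozoa", ALGAL_HGT: "algae", BACTERIAL: "bacteria"}
#: Opposing group whose best hit sits ``margin`` bits below the self-score.
#: Bacterial genes' eukaryote decoys must avoid the algae and host subtrees,
#: otherwise a contaminant gene would fake an hA signal.
_CROSS_GROUP = {HOST: "algae", ALGAL_HGT: "lophotrochozoa", BACTERIAL: "eukaryote_other"}


def simulate_hit_table(
    catalog: GeneCatalog,
    truth: TruthTable,
    tree: TaxonomyTree,
    score_model: ScoreModel = ScoreModel(),
    seed: int = 0,
    margin: float = 400.0,
    n_same_group_hits: int = 3,
) -> HitTable:
    """Simulate a protein-level hit table whose bit scores track gene origin.

    Each gene hits ``n_same_group_hits`` taxa of its true-origin group near
    its full self-score (gene length x bits-per-residue x divergence
    decay) and one taxon of the opposing group ``margin`` bits lower, plus
    Gaussian noise.  Planted HGT genes therefore carry hA >= margin (minus
    noise) while host genes carry hA <= -margin; bacterial genes show the
    same structure on the h axis.  Bit scores are realised through the raw
    score model so raw and bit columns stay mutually consistent.
    """
    score_model.validate()
    rng = np.random.default_rng(seed)
    group_taxa = {g: group_leaf_taxa(tree, g) for g in
                  ("bacteria" if "bacteria" in tree.groups else "prokaryote",
                   "lophotrochozoa", "algae")}
    if "bacteria" not in group_taxa:
        group_taxa["bacteria"] = group_taxa["prokaryote"]
    donor_host = tree.group_taxa("algae") | tree.group_taxa("lophotrochozoa")
    euk_other = [t for t in group_leaf_taxa(tree, "eukaryote") if t not in donor_host]
    group_taxa["eukaryote_other"] = euk_other or ["Eukaryota"]
    table = HitTable()
    for gene in catalog:
        origin = truth.gene_origin.get(gene.gene_id, HOST)
        L_aa = gene.length // 3
        base = L_aa * score_model.bits_per_identical_residue * score_model.divergence_decay
        own_group = _ORIGIN_GROUP[origin]
        cross_group = _CROSS_GROUP[origin]
        own_taxa = group_taxa[own_group]
        cross_taxa = group_taxa[cross_group]
        # Own-group hits: best near the self-score, extras slightly lower.
        for i in range(n_same_group_hits):
            taxon = own_taxa[int(rng.integers(len(own_taxa)))]
            drop = 0.0 if i == 0 else float(rng.uniform(5.0, 30.0))
            bits = base - drop + float(rng.normal(0.0, score_model.noise_sd))
            table.append(_make_hit(gene, taxon, bits, L_aa, score_model, rng, i))
        # One opposing-group hit, margin bits lower.
        cross_bits = base - margin + float(rng.normal(0.0, score_model.noise_sd))
        if cross_bits >= 30.0:
            taxon = cross_taxa[int(rng.integers(len(cross_taxa)))]
            table.append(_make_hit(gene, taxon, cross_bits, L_aa, score_model,
                                   rng, n_same_group_hits))
    return table


def _make_hit(gene: GeneModel, taxon: str, bits: float, qlen_aa: int,
              score_model: ScoreModel, rng, serial: int) -> HitRecord:
    bits = max(bits, 25.0)
    align_frac = float(rng.uniform(0.70, 0.98))
    align_len = max(1, int(qlen_aa * align_frac))
    e_value = min(10.0, qlen_aa * 1e9 * 2.0 ** (-bits))
    return HitRecord(
        query_id=gene.gene_id,
        subject_id=f"{taxon}|p{serial}",
        subject_taxon_id=taxon,
        percent_identity=float(rng.uniform(50.0, 95.0)),
        alignment_length=align_len,
        bit_score=bits,
        e_value=e_value,
        query_start=1,
        query_end=align_len,
        query_length=qlen_aa,
        raw_score=score_model.raw_from_bits(bits),
    ).validate()


def simulate_organelle_hits(
    scaffolds: ScaffoldSet,
    truth: TruthTable,
    seed: int = 0,
    organelle_bits_range: tuple[float, float] = (1200.0, 1500.0),
    background_bits_range: tuple[float, float] = (60.0, 600.0),
    background_fraction: float = 0.05,
) -> HitTable:
    """Scaffold-vs-organelle-reference blastn-style hits.

    True organelle scaffolds score far above the 1000-bit rule; a small
    fraction of nuclear scaffolds get sub-threshold background hits.
    """
    rng = np.random.default_rng(seed)
    table = HitTable()
    for s in scaffolds:
        label = truth.scaffold_label.get(s.scaffold_id, "nuclear")
        if label == "organelle":
            bits = float(rng.uniform(*organelle_bits_range))
        elif rng.random() < background_fraction:
            bits = float(rng.uniform(*background_bits_range))
        else:
            continue
        align_len = int(rng.integers(500, 2000))
        table.append(HitRecord(
            query_id=s.scaffold_id,
            subject_id="kpDNA_ref" if label == "organelle" else "kpDNA_ref",
            subject_taxon_id="organelle_reference",
            percent_identity=float(rng.uniform(80.0, 99.0)),
            alignment_length=align_len,
            bit_score=bits,
            e_value=min(10.0, 1e9 * 2.0 ** (-bits)),
            query_start=1,
            query_end=align_len,
            query_length=s.length,
        ).validate())
    return table


# ---------------------------------------------------------------------------
# Depths
# ---------------------------------------------------------------------------

@dataclass
class DepthRegime:
    mu_nuclear: float = 31.0
    sigma_nuclear: float = 3.0
    mu_contaminant: float = 8.0
    organelle_fold_range: tuple[float, float] = (17.0, 166.0)
    tissue_ratio_range: tuple[float, float] = (2.2, 3.8)
    rich_library: str = "lib_rich"
    poor_library: str = "lib_poor"


def simulate_depths(
    scaffolds: ScaffoldSet,
    truth: TruthTable,
    seed: int = 0,
    regime: DepthRegime = DepthRegime(),
) -> dict[str, dict[str, float]]:
    """Per-scaffold per-library depths; attached to ``scaffolds`` in place.

    Nuclear scaffolds draw Normal(mu_nuclear, sigma) in both libraries;
    organelle scaffolds sit ``organelle_fold_range`` times above the
    nuclear mean in the kleptoplast-poor library and a further two- to
    four-fold higher in the kleptoplast-rich one; bacterial contaminants
    get their own (lower) depth scale.
    """
    rng = np.random.default_rng(seed)
    depths: dict[str, dict[str, float]] = {}
    for s in scaffolds:
        label = truth.scaffold_label.get(s.scaffold_id, "nuclear")
        if label == "organelle":
            fold = float(rng.uniform(*regime.organelle_fold_range))
            poor = regime.mu_nuclear * fold
            ratio = float(rng.uniform(*regime.tissue_ratio_range))
            rich = poor * ratio
        elif label == "bacterial_contaminant":
            poor = max(0.5, float(rng.normal(regime.mu_contaminant, regime.sigma_nuclear)))
            rich = max(0.5, float(rng.normal(regime.mu_contaminant, regime.sigma_nuclear)))
        else:
            poor = max(0.5, float(rng.normal(regime.mu_nuclear, regime.sigma_nuclear)))
            rich = max(0.5, float(rng.normal(regime.mu_nuclear, regime.sigma_nuclear)))
        d = {regime.rich_library: rich, regime.poor_library: poor}
        depths[s.scaffold_id] = d
        s.depth.update(d)
    return depths


# ---------------------------------------------------------------------------
# Read-level screen inputs
# ---------------------------------------------------------------------------

@dataclass
class ReadRegime:
    """Negative-binomial read-count regime for the read-level screen.

    Target TPMs follow the published contrast: rare algal matches versus
    abundant host single-copy matches (about 100x higher), both strongly
    overdispersed (control SD of the same order as the mean).  TPM targets
    are on the per-million-library-reads scale.
    """
    n_algal: int = 614
    n_control: int = 905
    target_tpm_algal: float = 25.0
    target_tpm_control: float = 2601.0
    dispersion_algal: float = 0.06
    dispersion_control: float = 1.4
    library_total_reads: float = 1e6
    min_len_bp: int = 500
    max_len_bp: int = 2000
    n_shared_homolog: int = 0
    shared_reads_total: int = 970
    shared_reads_host_fraction: float = 0.755


@dataclass
class ReadSimResult:
    counts: dict[str, int]
    lengths: dict[str, int]
    algal_ids: list[str]
    control_ids: list[str]
    shared_ids: list[str]
    library_total_reads: float


def _nb_draw(rng, mean: float, dispersion: float) -> int:
    """Negative binomial with mean ``mean`` and size ``dispersion`` (var = mu + mu^2/r)."""
    if mean <= 0:
        return 0
    r = dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_read_hits(
    seed: int = 0,
    regime: ReadRegime = ReadRegime(),
) -> ReadSimResult:
    """Simulate read-hit counts for the algal query set and the host control set.

    Optional planted "shared-homolog" queries (``n_shared_homolog``) sit in
    the algal set with control-like abundance, emulating an algal query
    whose reads really come from a host paralog — these must turn up in
    the flag list and then be explained away by the host-homolog check.
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    per_million = regime.library_total_reads / 1e6
    algal_ids, control_ids, shared_ids = [], [], []
    for i in range(regime.n_algal):
        qid = f"algal_q{i + 1:04d}"
        algal_ids.append(qid)
        length = int(rng.integers(regime.min_len_bp, regime.max_len_bp + 1))
        lengths[qid] = length
        if i < regime.n_shared_homolog:
            shared_ids.append(qid)
            mean = regime.target_tpm_control * (length / 1000.0) * per_million
            counts[qid] = _nb_draw(rng, mean, regime.dispersion_control)
        else:
            mean = regime.target_tpm_algal * (length / 1000.0) * per_million
            counts[qid] = _nb_draw(rng, mean, regime.dispersion_algal)
    for i in range(regime.n_control):
        qid = f"host_sc{i + 1:04d}"
        control_ids.append(qid)
        length = int(rng.integers(regime.min_len_bp, regime.max_len_bp + 1))
        lengths[qid] = length
        mean = regime.target_tpm_control * (length / 1000.0) * per_million
        counts[qid] = _nb_draw(rng, mean, regime.dispersion_control)
    return ReadSimResult(counts, lengths, algal_ids, control_ids, shared_ids,
                         regime.library_total_reads)


def simulate_shared_reads(
    seed: int = 0,
    n_reads: int = 970,
    host_fraction: float = 0.755,
) -> tuple[set[str], HitTable]:
    """Reads hitting a flagged algal query, a fraction of which also hit a host gene.

    Returns the read-id set for the flagged query and a read-vs-host-gene
    hit table covering ``host_fraction`` of those reads.
    """
    rng = np.random.default_rng(seed)
    read_ids = {f"read{i + 1:05d}" for i in range(n_reads)}
    n_shared = int(round(host_fraction * n_reads))
    shared = rng.choice(sorted(read_ids), size=n_shared, replace=False)
    table = HitTable()
    for rid in shared:
        table.append(HitRecord(
            query_id=str(rid), subject_id="host_paralog",
            subject_taxon_id="Mollusca", percent_identity=90.0,
            alignment_length=100, bit_score=80.0, e_value=1e-10,
            query_start=1, query_end=100, query_length=101,
        ).validate())
    return read_ids, table


# ---------------------------------------------------------------------------
# Orthogroup counts and DEG tables
# ---------------------------------------------------------------------------

@dataclass
class CountsRegime:
    n_orthogroups: int = 200
    n_species: int = 18
    focal_species: str = "PoB"
    lambda_base: float = 3.0
    n_planted_expanded: int = 3
    n_planted_enriched: int = 1
    planted_focal_min: int = 60
    planted_focal_max: int = 250
    background_up_rate: float = 162.0 / 77230.0
    enriched_up_rate: float = 45.0 / 203.0


def simulate_counts_and_degs(
    seed: int = 0,
    regime: CountsRegime = CountsRegime(),
) -> tuple[pd.DataFrame, dict[str, str], DEGTable, TruthTable]:
    """Orthogroup count matrix + gene->orthogroup membership + DEG table.

    Baseline counts are Poisson(``lambda_base``) per species.  Planted
    expanded orthogroups get the focal count inflated far beyond the other
    species (guaranteeing z > 2 at the default shape); planted enriched
    orthogroups additionally receive an up-regulated gene fraction far
    above the genome background.
    """
    rng = np.random.default_rng(seed)
    if regime.n_planted_enriched > regime.n_planted_expanded:
        raise ValueError("cannot plant more enriched than expanded orthogroups")
    species = [regime.focal_species] + [f"sp{i + 1:02d}"
                                        for i in range(regime.n_species - 1)]
    og_ids = [f"OG{i + 1:07d}" for i in range(regime.n_orthogroups)]
    counts = rng.poisson(regime.lambda_base,
                         size=(regime.n_orthogroups, regime.n_species))
    truth = TruthTable()
    planted = rng.choice(regime.n_orthogroups, size=regime.n_planted_expanded,
                         replace=False)
    for j, row in enumerate(planted):
        counts[row, 0] = int(rng.integers(regime.planted_focal_min,
                                          regime.planted_focal_max + 1))
        truth.planted_expanded.add(og_ids[row])
        if j < regime.n_planted_enriched:
            truth.planted_enriched.add(og_ids[row])
    matrix = pd.DataFrame(counts, index=og_ids, columns=species)
    membership: dict[str, str] = {}
    deg_records: list[DEGRecord] = []
    for og in og_ids:
        n_focal = int(matrix.at[og, regime.focal_species])
        up_rate = (regime.enriched_up_rate if og in truth.planted_enriched
                   else regime.background_up_rate)
        for i in range(n_focal):
            gid = f"{og}.g{i + 1:03d}"
            membership[gid] = og
            if rng.random() < up_rate:
                deg_records.append(DEGRecord(
                    gid, float(rng.normal(2.5, 0.8)),
                    float(rng.uniform(1e-8, 0.009)), "up"))
            elif rng.random() < regime.background_up_rate:
                deg_records.append(DEGRecord(
                    gid, float(-rng.normal(2.5, 0.8)),
                    float(rng.uniform(1e-8, 0.009)), "down"))
            else:
                deg_records.append(DEGRecord(
                    gid, float(rng.normal(0.0, 0.5)),
                    float(rng.uniform(0.05, 1.0)), "ns"))
    return matrix, membership, DEGTable(deg_records), truth
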