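"""Shared data model and readers/writers for every external format.

The pipeline consumes tabular outputs of homology-search tools (BLAST
outfmt-6-style TSV, with explicit dialects), FASTA scaffolds, GFF3 gene
rows, and plain TSV tables for taxonomy, read depth, orthogroup counts and
differential expression.  All coordinates are converted to a 0-based
half-open convention at the I/O boundary; external GFF3 stays 1-based
inclusive.

Parsers validate aggressively: a malformed row raises :class:`FormatError`
naming the offending line, never a silent skip.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, asdict, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("kleptoscreen")

UNASSIGNED = "UNASSIGNED"

REQUIRED_GROUPS = ("prokaryote", "eukaryote", "algae", "lophotrochozoa")

#: Column order of NCBI BLAST ``-outfmt 6`` and of the MMseqs2 convertalis
#: default.  Dialects extend this on the right.
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Explicit hit-table dialects (never sniffed; outfmt-6 variants differ
#: silently in column order).  ``mmseq2`` is the 12 standard columns plus
#: ``qlen`` and ``raw`` (the un-normalised alignment score), the output of
#: ``--format-output`` with those fields appended.
HIT_DIALECTS = {
    "blast6": BLAST6_COLUMNS,
    "blast6+qlen": BLAST6_COLUMNS + ("qlen",),
    "mmseq2": BLAST6_COLUMNS + ("qlen", "raw"),
}


class FormatError(ValueError):
    """A malformed external file; carries the path and 1-based line number."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class ValidationError(ValueError):
    """An in-memory object violating a type invariant."""


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    """One homology match between a query (gene model) and a subject.

    ``bit_score`` is the log-scaled, database-size-independent score
    (lambda*S - ln K)/ln 2; ``raw_score`` is the plain alignment score (sum
    of substitution-matrix scores and gap penalties), present only for
    dialects that carry it.
    """

    query_id: str
    subject_id: str
    subject_taxon_id: str
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    query_start: int  # 1-based inclusive, as in outfmt 6
    query_end: int
    query_length: Optional[int] = None
    raw_score: Optional[float] = None

    def validate(self) -> "HitRecord":
        if self.query_start > self.query_end:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: query_start > query_end")
        if self.alignment_length < 1:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: alignment_length < 1")
        if self.bit_score < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative bit score")
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: pident outside [0,100]")
        if self.query_length is not None and self.query_length < 1:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: query_length < 1")
        return self

    @property
    def query_coverage(self) -> float:
        """Fraction of the query spanned by the aligned region."""
        if self.query_length is None:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: query_length required "
                "for coverage but absent (use a qlen-bearing dialect)")
        return (self.query_end - self.query_start + 1) / self.query_length


class HitTable:
    """An ordered collection of :class:`HitRecord` with per-query access."""

    def __init__(self, records: Iterable[HitRecord] = ()):
        self.records: list[HitRecord] = list(records)

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def append(self, rec: HitRecord) -> None:
        self.records.append(rec)

    def query_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.query_id, None)
        return list(seen)

    def by_query(self) -> dict[str, "HitTable"]:
        out: dict[str, HitTable] = {}
        for r in self.records:
            out.setdefault(r.query_id, HitTable()).append(r)
        return out

    def for_query(self, query_id: str) -> "HitTable":
        return HitTable(r for r in self.records if r.query_id == query_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def _parse_field(text, caster, what, path, line_no):
    try:
        return caster(text)
    except ValueError:
        raise FormatError(path, line_no, f"cannot parse {what} from {text!r}") from None


def read_hit_table(
    path,
    dialect: str,
    taxon_map: Optional[Mapping[str, str]] = None,
    with_taxid: bool = False,
    query_lengths: Optional[Mapping[str, int]] = None,
) -> HitTable:
    """Read a homology-hit TSV in an explicit outfmt-6-style ``dialect``.

    Parameters
    ----------
    dialect
        One of ``blast6``, ``blast6+qlen``, ``mmseq2`` (see
        :data:`HIT_DIALECTS`).
    taxon_map
        Optional subject_id -> taxon_id mapping.  When absent and no
        ``staxid`` column is present, the subject id itself is used as the
        taxon id (the convention of the synthetic tables).
    with_taxid
        If true, one extra trailing ``staxid`` column is expected.
    query_lengths
        Companion lengths (e.g. from the query FASTA) for dialects without
        a ``qlen`` column.
    """
    if dialect not in HIT_DIALECTS:
        raise ValueError(f"unknown hit-table dialect {dialect!r}; "
                         f"choose from {sorted(HIT_DIALECTS)}")
    columns = HIT_DIALECTS[dialect] + (("staxid",) if with_taxid else ())
    table = HitTable()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise FormatError(path, line_no,
                                  f"expected {len(columns)} columns for dialect "
                                  f"{dialect!r}, found {len(parts)}")
            row = dict(zip(columns, parts))
            qlen: Optional[int]
            if "qlen" in row:
                qlen = _parse_field(row["qlen"], int, "qlen", path, line_no)
            elif query_lengths is not None:
                qlen = query_lengths.get(row["qseqid"])
            else:
                qlen = None
            if with_taxid:
                taxon = row["staxid"]
            elif taxon_map is not None:
                taxon = taxon_map.get(row["sseqid"], row["sseqid"])
            else:
                taxon = row["sseqid"]
            rec = HitRecord(
                query_id=row["qseqid"],
                subject_id=row["sseqid"],
                subject_taxon_id=taxon,
                percent_identity=_parse_field(row["pident"], float, "pident", path, line_no),
                alignment_length=_parse_field(row["length"], int, "length", path, line_no),
                bit_score=_parse_field(row["bitscore"], float, "bitscore", path, line_no),
                e_value=_parse_field(row["evalue"], float, "evalue", path, line_no),
                query_start=_parse_field(row["qstart"], int, "qstart", path, line_no),
                query_end=_parse_field(row["qend"], int, "qend", path, line_no),
                query_length=qlen,
                raw_score=(_parse_field(row["raw"], float, "raw", path, line_no)
                           if "raw" in row else None),
            )
            try:
                rec.validate()
            except ValidationError as exc:
                raise FormatError(path, line_no, str(exc)) from None
            table.append(rec)
    return table


def write_hit_table(table: HitTable, path, dialect: str, with_taxid: bool = False) -> None:
    """Write ``table`` as TSV in ``dialect`` column order (round-trips exactly)."""
    if dialect not in HIT_DIALECTS:
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    columns = HIT_DIALECTS[dialect]
    with open(path, "w") as fh:
        for r in table:
            row = {
                "qseqid": r.query_id, "sseqid": r.subject_id,
                "pident": repr(r.percent_identity),
                "length": str(r.alignment_length),
                "mismatch": "0", "gapopen": "0",
                "qstart": str(r.query_start), "qend": str(r.query_end),
                "sstart": "1", "send": str(r.alignment_length),
                "evalue": repr(r.e_value), "bitscore": repr(r.bit_score),
            }
            if "qlen" in columns:
                if r.query_length is None:
                    raise ValidationError(
                        f"hit {r.query_id}->{r.subject_id}: dialect {dialect!r} "
                        "requires query_length")
                row["qlen"] = str(r.query_length)
            if "raw" in columns:
                if r.raw_score is None:
                    raise ValidationError(
                        f"hit {r.query_id}->{r.subject_id}: dialect {dialect!r} "
                        "requires raw_score")
                row["raw"] = repr(r.raw_score)
            out = [row[c] for c in columns]
            if with_taxid:
                out.append(r.subject_taxon_id)
            fh.write("\t".join(out) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

class TaxonomyTree:
    """A rooted taxonomy with named groups.

    ``parents`` maps every taxon id to its parent id (the root maps to
    ``None``).  ``groups`` maps a group name to the set of *seed* node ids;
    a taxon belongs to a group when the taxon or any of its ancestors is a
    seed node.  The four groups the screens rely on — prokaryote,
    eukaryote, algae, lophotrochozoa — are mandatory.
    """

    def __init__(self,
                 parents: Mapping[str, Optional[str]],
                 names: Optional[Mapping[str, str]] = None,
                 groups: Optional[Mapping[str, Iterable[str]]] = None):
        self.parents: dict[str, Optional[str]] = dict(parents)
        self.names: dict[str, str] = dict(names or {})
        self.groups: dict[str, frozenset[str]] = {
            g: frozenset(members) for g, members in (groups or {}).items()}
        self._depth_cache: dict[str, int] = {}
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> str:
        return self._root

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    def validate(self) -> "TaxonomyTree":
        roots = [t for t, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"taxonomy must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for t, p in self.parents.items():
            if p is not None and p not in self.parents:
                raise ValidationError(f"orphan node {t!r}: parent {p!r} does not exist")
        # Cycle check: every path must terminate at the root.
        for t in self.parents:
            seen = set()
            node: Optional[str] = t
            while node is not None:
                if node in seen:
                    raise ValidationError(f"cycle detected at node {node!r}")
                seen.add(node)
                node = self.parents[node]
        for g in REQUIRED_GROUPS:
            if g not in self.groups:
                raise ValidationError(f"required group {g!r} missing")
        for g, members in self.groups.items():
            unknown = set(members) - set(self.parents)
            if unknown:
                raise ValidationError(f"group {g!r} names unknown taxa {sorted(unknown)}")
        algae = self.group_taxa("algae")
        loph = self.group_taxa("lophotrochozoa")
        euk = self.group_taxa("eukaryote")
        if not algae <= euk:
            raise ValidationError("algae group is not contained in eukaryote group")
        if not loph <= euk:
            raise ValidationError("lophotrochozoa group is not contained in eukaryote group")
        if algae & loph:
            raise ValidationError("algae and lophotrochozoa groups overlap")
        return self

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Ancestor path from ``taxon_id`` (inclusive) up to the root."""
        if taxon_id not in self.parents:
            raise KeyError(f"unknown taxon {taxon_id!r}")
        out = []
        node: Optional[str] = taxon_id
        while node is not None:
            out.append(node)
            node = self.parents[node]
        return out

    def depth(self, taxon_id: str) -> int:
        if taxon_id not in self._depth_cache:
            self._depth_cache[taxon_id] = len(self.path_to_root(taxon_id)) - 1
        return self._depth_cache[taxon_id]

    def is_ancestor_or_self(self, ancestor: str, taxon_id: str) -> bool:
        return ancestor in self.path_to_root(taxon_id)

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a nonempty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set")
        common = set(self.path_to_root(taxa[0]))
        for t in taxa[1:]:
            common &= set(self.path_to_root(t))
        return max(common, key=self.depth)

    def children(self, taxon_id: str) -> list[str]:
        return [t for t, p in self.parents.items() if p == taxon_id]

    def subtree(self, taxon_id: str) -> set[str]:
        """All nodes at or below ``taxon_id``."""
        out, stack = set(), [taxon_id]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(self.children(node))
        return out

    # -- groups ------------------------------------------------------------
    def in_group(self, taxon_id: str, group: str) -> bool:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        seeds = self.groups[group]
        return any(a in seeds for a in self.path_to_root(taxon_id))

    def group_taxa(self, group: str) -> set[str]:
        """All taxa belonging to ``group`` (seeds expanded to subtrees)."""
        out: set[str] = set()
        for seed in self.groups[group]:
            out |= self.subtree(seed)
        return out


def read_taxonomy(path) -> TaxonomyTree:
    """Read a taxonomy TSV of (taxon_id, parent_id, name, groups).

    ``parent_id`` is empty or ``-`` for the root; ``groups`` is a
    comma-separated list of group names seeded at that node (may be empty).
    """
    parents: dict[str, Optional[str]] = {}
    names: dict[str, str] = {}
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(path, line_no, f"expected 4 columns, found {len(parts)}")
            taxon_id, parent_id, name, group_field = parts
            if taxon_id in parents:
                raise FormatError(path, line_no, f"duplicate taxon {taxon_id!r}")
            parents[taxon_id] = None if parent_id in ("", "-") else parent_id
            names[taxon_id] = name
            for g in filter(None, group_field.split(",")):
                groups.setdefault(g.strip(), set()).add(taxon_id)
    try:
        return TaxonomyTree(parents, names, groups)
    except ValidationError as exc:
        raise FormatError(path, 0, str(exc)) from None


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    seeded: dict[str, list[str]] = {}
    for g, members in tree.groups.items():
        for m in members:
            seeded.setdefault(m, []).append(g)
    with open(path, "w") as fh:
        for taxon_id, parent in tree.parents.items():
            fh.write("\t".join([
                taxon_id,
                parent if parent is not None else "-",
                tree.names.get(taxon_id, taxon_id),
                ",".join(sorted(seeded.get(taxon_id, []))),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Gene models and scaffolds
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene placed on a scaffold; coordinates 0-based half-open internally."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    assigned_taxon: Optional[str] = None

    def validate(self) -> "GeneModel":
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        return self

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneCatalog:
    def __init__(self, genes: Iterable[GeneModel] = ()):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValidationError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene.validate()

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def by_scaffold(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self:
            out.setdefault(g.scaffold_id, []).append(g)
        return out

    def validate_against(self, scaffolds: "ScaffoldSet") -> "GeneCatalog":
        for g in self:
            if g.scaffold_id not in scaffolds:
                raise ValidationError(
                    f"gene {g.gene_id}: scaffold {g.scaffold_id!r} not in assembly")
            if g.end > scaffolds[g.scaffold_id].length:
                raise ValidationError(
                    f"gene {g.gene_id}: extends past scaffold end")
        return self


@dataclass
class Scaffold:
    scaffold_id: str
    length: int
    sequence: Optional[str] = None
    depth: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "Scaffold":
        if self.length < 1:
            raise ValidationError(f"scaffold {self.scaffold_id}: length < 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"scaffold {self.scaffold_id}: sequence/length mismatch")
        for lib, d in self.depth.items():
            if d < 0:
                raise ValidationError(
                    f"scaffold {self.scaffold_id}: negative depth in {lib}")
        return self

    def mean_depth(self) -> float:
        if not self.depth:
            raise ValidationError(f"scaffold {self.scaffold_id}: no depth data")
        return sum(self.depth.values()) / len(self.depth)


class ScaffoldSet:
    def __init__(self, scaffolds: Iterable[Scaffold] = ()):
        self.scaffolds: dict[str, Scaffold] = {}
        for s in scaffolds:
            self.add(s)

    def add(self, s: Scaffold) -> None:
        if s.scaffold_id in self.scaffolds:
            raise ValidationError(f"duplicate scaffold id {s.scaffold_id!r}")
        self.scaffolds[s.scaffold_id] = s.validate()

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self.scaffolds.values())

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        return self.scaffolds[scaffold_id]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def ids(self) -> list[str]:
        return list(self.scaffolds)


def read_gff_genes(path) -> GeneCatalog:
    """Read gene rows from a GFF3 file (1-based inclusive -> half-open).

    Only ``gene``-type rows are consumed; the gene id comes from the
    ``ID=`` attribute.
    """
    catalog = GeneCatalog()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(path, line_no, f"expected 9 columns, found {len(parts)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            start_i = _parse_field(start, int, "start", path, line_no)
            end_i = _parse_field(end, int, "end", path, line_no)
            if strand not in ("+", "-"):
                raise FormatError(path, line_no, f"bad strand {strand!r}")
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                raise FormatError(path, line_no, "gene row without ID attribute")
            if start_i < 1 or end_i < start_i:
                raise FormatError(path, line_no, f"bad coordinates {start}..{end}")
            try:
                catalog.add(GeneModel(gene_id, seqid, start_i - 1, end_i, strand))
            except ValidationError as exc:
                raise FormatError(path, line_no, str(exc)) from None
    return catalog


def write_gff_genes(catalog: GeneCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in catalog:
            fh.write("\t".join([
                g.scaffold_id, "kleptoscreen", "gene",
                str(g.start + 1), str(g.end), ".", g.strand, ".",
                f"ID={g.gene_id}",
            ]) + "\n")


def read_fasta(path) -> ScaffoldSet:
    out = ScaffoldSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        out.add(Scaffold(rec.id, len(rec.seq), sequence=str(rec.seq)))
    return out


def write_fasta(scaffolds: ScaffoldSet, path) -> None:
    records = []
    for s in scaffolds:
        seq = s.sequence if s.sequence is not None else "N" * s.length
        records.append(SeqRecord(Seq(seq), id=s.scaffold_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_depth_table(path, scaffolds: Optional[ScaffoldSet] = None) -> dict[str, dict[str, float]]:
    """Read a long-format depth TSV (scaffold_id, library_id, mean_depth).

    Returns scaffold_id -> {library_id: depth}; when ``scaffolds`` is
    given, depths are attached to it in place and unknown scaffolds are an
    error.
    """
    depths: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(path, line_no, f"expected 3 columns, found {len(parts)}")
            sid, lib, depth = parts
            d = _parse_field(depth, float, "depth", path, line_no)
            if d < 0:
                raise FormatError(path, line_no, f"negative depth {depth}")
            if scaffolds is not None and sid not in scaffolds:
                raise FormatError(path, line_no, f"unknown scaffold {sid!r}")
            depths.setdefault(sid, {})[lib] = d
    if scaffolds is not None:
        for sid, libdepths in depths.items():
            scaffolds[sid].depth.update(libdepths)
    return depths


def write_depth_table(depths: Mapping[str, Mapping[str, float]], path) -> None:
    with open(path, "w") as fh:
        for sid, libdepths in depths.items():
            for lib, d in libdepths.items():
                fh.write(f"{sid}\t{lib}\t{repr(float(d))}\n")


# ---------------------------------------------------------------------------
# Orthogroup count matrix and DEG table
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> pd.DataFrame:
    """Read an orthogroup x species gene-count TSV (first column = orthogroup id).

    Counts must be non-negative integers; anything else is a validation
    error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(path, 0, "empty count matrix")
    for col in df.columns:
        series = df[col]
        if not pd.api.types.is_numeric_dtype(series):
            raise FormatError(path, 0, f"non-numeric gene count in column {col!r}")
        if not (series == series.astype(int)).all():
            raise FormatError(path, 0, f"non-integer gene count in column {col!r}")
        if (series < 0).any():
            raise FormatError(path, 0, f"negative gene count in column {col!r}")
    return df.astype(int)


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="orthogroup")


@dataclass
class DEGRecord:
    gene_id: str
    log2_fold_change: float
    fdr: float
    direction: str  # up | down | ns

    def validate(self, fdr_cutoff: float = 0.01) -> "DEGRecord":
        if self.direction not in ("up", "down", "ns"):
            raise ValidationError(f"gene {self.gene_id}: bad direction {self.direction!r}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValidationError(f"gene {self.gene_id}: FDR outside [0,1]")
        if self.direction in ("up", "down") and self.fdr >= fdr_cutoff:
            raise ValidationError(
                f"gene {self.gene_id}: direction {self.direction!r} with FDR "
                f"{self.fdr} >= cutoff {fdr_cutoff}")
        return self


class DEGTable:
    """Differential-expression labels (e.g. digestive gland vs control tissue)."""

    def __init__(self, records: Iterable[DEGRecord] = (), fdr_cutoff: float = 0.01):
        self.fdr_cutoff = fdr_cutoff
        self.records: list[DEGRecord] = [r.validate(fdr_cutoff) for r in records]

    def __iter__(self) -> Iterator[DEGRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def up_genes(self) -> set[str]:
        return {r.gene_id for r in self.records if r.direction == "up"}

    def down_genes(self) -> set[str]:
        return {r.gene_id for r in self.records if r.direction == "down"}


def read_deg_table(path, fdr_cutoff: float = 0.01) -> DEGTable:
    """Read a DEG TSV of (gene_id, log2_fold_change, fdr, direction)."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(path, line_no, f"expected 4 columns, found {len(parts)}")
            gene_id, lfc, fdr, direction = parts
            rec = DEGRecord(
                gene_id,
                _parse_field(lfc, float, "log2_fold_change", path, line_no),
                _parse_field(fdr, float, "fdr", path, line_no),
                direction,
            )
            try:
                rec.validate(fdr_cutoff)
            except ValidationError as exc:
                raise FormatError(path, line_no, str(exc)) from None
            records.append(rec)
    return DEGTable(records, fdr_cutoff)


def write_deg_table(table: DEGTable, path) -> None:
    with open(path, "w") as fh:
        for r in table:
            fh.write(f"{r.gene_id}\t{repr(r.log2_fold_change)}\t{repr(r.fdr)}\t{r.direction}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LcaConfig:
    """MEGAN-style LCA parameters."""
    min_score: float = 50.0
    max_expected: float = 1e-4
    top_percent: float = 20.0
    min_support_percent: float = 0.1
    min_support: int = 1
    lca_percent: float = 90.0


@dataclass
class AlignScreenConfig:
    """Genome-level alignment credibility thresholds (coverage strict >,
    normalised score strict >)."""
    min_query_coverage: float = 0.60
    min_norm_score: float = 2.0
    max_evalue: float = 1e-4


@dataclass
class ReadScreenConfig:
    max_evalue: float = 1e-3
    flag_tpm: float = 100.0
    #: TPM denominator: "universe" (the union of query sets; TPMs sum to 1e6)
    #: or "library_total" (per-million of total library reads).
    tpm_denominator: str = "universe"
    #: A flagged query counts as explained by a host homolog when more than
    #: this fraction of its reads also hit a host gene.
    host_shared_fraction: float = 0.5


@dataclass
class HgtIndexConfig:
    threshold: float = 100.0
    #: Bit score assigned to a group with no hit.
    missing_group_bits: float = 0.0
    #: "donor-host" (default: prokaryote-eukaryote / algae-lophotrochozoan,
    #: candidates at index >= +threshold) or "host-donor" (negated).
    sign: str = "donor-host"


@dataclass
class DecontamConfig:
    min_bacterial_genes: int = 2
    max_loph_genes: int = 0
    organelle_min_bitscore: float = 1000.0
    organelle_min_depth_fold: float = 10.0
    tissue_ratio_min: float = 2.0
    tissue_ratio_max: float = 4.0


@dataclass
class ExpansionConfig:
    z_threshold: float = 2.0
    #: Include the focal species in the row mean/SD (heatmap convention).
    include_focal: bool = True
    enrichment_alpha: float = 1e-4
    #: Sidedness of the enrichment test: "two-sided" or "greater".
    sided: str = "two-sided"


@dataclass
class ScreenConfig:
    """All pipeline thresholds, with the published defaults."""
    lca: LcaConfig = field(default_factory=LcaConfig)
    align_screen: AlignScreenConfig = field(default_factory=AlignScreenConfig)
    read_screen: ReadScreenConfig = field(default_factory=ReadScreenConfig)
    hgt_index: HgtIndexConfig = field(default_factory=HgtIndexConfig)
    decontam: DecontamConfig = field(default_factory=DecontamConfig)
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    rng_seed: int = 0

    def validate(self) -> "ScreenConfig":
        for section in (self.lca, self.align_screen, self.read_screen,
                        self.hgt_index, self.decontam, self.expansion):
            for f in fields(section):
                v = getattr(section, f.name)
                if isinstance(v, (int, float)) and not math.isfinite(v):
                    raise ValidationError(f"config {f.name} is not finite")
        if not 0 < self.lca.top_percent <= 100:
            raise ValidationError("lca.top_percent must be in (0, 100]")
        if not 0 < self.lca.lca_percent <= 100:
            raise ValidationError("lca.lca_percent must be in (0, 100]")
        if self.hgt_index.sign not in ("donor-host", "host-donor"):
            raise ValidationError(f"bad hgt_index.sign {self.hgt_index.sign!r}")
        if self.read_screen.tpm_denominator not in ("universe", "library_total"):
            raise ValidationError(
                f"bad read_screen.tpm_denominator {self.read_screen.tpm_denominator!r}")
        if self.expansion.sided not in ("two-sided", "greater"):
            raise ValidationError(f"bad expansion.sided {self.expansion.sided!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        sections = {
            "lca": LcaConfig, "align_screen": AlignScreenConfig,
            "read_screen": ReadScreenConfig, "hgt_index": HgtIndexConfig,
            "decontam": DecontamConfig, "expansion": ExpansionConfig,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key in sections:
                known = {f.name for f in fields(sections[key])}
                unknown = set(val) - known
                if unknown:
                    raise ValidationError(f"unknown {key} options {sorted(unknown)}")
                kwargs[key] = sections[key](**val)
            elif key == "rng_seed":
                kwargs[key] = int(val)
            else:
                raise ValidationError(f"unknown config section {key!r}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging to stderr."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
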