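import pytest

from kleptoscreen.core_io import (HitRecord, HitTable, ScreenConfig,
                                  TaxonomyTree)


@pytest.fixture
def cfg() -> ScreenConfig:
    return ScreenConfig().validate()


@pytest.fixture
def tiny_tree() -> TaxonomyTree:
    """Hand-built 12-node taxonomy with all four screen groups.

    root -> Bacteria -> {Ecoli, Bsubtilis}
         -> Eukaryota -> Viridiplantae -> {Chlorella, Caulerpa}
                      -> Metazoa -> Lophotrochozoa -> {Aplysia, Plakobranchus}
                      -> Fungi
    """
    parents = {
        "root": None,
        "Bacteria": "root",
        "Ecoli": "Bacteria",
        "Bsubtilis": "Bacteria",
        "Eukaryota": "root",
        "Viridiplantae": "Eukaryota",
        "Chlorella": "Viridiplantae",
        "Caulerpa": "Viridiplantae",
        "Metazoa": "Eukaryota",
        "Lophotrochozoa": "Metazoa",
        "Aplysia": "Lophotrochozoa",
        "Plakobranchus": "Lophotrochozoa",
        "Fungi": "Eukaryota",
    }
    groups = {
        "prokaryote": {"Bacteria"},
        "bacteria": {"Bacteria"},
        "eukaryote": {"Eukaryota"},
        "algae": {"Viridiplantae"},
        "lophotrochozoa": {"Lophotrochozoa"},
    }
    return TaxonomyTree(parents, groups=groups)


def make_hit(query="g1", taxon="Aplysia", bits=200.0, evalue=1e-20,
             subject=None, qlen=300, align_len=250, qstart=1, qend=None,
             raw=None, pident=80.0) -> HitRecord:
    return HitRecord(
        query_id=query,
        subject_id=subject if subject is not None else f"{taxon}|p1",
        subject_taxon_id=taxon,
        percent_identity=pident,
        alignment_length=align_len,
        bit_score=bits,
        e_value=evalue,
        query_start=qstart,
        query_end=qend if qend is not None else qstart + align_len - 1,
        query_length=qlen,
        raw_score=raw,
    ).validate()


@pytest.fixture
def hit_factory():
    return make_hit
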