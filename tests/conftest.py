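import pytest

from mitocistron.evidence import ContigAlignment, parse_gene_content
from mitocistron.fixtures import TABLE2_CONTIGS, beauveria_like_annotation
from mitocistron.genome import CircularGenome, GeneFeature, GenomeAnnotation


@pytest.fixture(scope="session")
def fixture_ann():
    """Deterministic anchor-honoring annotation (one rnl intron + rps3)."""
    return beauveria_like_annotation()


@pytest.fixture(scope="session")
def table2_contigs():
    return [
        ContigAlignment(
            contig_id=cid, strain=strain, start=start, end=end,
            gene_content=tuple(parse_gene_content(content)),
        )
        for cid, strain, start, end, content in TABLE2_CONTIGS
    ]


def make_annotation(spec, length, sequence=None, genome_id="toy"):
    """Small helper: spec = [(name, kind, start, end, introns?), ...]."""
    seq = sequence if sequence is not None else ("AT" * length)[:length]
    genome = CircularGenome(id=genome_id, sequence=seq)
    feats = []
    for item in spec:
        name, kind, start, end = item[:4]
        introns = tuple(item[4]) if len(item) > 4 else ()
        feats.append(GeneFeature(name=name, kind=kind, start=start, end=end,
                                 wraps_origin=start > end, introns=introns))
    return GenomeAnnotation(genome=genome, features=tuple(feats))


@pytest.fixture()
def toy_factory():
    return make_annotation
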