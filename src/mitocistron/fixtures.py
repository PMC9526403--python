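"""Published reference tables and a deterministic anchor-honoring fixture.

This module packages, as Python constants, the worked-example inputs the
inference is demonstrated on: the per-strain intron count table, the
transcript-contig table (23 contigs from three strains aligned to their
mitogenomes, with gene-content labels), the cDNA-PCR validated junction
pairs, the canonical Beauveria gene order, and the printed coordinate
anchors. ``beauveria_like_annotation()`` builds a single deterministic
annotation whose coordinates honor every anchor (trnR_2 at 17,359-17,429;
trnG starting at 25,199; trnM_3 ending at 5,543; the 2/3/26/53-bp
intergenic distances) so that the contig table can be interpreted against
it coordinate-by-coordinate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import CircularGenome, GeneFeature, GenomeAnnotation

__all__ = [
    "CANONICAL_GENE_ORDER",
    "PCG_CONCAT_ORDER",
    "TRNA_GENES",
    "PCG_GENES",
    "RRNA_GENES",
    "TABLE1_INTRON_COUNTS",
    "TABLE2_CONTIGS",
    "VALIDATED_JUNCTIONS",
    "ZERO_COVERAGE_TRNAS",
    "ANCHORS",
    "ABSTRACT_UNIT_STRING",
    "FIXTURE_COORDS",
    "beauveria_like_annotation",
]

# Canonical single-strand gene order, written from trnM_1; the control
# region lies between trnM_3 and trnM_1 (i.e. inside the wrap junction).
# Duplicate tRNAs are disambiguated by a subscript index in genomic order.
CANONICAL_GENE_ORDER: tuple[str, ...] = (
    "trnM_1", "trnL_1", "trnA", "trnF", "trnK", "trnL_2", "trnQ", "trnH",
    "trnM_2", "nad2", "nad3", "atp9", "cox2", "trnR_1", "nad4L", "nad5",
    "cob", "trnC", "cox1", "trnR_2", "nad1", "nad4", "atp8", "atp6", "rns",
    "trnY", "trnD", "trnS_1", "trnN", "cox3", "trnG", "nad6", "trnV",
    "trnI", "trnS_2", "trnW", "trnP", "rnl", "trnT", "trnE", "trnM_3",
)

# 15-PCG concatenation order used for phylogenetic matrices.
PCG_CONCAT_ORDER: tuple[str, ...] = (
    "rps3", "nad2", "nad3", "atp9", "cox2", "nad4L", "nad5", "cob", "cox1",
    "nad1", "nad4", "atp8", "atp6", "cox3", "nad6",
)

TRNA_GENES = tuple(g for g in CANONICAL_GENE_ORDER if g.startswith("trn"))
RRNA_GENES = ("rns", "rnl")
PCG_GENES = tuple(g for g in CANONICAL_GENE_ORDER if not g.startswith("trn") and g not in RRNA_GENES)

# Per-strain intron counts by host gene (printed Total column reproduced by
# the row sums).
TABLE1_INTRON_COUNTS = pd.DataFrame(
    [
        ("B. amorpha GYU-BMZ01", 1, 1, 0, 1, 1, 1),
        ("B. amorpha GYU-BMZ02", 1, 1, 0, 1, 1, 1),
        ("B. bassiana YMM", 1, 0, 0, 1, 0, 0),
        ("B. bassiana GYU-BMZ04", 1, 1, 0, 1, 0, 0),
        ("B. bassiana ARSEF 8028", 1, 1, 0, 1, 1, 0),
        ("B. brongniartii GYU-BMZ03", 2, 1, 1, 1, 2, 1),
        ("B. caledonica ATCC 64970", 1, 0, 0, 2, 1, 0),
        ("B. pseudobassiana ATCC 90518", 1, 0, 0, 0, 0, 0),
    ],
    columns=["strain", "rnl", "cox2", "nad5", "cob", "cox1", "nad1"],
).set_index("strain")

# Transcript contigs: (contig_id, strain, start, end, printed gene content).
# Coordinates are each strain's own mitogenome coordinates. The C1 label
# prints "trnM3" where genomic order implies the trnM_2 slot; the raw label
# is kept here and resolved positionally downstream.
TABLE2_CONTIGS: tuple[tuple[str, str, int, int, str], ...] = (
    ("A", "ARSEF 8028", 1, 5664, "rnl(rps3)-trnT-trnE-trnM3"),
    ("B1", "ATCC 90518", 6198, 6433, "trnL1-trnA-trnF-trnK-trnL2"),
    ("B2", "ATCC 90518", 6414, 10490, "trnL2-trnQ-trnH-trnM2-nad2-nad3-atp9-cox2-trnR1"),
    ("B3", "ATCC 90518", 10540, 12490, "nad4L-nad5"),
    ("B4", "ATCC 90518", 12470, 12830, "nad5-cob"),
    ("B5", "ATCC 90518", 12729, 14308, "cob-trnC"),
    ("B6", "ATCC 90518", 14313, 17358, "cox1"),
    ("B7", "ATCC 90518", 17429, 17866, "nad1"),
    ("B8", "ATCC 90518", 17862, 18968, "nad1"),
    ("B9", "ATCC 90518", 19715, 20804, "nad1-nad4-atp8"),
    ("B10", "ATCC 90518", 20795, 22128, "atp8-atp6"),
    ("B11", "ATCC 90518", 22273, 23966, "rns-trnY"),
    ("B12", "ATCC 90518", 24047, 25172, "trnS-trnN-cox3"),
    ("B13", "ATCC 90518", 25704, 26318, "nad6-trnV"),
    ("C1", "GYU-BMZ01", 6367, 6996, "trnA-trnF-trnK-trnL2-trnQ-trnH-trnM3"),
    ("C2", "GYU-BMZ01", 7011, 16819, "nad2-nad3-atp9-cox2-trnR1-nad4L-nad5-cob"),
    ("C3", "GYU-BMZ01", 16818, 21192, "cob-trnC-cox1"),
    ("C4", "GYU-BMZ01", 21302, 24514, "nad1-nad4"),
    ("C5", "GYU-BMZ01", 25713, 28925, "nad4-atp8-atp6-rns"),
    ("C6", "GYU-BMZ01", 29091, 29353, "trnD-trnS-trnN"),
    ("C7", "GYU-BMZ01", 29342, 30157, "trnN-cox3"),
    ("C8", "GYU-BMZ01", 30529, 31900, "nad6-trnV"),
    ("C9", "GYU-BMZ01", 31954, 32191, "trnI-trnS-trnW"),
)

# Gene-pair junctions demonstrated by cDNA-PCR across zero-coverage tRNAs.
VALIDATED_JUNCTIONS: tuple[tuple[str, str], ...] = (
    ("cox1", "trnR_2"),
    ("trnR_2", "nad1"),
    ("cox3", "trnG"),
    ("trnG", "nad6"),
    ("trnP", "rnl"),
)

# tRNAs with no read evidence in the pooled transcript alignments.
ZERO_COVERAGE_TRNAS = ("trnM_1", "trnR_2", "trnG", "trnP")

# Printed coordinate anchors (1-based inclusive).
ANCHORS = {
    "trnR_2": (17359, 17429),
    "trnG_start": 25199,
    "trnM_3_end": 5543,
    "contig_A_end": 5664,
    "B12_end": 25172,
    "gap_trnM_1_trnL_1": 2,
    "gap_trnY_trnD": 3,
    "gap_trnV_trnI": 2,
    "gap_B12_trnG": 26,
    "gap_trnG_nad6": 53,
    "gap_C8_C9": 53,
    "gap_trnP_rnl": 25,
}

ABSTRACT_UNIT_STRING = (
    "trnM_1-trnL_1-trnA-trnF-trnK-trnL_2-trnQ-trnH-trnM_2-nad2-nad3-atp9-"
    "cox2-trnR_1-nad4L-nad5-cob-trnC-cox1-trnR_2-nad1-nad4-atp8-atp6-rns-"
    "trnY-trnD-trnS_1-trnN-cox3-trnG-nad6-trnV-trnI-trnS_2-trnW-trnP-"
    "rnl(rps3)-trnT-trnE-trnM_3"
)

# Deterministic fixture layout: name -> (kind, start, end). Genomic order
# starts inside the rnl..trnM_3 run so that contig A's 1-5,664 interval
# fits, like the published linearization. tRNAs in the dense trnL_1..trnK
# cluster are 50 bp (the printed B1 interval holds five tRNAs in 236 bp);
# trnR_2 keeps its printed 71-bp span.
FIXTURE_COORDS: tuple[tuple[str, str, int, int], ...] = (
    ("rnl", "rRNA", 1, 4980),
    ("trnT", "tRNA", 5200, 5270),
    ("trnE", "tRNA", 5390, 5460),
    ("trnM_3", "tRNA", 5473, 5543),
    ("control_region", "control", 5544, 6124),
    ("trnM_1", "tRNA", 6125, 6195),
    ("trnL_1", "tRNA", 6198, 6247),
    ("trnA", "tRNA", 6250, 6299),
    ("trnF", "tRNA", 6302, 6351),
    ("trnK", "tRNA", 6355, 6404),
    ("trnL_2", "tRNA", 6408, 6478),
    ("trnQ", "tRNA", 6481, 6551),
    ("trnH", "tRNA", 6554, 6624),
    ("trnM_2", "tRNA", 6627, 6697),
    ("nad2", "PCG", 6699, 8297),
    ("nad3", "PCG", 8297, 8716),
    ("atp9", "PCG", 8748, 8972),
    ("cox2", "PCG", 9013, 9762),
    ("trnR_1", "tRNA", 9863, 9933),
    ("nad4L", "PCG", 10520, 10786),
    ("nad5", "PCG", 10786, 12756),
    ("cob", "PCG", 12790, 13971),
    ("trnC", "tRNA", 14230, 14300),
    ("cox1", "PCG", 14313, 17357),
    ("trnR_2", "tRNA", 17359, 17429),
    ("nad1", "PCG", 17431, 19746),
    ("nad4", "PCG", 19749, 20648),
    ("atp8", "PCG", 20661, 20807),
    ("atp6", "PCG", 20850, 21629),
    ("rns", "rRNA", 22150, 23569),
    ("trnY", "tRNA", 23920, 23963),
    ("trnD", "tRNA", 23967, 24037),
    ("trnS_1", "tRNA", 24048, 24118),
    ("trnN", "tRNA", 24121, 24191),
    ("cox3", "PCG", 24363, 25172),
    ("trnG", "tRNA", 25199, 25269),
    ("nad6", "PCG", 25323, 25922),
    ("trnV", "tRNA", 26280, 26350),
    ("trnI", "tRNA", 26353, 26423),
    ("trnS_2", "tRNA", 26426, 26496),
    ("trnW", "tRNA", 26499, 26569),
    ("trnP", "tRNA", 26572, 26642),
)

FIXTURE_LENGTH = 26667  # trnP end + 25-bp wrap gap back to rnl

_RNL_INTRON = (1601, 3400)
_RPS3 = (1700, 2899)


def _fill_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random sense codons (no internal stop) with mitochondrial AT bias."""
    bases = "AT" * 3 + "GC"  # ~75% AT
    out = []
    for _ in range(n_codons):
        while True:
            codon = "".join(rng.choice(list(bases), size=3))
            if codon not in ("TAA", "TAG", "TGA"):
                out.append(codon)
                break
    return "".join(out)


def _random_at_biased(rng: np.random.Generator, n: int, at: float = 0.73) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def beauveria_like_annotation(seed: int = 0, genome_id: str = "ATCC_90518") -> GenomeAnnotation:
    """Deterministic fixture genome + annotation honoring every printed
    anchor, with one group-I intron in rnl carrying the nested rps3 ORF."""
    rng = np.random.default_rng(seed)
    L = FIXTURE_LENGTH
    seq = list(_random_at_biased(rng, L))

    def put(start: int, text: str) -> None:
        seq[start - 1 : start - 1 + len(text)] = list(text)

    # protein-coding genes: ATG .. sense codons .. TAA
    for name, kind, s, e in FIXTURE_COORDS:
        if kind != "PCG":
            continue
        n = e - s + 1
        assert n % 3 == 0, name
        body = _fill_codons(rng, n // 3 - 2)
        put(s, "ATG" + body + "TAA")

    # rnl group-I intron: upstream exon ends T, intron is GT .. AG.
    i_s, i_e = _RNL_INTRON
    put(i_s - 1, "T")
    put(i_s, "GT")
    put(i_e - 1, "AG")
    # nested rps3 ORF inside the intron
    r_s, r_e = _RPS3
    n = r_e - r_s + 1
    put(r_s, "ATG" + _fill_codons(rng, n // 3 - 2) + "TAA")

    genome = CircularGenome(id=genome_id, sequence="".join(seq))
    feats = []
    for name, kind, s, e in FIXTURE_COORDS:
        introns = (_RNL_INTRON,) if name == "rnl" else ()
        feats.append(GeneFeature(name=name, kind=kind, start=s, end=e, introns=introns))
    feats.append(GeneFeature(name="rps3", kind="PCG", start=r_s, end=r_e, nested_in="rnl"))
    return GenomeAnnotation(genome=genome, features=tuple(feats))


def table2_dataframe() -> pd.DataFrame:
    return pd.DataFrame(
        list(TABLE2_CONTIGS),
        columns=["contig_id", "strain", "start", "end", "gene_content"],
    )
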