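"""Group-I intron boundary checks, in-silico splicing, and intron ORF scans.

Fungal mitochondrial group-I introns are flagged by a U (T on the DNA sense
strand) at the 3' end of the upstream exon and a G at the 3' end of the
intron; the splice dinucleotides are predominantly GT..AG. Both are reported
as independent boolean flags, never used as hard filters, because they are
tendencies of the intron class rather than absolutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome import CircularGenome, GeneFeature, GenomeAnnotation, circular_contains

__all__ = [
    "SpliceCheck",
    "IntronOrf",
    "IntronOrfReport",
    "check_splice_boundaries",
    "splice_gene",
    "scan_intron_orfs",
    "intron_presence_matrix",
]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SpliceCheck:
    """Boundary evaluation for one intron (DNA sense strand, U == T)."""

    gene: str
    intron: tuple[int, int]
    upstream_exon_last_base: str
    intron_last_base: str
    first_two: str
    last_two: str

    @property
    def group1_ok(self) -> bool:
        return self.upstream_exon_last_base == "T" and self.intron_last_base == "G"

    @property
    def gtag_ok(self) -> bool:
        return self.first_two == "GT" and self.last_two == "AG"


def check_splice_boundaries(gene: GeneFeature, genome: CircularGenome) -> list[SpliceCheck]:
    """One SpliceCheck per intron of ``gene``; both rules scored independently."""
    if not gene.introns:
        raise ValueError(f"{gene.name} has no introns")
    L = genome.length
    out = []
    for (s, e) in gene.introns:
        if not (circular_contains(gene.start, gene.end, s, L)
                and circular_contains(gene.start, gene.end, e, L)):
            raise ValueError(f"{gene.name}: intron ({s},{e}) outside gene span")
        out.append(
            SpliceCheck(
                gene=gene.name,
                intron=(s, e),
                upstream_exon_last_base=genome.base(s - 1).upper(),
                intron_last_base=genome.base(e).upper(),
                first_two=(genome.base(s) + genome.base(s + 1)).upper(),
                last_two=(genome.base(e - 1) + genome.base(e)).upper(),
            )
        )
    return out


def splice_gene(gene: GeneFeature, genome: CircularGenome) -> str:
    """Exon concatenation of the gene; identity for intronless genes."""
    return "".join(genome.fetch(s, e) for s, e in gene.exon_intervals(genome.length))


@dataclass(frozen=True)
class IntronOrf:
    frame: int  # 0..2, offset within the intron
    start: int  # genomic, 1-based, first base of ATG
    end: int    # genomic, 1-based, last base (stop codon or boundary-truncated)
    length_aa: int


@dataclass(frozen=True)
class IntronOrfReport:
    gene: str
    intron_index: int
    intron: tuple[int, int]
    orfs: tuple[IntronOrf, ...]

    @property
    def has_start_codon(self) -> bool:
        return bool(self.orfs)


def scan_intron_orfs(gene: GeneFeature, genome: CircularGenome, min_aa: int = 50) -> list[IntronOrfReport]:
    """Forward-frame ORFs (ATG .. stop/boundary) of >= min_aa codons inside
    each intron. An empty ORF list is the signal of intron ORF loss.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    L = genome.length
    reports = []
    for k, (s, e) in enumerate(gene.introns, start=1):
        seq = genome.fetch(s, e).upper()
        orfs: list[IntronOrf] = []
        for frame in range(3):
            i = frame
            while i + 3 <= len(seq):
                if seq[i : i + 3] != "ATG":
                    i += 3
                    continue
                j = i
                while j + 3 <= len(seq) and seq[j : j + 3] not in STOP_CODONS:
                    j += 3
                stop_included = j + 3 <= len(seq)
                end_idx = j + 3 if stop_included else j
                n_aa = (end_idx - i) // 3 - (1 if stop_included else 0)
                if n_aa >= min_aa:
                    orfs.append(
                        IntronOrf(
                            frame=frame,
                            start=(s - 1 + i) % L + 1,
                            end=(s - 1 + end_idx - 1) % L + 1,
                            length_aa=n_aa,
                        )
                    )
                i = end_idx if stop_included else len(seq)
        reports.append(IntronOrfReport(gene=gene.name, intron_index=k, intron=(s, e), orfs=tuple(orfs)))
    return reports


def _insertion_sites(ann: GenomeAnnotation) -> list[tuple[str, int]]:
    """(host gene, exon-space insertion coordinate) for every intron.

    The insertion coordinate is the number of exonic bases 5' of the intron,
    which is comparable across strains whose exon sequences are homologous.
    """
    L = ann.length
    sites = []
    for f in ann.features:
        if not f.introns or f.nested_in:
            continue
        gene_start = f.start
        exon_before = 0
        prev_end_u = gene_start - 1  # unrolled
        for (s, e) in f.introns:
            s_u = s if s >= gene_start else s + L
            e_u = e if e >= gene_start else e + L
            exon_before += s_u - prev_end_u - 1
            sites.append((f.name, exon_before))
            prev_end_u = e_u
    return sites


def intron_presence_matrix(
    annotations: dict[str, GenomeAnnotation] | Sequence[GenomeAnnotation],
    tolerance: int = 10,
) -> pd.DataFrame:
    """Strain x intron-site presence/absence matrix.

    Homologous insertion sites (same host gene, exon-space coordinate within
    ``tolerance`` bp) share a column, so row sums reproduce per-strain intron
    counts while columns expose which sites are shared between strains.
    """
    if not isinstance(annotations, dict):
        annotations = {ann.genome.id: ann for ann in annotations}
    if len(annotations) < 2:
        raise ValueError("need at least two annotations to compare")
    # cluster sites per host gene by insertion coordinate
    per_strain = {strain: _insertion_sites(ann) for strain, ann in annotations.items()}
    clusters: dict[str, list[int]] = {}
    for sites in per_strain.values():
        for gene, pos in sites:
            centers = clusters.setdefault(gene, [])
            if not any(abs(pos - c) <= tolerance for c in centers):
                centers.append(pos)
    for gene in clusters:
        clusters[gene].sort()
    columns = [f"{gene}@{c}" for gene in sorted(clusters) for c in clusters[gene]]
    df = pd.DataFrame(0, index=list(annotations), columns=columns, dtype=int)
    for strain, sites in per_strain.items():
        for gene, pos in sites:
            center = min(clusters[gene], key=lambda c: abs(pos - c))
            df.loc[strain, f"{gene}@{center}"] = 1
    return df
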