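"""Classify transcript evidence (reads and contigs) against an annotation.

Two kinds of evidence enter the pipeline and are treated uniformly as
intervals plus junction observations: per-read split alignments (SAM
dialect) and pre-assembled transcript contigs with gene-content labels
(the published table dialect). Read classes mirror the two read types seen
around introns — splicing reads spanning two exons, and reads mapped to
introns/exons and across their boundary — plus wrap-around reads that tie
the tail of a feature (or the genome) to its head.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .genome import (
    CircularGenome,
    GenomeAnnotation,
    circular_contains,
    circular_overlap,
    circular_span_length,
    locate,
)

__all__ = [
    "ReadAlignment",
    "EvidenceClass",
    "ContigAlignment",
    "PolyASite",
    "classify_read",
    "classify_contig",
    "gene_content_label",
    "detect_polyA",
    "gene_read_coverage",
    "CoverageReport",
    "parse_gene_content",
    "resolve_gene_content",
    "ContentResolutionError",
]


class EvidenceClass(str, Enum):
    PLAIN_EXONIC = "plain_exonic"
    SPLICING = "splicing"
    INTRON_CONTAINING = "intron_containing"
    WRAPAROUND = "wraparound"
    UNALIGNED = "unaligned"


@dataclass(frozen=True)
class ReadAlignment:
    """A (possibly split) read alignment.

    ``segments`` are (genome_start, genome_end, read_start, read_end),
    all 1-based inclusive, ordered by read coordinate.
    """

    read_id: str
    segments: tuple[tuple[int, int, int, int], ...]
    softclip_head: str = ""
    softclip_tail: str = ""


@dataclass(frozen=True)
class ContigAlignment:
    """One transcript contig aligned to a strain's mitogenome.

    ``gene_content`` holds the label tokens as supplied (e.g. from the
    published table); canonical resolution against an annotation happens in
    :func:`resolve_gene_content`. ``segments`` optionally refine the
    envelope interval into exon-projected pieces for contigs assembled from
    spliced transcripts.
    """

    contig_id: str
    strain: str
    start: int
    end: int
    gene_content: tuple[str, ...] = ()
    wraps_origin: bool = False
    segments: tuple[tuple[int, int], ...] = ()
    source_molecule: str | None = None

    def intervals(self) -> tuple[tuple[int, int], ...]:
        return self.segments if self.segments else ((self.start, self.end),)


@dataclass(frozen=True)
class PolyASite:
    position: int  # genomic position of the last templated base
    tail_length: int
    read_id: str | None = None


# ---------------------------------------------------------------------------
# gene-content labels
# ---------------------------------------------------------------------------

_TRN_TOKEN = re.compile(r"^(trn[A-Z])[_ ]?(\d)?$")


class ContentResolutionError(ValueError):
    pass


def parse_gene_content(label: str) -> list[str]:
    """Split a dash-separated gene-content label into tokens.

    Nested-gene notation like ``rnl(rps3)`` or ``rnl (rps3)`` collapses to
    the host token; thousands separators and surrounding whitespace are
    tolerated.
    """
    tokens = []
    for raw in label.replace("–", "-").split("-"):
        tok = raw.strip().replace(" ", "")
        if not tok:
            continue
        tok = re.sub(r"\(.*?\)", "", tok)  # drop nested-gene parenthetical
        tokens.append(tok)
    return tokens


def _token_key(token: str) -> tuple[str, int | None]:
    m = _TRN_TOKEN.match(token)
    if m:
        return m.group(1), int(m.group(2)) if m.group(2) else None
    return token, None


def resolve_gene_content(
    tokens: list[str] | tuple[str, ...],
    ann: GenomeAnnotation,
) -> tuple[list[str], list[str]]:
    """Resolve label tokens to canonical gene names by genomic position.

    Duplicate tRNA names map onto the canonical copy that makes the token
    list a contiguous run of the annotation's circular gene order (a printed
    subscript that contradicts its neighbours is overridden and flagged).
    Returns (canonical names, flags) where flags notes overridden tokens.

    Raises ContentResolutionError if a token names a gene absent from the
    annotation or no contiguous placement exists.
    """
    order = ann.gene_names()
    n = len(order)
    keys = [_token_key(t) for t in tokens]
    slot_keys = [_token_key(g) for g in order]
    known_bases = {b for b, _ in slot_keys}
    unknown = [t for t, (b, _) in zip(tokens, keys) if b not in known_bases]
    if unknown:
        raise ContentResolutionError(f"unknown gene name(s) in content label: {unknown}")
    best: tuple[int, list[str]] | None = None
    for off in range(n):
        window = [(off + i) % n for i in range(len(keys))]
        if any(slot_keys[w][0] != keys[i][0] for i, w in enumerate(window)):
            continue
        agreement = sum(
            1 for i, w in enumerate(window)
            if keys[i][1] is None or keys[i][1] == slot_keys[w][1]
        )
        if best is None or agreement > best[0]:
            best = (agreement, [order[w] for w in window])
    if best is None:
        raise ContentResolutionError(
            f"content label {list(tokens)} is not a contiguous run of the gene order"
        )
    resolved = best[1]
    flags = [
        f"token {tok!r} resolved to {name} by position"
        for tok, name, (b, idx) in zip(tokens, resolved, keys)
        if idx is not None and _token_key(name)[1] != idx
    ]
    return resolved, flags


def gene_content_label(interval: tuple[int, int], ann: GenomeAnnotation) -> list[str]:
    """Genes whose spans intersect the (possibly wrapping) interval, in
    genomic order; partial overlaps included. Monotone in the interval."""
    L = ann.length
    out = []
    for f in ann.genes():
        if circular_overlap(interval, (f.start, f.end), L):
            out.append(f.name)
    # order genes along the interval starting at its 5' end; a gene that
    # already covers the interval's first base sorts first
    start = interval[0]

    def key(name: str) -> int:
        f = ann.feature(name)
        if circular_contains(f.start, f.end, start, L):
            return 0
        return (f.start - start) % L

    out.sort(key=key)
    return out


# ---------------------------------------------------------------------------
# read and contig classification
# ---------------------------------------------------------------------------

def _intron_junctions(ann: GenomeAnnotation) -> list[tuple[int, int]]:
    out = []
    for f in ann.features:
        if f.nested_in is None:
            out.extend(f.introns)
    return out


def classify_read(
    r: ReadAlignment,
    ann: GenomeAnnotation,
    junction_tolerance: int = 3,
    min_wrap_arm: int = 20,
) -> EvidenceClass:
    """Assign exactly one evidence class to an aligned read.

    splicing: consecutive segments flank an annotated intron, their inner
    ends concordant with the intron boundaries within ``junction_tolerance``
    bp. intron_containing: any aligned base labels as intron (which covers
    alignments crossing an exon/intron boundary). wraparound: consecutive
    segments jump from the tail of a feature (or the genome) back to its
    head, both arms >= ``min_wrap_arm`` bases.
    """
    if not r.segments:
        return EvidenceClass.UNALIGNED
    L = ann.length
    introns = _intron_junctions(ann)
    # splicing: exon-adjacent segments across an annotated intron
    for (a, b) in zip(r.segments, r.segments[1:]):
        for (i_s, i_e) in introns:
            if (abs(a[1] - (i_s - 1)) <= junction_tolerance
                    and abs(b[0] - (i_e + 1)) <= junction_tolerance):
                return EvidenceClass.SPLICING
    # intron-containing: any aligned base inside an intron
    for (gs, ge, _, _) in r.segments:
        for (i_s, i_e) in introns:
            if circular_overlap((gs, ge), (i_s, i_e), L):
                return EvidenceClass.INTRON_CONTAINING
    # wraparound: tail->head jump within one feature or across the origin
    for (a, b) in zip(r.segments, r.segments[1:]):
        arm_a = a[1] - a[0] + 1
        arm_b = b[1] - b[0] + 1
        if arm_a < min_wrap_arm or arm_b < min_wrap_arm:
            continue
        if b[0] < a[0]:  # genomic jump backwards in read order
            for f in ann.top_level():
                if (circular_contains(f.start, f.end, a[1], L)
                        and circular_contains(f.start, f.end, b[0], L)):
                    return EvidenceClass.WRAPAROUND
            return EvidenceClass.WRAPAROUND  # across the genome origin
    return EvidenceClass.PLAIN_EXONIC


def classify_contig(c: ContigAlignment, ann: GenomeAnnotation) -> str:
    """intron_containing iff the contig's aligned interval(s) cover at least
    one annotated intron base, else intron_free. Spliced-projection contigs
    (exon segments with gaps at introns) therefore classify intron_free."""
    L = ann.length
    for (i_s, i_e) in _intron_junctions(ann):
        for iv in c.intervals():
            if circular_overlap(iv, (i_s, i_e), L):
                return "intron_containing"
    return "intron_free"


def detect_polyA(
    r: ReadAlignment,
    ann: GenomeAnnotation | CircularGenome,
    min_tail: int = 6,
) -> PolyASite | None:
    """PolyA site from a 3' soft-clip: the clip must be an A-run of at least
    ``min_tail`` bases with at most one mismatch, and must not itself be
    genome-templated (the genomic continuation is not the same A-run)."""
    tail = r.softclip_tail.upper()
    if len(tail) < min_tail or not r.segments:
        return None
    if sum(1 for b in tail if b != "A") > 1:
        return None
    genome = ann.genome if isinstance(ann, GenomeAnnotation) else ann
    last = r.segments[-1][1]
    continuation = "".join(genome.base(last + 1 + i) for i in range(len(tail)))
    if sum(1 for b in continuation.upper() if b != "A") <= 1:
        return None  # tail could be templated by a genomic A-run
    return PolyASite(position=last, tail_length=len(tail), read_id=r.read_id)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageReport:
    per_gene: dict[str, tuple[bool, float]]  # name -> (covered, exon fraction)
    genome_fraction: float

    def uncovered(self) -> list[str]:
        return [g for g, (cov, _) in self.per_gene.items() if not cov]


def gene_read_coverage(evidence: list, ann: GenomeAnnotation) -> CoverageReport:
    """Per-gene covered flags and exon-space covered fractions, plus the
    genome-wide covered fraction (all positions).

    For contigs that carry gene-content labels the covered flag comes from
    the labels (pooled across strains); positional fractions use the aligned
    intervals. Label-less contigs and reads contribute positionally.
    """
    L = ann.length
    labeled_genes: set[str] = set()
    intervals: list[tuple[int, int]] = []
    for ev in evidence:
        if isinstance(ev, ContigAlignment):
            if ev.gene_content:
                resolved, _ = resolve_gene_content(ev.gene_content, ann)
                labeled_genes.update(resolved)
            intervals.extend(ev.intervals())
        elif isinstance(ev, ReadAlignment):
            intervals.extend((gs, ge) for gs, ge, _, _ in ev.segments)
        else:
            intervals.append(tuple(ev))

    covered = bytearray(L)
    for (s, e) in intervals:
        s_u, e_u = (s, e) if s <= e else (s, e + L)
        for p in range(s_u, e_u + 1):
            covered[(p - 1) % L] = 1

    has_labels = bool(labeled_genes)
    per_gene: dict[str, tuple[bool, float]] = {}
    for f in ann.genes():
        exon_pos = 0
        exon_cov = 0
        for (s, e) in f.exon_intervals(L):
            n = circular_span_length(s, e, L)
            exon_pos += n
            s_u, e_u = (s, e) if s <= e else (s, e + L)
            exon_cov += sum(covered[(p - 1) % L] for p in range(s_u, e_u + 1))
        frac = exon_cov / exon_pos if exon_pos else 0.0
        flag = f.name in labeled_genes if has_labels else exon_cov > 0
        per_gene[f.name] = (flag, frac)
    return CoverageReport(per_gene=per_gene, genome_fraction=sum(covered) / L)
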