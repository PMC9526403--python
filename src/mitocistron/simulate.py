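"""Synthetic mitogenome, transcription and evidence generator with truth.

The generator emulates the RNA-processing model the inference is built to
detect: one or more polycistronic transcription units are transcribed from
a circular, single-strand mitogenome; a polyA tail is added to the growing
polycistronic transcript *before* splicing (so polyadenylated molecules can
still contain group-I introns); introns are then spliced; finally the
punctuation tRNAs are cleaved out, releasing mono-/di-/tri- and longer
oligocistronic RNAs and leaving coverage holes where a cleaved tRNA escaped
sequencing. Transcript contigs are produced by fragmenting the surviving
molecules into partially overlapping pieces, mimicking short-read de novo
assembly; every emitted record is tied back to ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .evidence import ContigAlignment, ReadAlignment, gene_content_label
from .fixtures import (
    CANONICAL_GENE_ORDER,
    TABLE1_INTRON_COUNTS,
    _fill_codons,
    _random_at_biased,
)
from .genome import CircularGenome, GeneFeature, GenomeAnnotation, locate

__all__ = [
    "SimConfig",
    "SimTruth",
    "Molecule",
    "make_genome",
    "simulate_processing",
    "fragment_to_evidence",
    "simulate",
    "intron_plan_for",
]

# canonical intron insertion points, as fractions of the host gene's exonic
# length; a strain with c introns in a gene uses the first c sites, so the
# sites are homologous across strains sharing a layout seed
_INTRON_SITE_FRACTIONS = (0.35, 0.65, 0.85)


def intron_plan_for(strain: str) -> dict[str, int]:
    """Intron plan (gene -> count) from the published per-strain profiles."""
    row = TABLE1_INTRON_COUNTS.loc[strain]
    return {gene: int(n) for gene, n in row.items() if n > 0}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated strain.

    ``unit_breaks`` lists gene pairs whose junction is a transcription-unit
    boundary (the control-region junction is always a boundary); K planted
    units need K-1 breaks. ``trna_cleavage_dropout`` is the probability a
    cleaved punctuation tRNA leaves no sequence evidence.
    """

    seed: int = 0
    strain: str = "sim"
    gene_order: tuple[str, ...] = CANONICAL_GENE_ORDER
    intron_plan: dict[str, int] = field(
        default_factory=lambda: {"rnl": 1, "cox2": 1, "cob": 1}
    )
    unit_breaks: tuple[tuple[str, str], ...] = ()
    polyA_before_splicing: bool = True
    trna_cleavage_dropout: float = 0.5
    mean_contig_length: int = 1500
    coverage_gap_rate: float = 0.1
    at_percent: float = 73.0
    control_length: int = 300
    trna_length: int = 71
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if sorted(self.gene_order) != sorted(set(self.gene_order)):
            raise ValueError("gene_order contains duplicates")
        if not 0.0 <= self.trna_cleavage_dropout <= 1.0:
            raise ValueError("dropout must be a probability")


@dataclass
class Molecule:
    """One RNA molecule at a given processing stage.

    ``footprint`` holds unrolled genomic intervals (1-based inclusive; end
    may exceed the genome length for origin-wrapping molecules), in 5'->3'
    transcript order.
    """

    molecule_id: str
    stage: str  # polyA_unspliced | polyA_spliced | oligocistronic | tRNA
    footprint: tuple[tuple[int, int], ...]
    genes: tuple[str, ...]
    polyadenylated: bool
    contains_intron: bool

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.footprint)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data."""

    config: SimConfig
    units: tuple[tuple[str, ...], ...]
    intron_intervals: dict[str, tuple[tuple[int, int], ...]]
    gene_exonic_seq: dict[str, str]
    tss_extension: int
    molecules: list[Molecule] = field(default_factory=list)
    cleaved_trnas: tuple[str, ...] = ()
    dropped_trnas: tuple[str, ...] = ()
    polyA_positions: tuple[int, ...] = ()
    contig_provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _gene_kind(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name in ("rnl", "rns"):
        return "rRNA"
    return "PCG"


def _gap_length(rng: np.random.Generator, up_kind: str, down_kind: str, is_break: bool,
                delta: int = 60) -> int:
    if is_break:
        return int(rng.integers(2 * delta, 6 * delta))
    if up_kind == "tRNA" and down_kind == "tRNA":
        return int(rng.integers(2, 4))
    if "tRNA" in (up_kind, down_kind):
        return int(rng.integers(5, 56))
    return int(rng.integers(25, 151))


def _pick_insertion(exon_seq: str, target: int) -> int:
    """Offset (0-based, number of exon bases before the intron) whose
    preceding exon base is T, at or after ``target``; canonical group-I
    introns insert after a U residue."""
    n = len(exon_seq)
    for i in range(target, n - 4):
        if exon_seq[i - 1] == "T":
            return i
    for i in range(4, n - 4):
        if exon_seq[i - 1] == "T":
            return i
    raise ValueError("no T residue available for intron insertion")


def make_genome(cfg: SimConfig) -> tuple[CircularGenome, GenomeAnnotation, SimTruth]:
    """Build a synthetic circular mitogenome, its annotation, and truth.

    Genes are laid out in ``cfg.gene_order`` with the control region
    appended after the final gene; intergenic gaps follow the punctuation
    geometry (2-3 bp inside tRNA clusters, <= 55 bp flanking tRNAs, 25-150
    bp elsewhere, and 120-360 bp at planted unit boundaries so breaks are
    not trivially re-bridgeable). Introns are planted with canonical
    boundaries (upstream exon ends in T; intron GT..AG); if rnl carries an
    intron the first one embeds an rps3 ORF as a nested gene.
    """
    rng = np.random.default_rng(cfg.seed)
    order = list(cfg.gene_order)
    unknown = set(cfg.intron_plan) - set(order)
    if unknown:
        raise ValueError(f"intron plan names genes outside the order: {sorted(unknown)}")

    # exonic gene sequences (shared across strains with the same seed)
    exonic: dict[str, str] = {}
    for g in order:
        kind = _gene_kind(g)
        if kind == "tRNA":
            exonic[g] = _random_at_biased(rng, cfg.trna_length)
        elif g == "rnl":
            exonic[g] = _random_at_biased(rng, 3600)
        elif g == "rns":
            exonic[g] = _random_at_biased(rng, 1400)
        else:
            n_codons = int(rng.integers(100, 500))
            exonic[g] = "ATG" + _fill_codons(rng, n_codons) + "TAA"

    gaps: list[int] = []
    breaks = {tuple(b) for b in cfg.unit_breaks}
    for i, g in enumerate(order):
        nxt = order[(i + 1) % len(order)]
        is_break = (g, nxt) in breaks
        gaps.append(_gap_length(rng, _gene_kind(g), _gene_kind(nxt), is_break))

    # intron sequences drawn from child generators keyed by (gene, ordinal),
    # so panels of strains differing only in their plans stay homologous
    gene_seqs: dict[str, str] = {}
    intron_rel: dict[str, list[tuple[int, int]]] = {}
    rps3_rel: tuple[str, int, int] | None = None
    for g in order:
        seq = exonic[g]
        count = cfg.intron_plan.get(g, 0)
        if not count:
            gene_seqs[g] = seq
            continue
        inserts = []
        for k in range(count):
            sub = np.random.default_rng([cfg.seed, 7, k, zlib.crc32(g.encode())])
            target = int(len(seq) * _INTRON_SITE_FRACTIONS[k % len(_INTRON_SITE_FRACTIONS)])
            offset = _pick_insertion(seq, target)
            if g == "rnl" and k == 0:
                body = _random_at_biased(sub, 1500 - 4)
                orf = "ATG" + _fill_codons(sub, 298) + "TAA"
                body = body[:60] + orf + body[60 + len(orf):]
                iseq = "GT" + body + "AG"
                rps3_off = 2 + 60  # within the intron sequence
            else:
                ilen = int(sub.integers(300, 901))
                iseq = "GT" + _random_at_biased(sub, ilen - 4) + "AG"
                rps3_off = None
            inserts.append((offset, iseq, rps3_off))
        inserts.sort(key=lambda t: t[0])
        out = []
        cursor = 0
        rel_introns = []
        shift = 0
        for offset, iseq, rps3_off in inserts:
            out.append(seq[cursor:offset])
            rel_introns.append((offset + shift, offset + shift + len(iseq) - 1))
            if rps3_off is not None:
                rps3_rel = (g, offset + shift + rps3_off, offset + shift + rps3_off + 900 - 1)
            out.append(iseq)
            shift += len(iseq)
            cursor = offset
        out.append(seq[cursor:])
        gene_seqs[g] = "".join(out)
        intron_rel[g] = rel_introns

    # assemble: gene, gap, gene, ..., last gene, gap, control, gap
    pieces: list[str] = []
    coords: dict[str, tuple[int, int]] = {}
    pos = 1
    for i, g in enumerate(order):
        s = gene_seqs[g]
        coords[g] = (pos, pos + len(s) - 1)
        pieces.append(s)
        pos += len(s)
        if i < len(order) - 1:
            gap = gaps[i]
        else:
            gap = int(rng.integers(20, 81))
        pieces.append(_random_at_biased(rng, gap))
        pos += gap
    control_start = pos
    pieces.append(_random_at_biased(rng, cfg.control_length))
    pos += cfg.control_length
    coords["__control__"] = (control_start, pos - 1)
    pieces.append(_random_at_biased(rng, int(rng.integers(20, 81))))
    sequence = "".join(pieces)
    L = len(sequence)

    # optional rotation of the origin
    off = cfg.origin_offset % L
    if off:
        sequence = sequence[off:] + sequence[:off]

    def shift_pos(p: int) -> int:
        return (p - 1 - off) % L + 1

    feats = []
    introns_by_gene: dict[str, tuple[tuple[int, int], ...]] = {}
    for g in order:
        s, e = coords[g]
        gs, ge = shift_pos(s), shift_pos(e)
        g_introns = tuple(
            (shift_pos(s + rs), shift_pos(s + re))
            for rs, re in intron_rel.get(g, [])
        )
        introns_by_gene[g] = g_introns
        feats.append(GeneFeature(
            name=g, kind=_gene_kind(g), start=gs, end=ge,
            wraps_origin=gs > ge, introns=g_introns,
        ))
    cs, ce = coords["__control__"]
    cs, ce = shift_pos(cs), shift_pos(ce)
    feats.append(GeneFeature(name="control_region", kind="control", start=cs, end=ce,
                             wraps_origin=cs > ce))
    if rps3_rel is not None:
        host, rs, re = rps3_rel
        hs = coords[host][0]
        ps, pe = shift_pos(hs + rs), shift_pos(hs + re)
        feats.append(GeneFeature(name="rps3", kind="PCG", start=ps, end=pe,
                                 wraps_origin=ps > pe, nested_in=host))

    genome = CircularGenome(id=cfg.strain, sequence=sequence)
    ann = GenomeAnnotation(genome=genome, features=tuple(feats))

    # planted units: runs of the gene order between breaks (the control
    # junction between order[-1] and order[0] is always a boundary)
    units: list[list[str]] = [[]]
    for i, g in enumerate(order):
        units[-1].append(g)
        nxt = order[(i + 1) % len(order)]
        if (g, nxt) in breaks and i < len(order) - 1:
            units.append([])
    truth = SimTruth(
        config=cfg,
        units=tuple(tuple(u) for u in units),
        intron_intervals={g: iv for g, iv in introns_by_gene.items() if iv},
        gene_exonic_seq=exonic,
        tss_extension=int(rng.integers(60, 201)),
    )
    return genome, ann, truth


# ---------------------------------------------------------------------------
# transcription and RNA processing
# ---------------------------------------------------------------------------

def _unrolled_span(ann: GenomeAnnotation, name: str, after: int | None = None) -> tuple[int, int]:
    f = ann.feature(name)
    L = ann.length
    s, e = f.start, f.end
    if e < s:
        e += L
    if after is not None:
        while s < after:
            s += L
            e += L
    return s, e


def _subtract_intervals(span: tuple[int, int], cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    cursor = span[0]
    for cs, ce in sorted(cuts):
        if ce < span[0] or cs > span[1]:
            continue
        if cs > cursor:
            out.append((cursor, cs - 1))
        cursor = max(cursor, ce + 1)
    if cursor <= span[1]:
        out.append((cursor, span[1]))
    return out


def simulate_processing(ann: GenomeAnnotation, truth: SimTruth) -> list[Molecule]:
    """Derive the molecule population from the planted units.

    Stage order with polyA-before-splicing: polyadenylation of the primary
    polycistron, then splicing, then tRNA-punctuation cleavage; the
    polyadenylated-but-unspliced intermediate is part of the population, so
    intron-containing polyadenylated molecules exist. With the reverse
    order (splice-first), every polyadenylated molecule is already spliced
    and no such intermediate is possible.
    """
    cfg = truth.config
    L = ann.length
    molecules: list[Molecule] = []
    cleaved: list[str] = []
    polyA_pos: list[int] = []
    control = ann.control
    for ui, unit in enumerate(truth.units):
        first_s, first_e = _unrolled_span(ann, unit[0])
        spans = [(unit[0], first_s, first_e)]
        cursor = first_s
        for g in unit[1:]:
            s, e = _unrolled_span(ann, g, after=cursor)
            spans.append((g, s, e))
            cursor = s
        start = spans[0][1]
        end = max(e for _, _, e in spans)
        # the unit abutting the control region starts inside it (TSS in
        # control): extend its 3' end into the control region as well, the
        # signal the terminal contig shows
        is_control_adjacent = control is not None and unit[-1] == cfg.gene_order[-1]
        ext = truth.tss_extension if is_control_adjacent else 0
        end3 = end + ext
        polyA_pos.append((end3 - 1) % L + 1)
        has_intron = any(g in truth.intron_intervals for g in unit)
        if cfg.polyA_before_splicing and has_intron:
            molecules.append(Molecule(
                molecule_id=f"u{ui}.polyA_unspliced", stage="polyA_unspliced",
                footprint=((start, end3),), genes=tuple(unit),
                polyadenylated=True, contains_intron=True,
            ))
        # splice: remove intron intervals (unrolled against each gene span)
        cuts = []
        for g, s, e in spans:
            f = ann.feature(g)
            gs = s
            for (i_s, i_e) in f.introns:
                rel_s = (i_s - f.start) % L
                rel_e = (i_e - f.start) % L
                cuts.append((gs + rel_s, gs + rel_e))
        spliced = _subtract_intervals((start, end3), cuts)
        # cleavage at punctuation tRNAs
        trna_cuts = []
        for g, s, e in spans:
            if _gene_kind(g) == "tRNA":
                trna_cuts.append((g, s, e))
                cleaved.append(g)
                molecules.append(Molecule(
                    molecule_id=f"u{ui}.trna.{g}", stage="tRNA",
                    footprint=((s, e),), genes=(g,),
                    polyadenylated=False, contains_intron=False,
                ))
        remaining = spliced
        for _, s, e in trna_cuts:
            remaining = [iv for piece in remaining for iv in _subtract_intervals(piece, [(s, e)])]
        # group contiguous spliced pieces into oligocistronic molecules:
        # pieces separated only by an excised intron stay joined; pieces
        # separated by a cleaved tRNA are distinct molecules
        groups: list[list[tuple[int, int]]] = []
        for iv in sorted(remaining):
            new_group = True
            if groups:
                gap_iv = (groups[-1][-1][1] + 1, iv[0] - 1)
                if gap_iv[1] >= gap_iv[0]:
                    if any(cs <= gap_iv[0] and ce >= gap_iv[1] for cs, ce in cuts):
                        new_group = False
                else:
                    new_group = False
            if new_group:
                groups.append([iv])
            else:
                groups[-1].append(iv)
        for gi, group in enumerate(groups):
            genes = tuple(
                g for g, s, e in spans
                if _gene_kind(g) != "tRNA"
                and any(not (e < iv[0] or s > iv[1]) for iv in group)
            )
            is_last = group[-1][1] == max(iv[1] for grp in groups for iv in grp)
            molecules.append(Molecule(
                molecule_id=f"u{ui}.olig.{gi}", stage="oligocistronic",
                footprint=tuple(group), genes=genes,
                polyadenylated=is_last, contains_intron=False,
            ))
    truth.molecules = molecules
    truth.cleaved_trnas = tuple(cleaved)
    truth.polyA_positions = tuple(polyA_pos)
    return molecules


# ---------------------------------------------------------------------------
# evidence emission
# ---------------------------------------------------------------------------

def _fold(iv: tuple[int, int], L: int) -> tuple[int, int, bool]:
    s = (iv[0] - 1) % L + 1
    e = (iv[1] - 1) % L + 1
    return s, e, iv[1] - iv[0] + 1 < L and s > e


def _transcript_to_genomic(footprint, t0: int, t1: int) -> list[tuple[int, int]]:
    """Map transcript-space interval [t0, t1] (1-based) onto the molecule's
    unrolled genomic segments."""
    out = []
    offset = 0
    for s, e in footprint:
        n = e - s + 1
        lo, hi = max(t0, offset + 1), min(t1, offset + n)
        if hi >= lo:
            out.append((s + lo - offset - 1, s + hi - offset - 1))
        offset += n
    return out


def fragment_to_evidence(
    molecules: list[Molecule],
    ann: GenomeAnnotation,
    truth: SimTruth,
) -> tuple[list[ContigAlignment], list[ReadAlignment]]:
    """Fragment the molecule population into contigs and alignment records.

    Oligocistronic molecules are tiled into overlapping contigs; assembly
    breakpoints (coverage gaps) fall inside genes, mimicking the published
    contig pairs broken within one coding region. Cleaved tRNAs drop out
    of the evidence with the configured probability. The polyadenylated
    unspliced intermediate contributes boundary-localized contigs around
    each intron plus a 3' polyA-tailed read; wrap-around reads are emitted
    for molecules crossing the genome origin.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    L = ann.length
    contigs: list[ContigAlignment] = []
    reads: list[ReadAlignment] = []
    dropped: list[str] = []
    counter = 0

    def add_contig(mol: Molecule, segs: list[tuple[int, int]]) -> None:
        nonlocal counter
        counter += 1
        cid = f"ctg{counter}"
        s0, _, _ = _fold(segs[0], L)
        _, e1, _ = _fold(segs[-1], L)
        folded = []
        for iv in segs:
            fs, fe, wraps = _fold(iv, L)
            if wraps:
                folded.extend([(fs, L), (1, fe)])
            else:
                folded.append((fs, fe))
        content: list[str] = []
        for fs, fe in folded:
            for g in gene_content_label((fs, fe), ann):
                if g not in content:
                    content.append(g)
        contigs.append(ContigAlignment(
            contig_id=cid, strain=cfg.strain, start=s0, end=e1,
            gene_content=tuple(content), wraps_origin=s0 > e1,
            segments=tuple(folded), source_molecule=mol.molecule_id,
        ))
        truth.contig_provenance[cid] = mol.molecule_id

    def add_polyA_read(mol: Molecule) -> None:
        nonlocal counter
        counter += 1
        last_s, last_e = mol.footprint[-1]
        seg_s = max(last_s, last_e - 79)
        gs, ge, wraps = _fold((seg_s, last_e), L)
        if wraps:
            arm1 = L - gs + 1
            segs = ((gs, L, 1, arm1), (1, ge, arm1 + 1, arm1 + ge))
        else:
            segs = ((gs, ge, 1, ge - gs + 1),)
        reads.append(ReadAlignment(
            read_id=f"polyA.{mol.molecule_id}",
            segments=segs,
            softclip_tail="A" * 10,
        ))

    for mol in molecules:
        if mol.stage == "tRNA":
            if rng.random() < cfg.trna_cleavage_dropout:
                dropped.append(mol.genes[0])
                continue
            add_contig(mol, list(mol.footprint))
            continue
        if mol.stage == "polyA_unspliced":
            # boundary-localized evidence: one contig around each intron
            for g in mol.genes:
                f = ann.feature(g)
                for (i_s, i_e) in f.introns:
                    s_u, e_u = i_s, i_e if i_e >= i_s else i_e + L
                    add_contig(mol, [(s_u - 150, e_u + 150)])
                    # a read crossing the exon/intron boundary
                    reads.append(ReadAlignment(
                        read_id=f"boundary.{g}.{i_s}",
                        segments=(((i_s - 50 - 1) % L + 1, (i_s + 48 - 1) % L + 1, 1, 99),),
                    ))
            add_polyA_read(mol)
            continue
        # oligocistronic molecules: overlapping tiling with intra-gene gaps
        T = mol.length
        t = 1
        while t <= T:
            ln = int(rng.normal(cfg.mean_contig_length, cfg.mean_contig_length / 5))
            ln = max(300, min(ln, 4000))
            t1 = min(T, t + ln - 1)
            segs = _transcript_to_genomic(mol.footprint, t, t1)
            if segs:
                add_contig(mol, segs)
            if t1 >= T:
                break
            overlap = int(rng.integers(20, 121))
            nxt = t1 - overlap + 1
            if rng.random() < cfg.coverage_gap_rate:
                gap = int(rng.integers(100, 601))
                cand = t1 + gap
                probe = _transcript_to_genomic(mol.footprint, cand, cand)
                if probe and cand < T:
                    pos = (probe[0][0] - 1) % L + 1
                    loc = locate(pos, ann)
                    end_loc = locate((_transcript_to_genomic(mol.footprint, t1, t1)[0][0] - 1) % L + 1, ann)
                    if loc.kind == "exon" and end_loc.kind == "exon" and loc.gene == end_loc.gene:
                        nxt = cand
            t = max(nxt, t + 1)
        if mol.polyadenylated:
            add_polyA_read(mol)
        # splicing reads at each excised intron boundary
        for g in mol.genes:
            f = ann.feature(g)
            for (i_s, i_e) in f.introns:
                reads.append(ReadAlignment(
                    read_id=f"splice.{g}.{i_s}",
                    segments=(
                        ((i_s - 40 - 1) % L + 1, (i_s - 2) % L + 1, 1, 40),
                        ((i_e) % L + 1, (i_e + 40 - 1) % L + 1, 41, 80),
                    ),
                ))
        # wrap-around reads for origin-crossing molecules
        if any(e > L for _, e in mol.footprint):
            for s, e in mol.footprint:
                if s <= L < e and e - L >= 20:
                    arm2 = min(40, e - L)
                    reads.append(ReadAlignment(
                        read_id=f"wrap.{mol.molecule_id}",
                        segments=(
                            (L - 39, L, 1, 40),
                            (1, arm2, 41, 40 + arm2),
                        ),
                    ))
                    break
    truth.dropped_trnas = tuple(dropped)
    return contigs, reads


def simulate(cfg: SimConfig) -> tuple[GenomeAnnotation, SimTruth, list[ContigAlignment], list[ReadAlignment]]:
    """End-to-end convenience: genome -> processing -> evidence."""
    _, ann, truth = make_genome(cfg)
    molecules = simulate_processing(ann, truth)
    contigs, reads = fragment_to_evidence(molecules, ann, truth)
    return ann, truth, contigs, reads
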