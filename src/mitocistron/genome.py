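"""Circular mitogenome data model and descriptive statistics.

Coordinates are 1-based inclusive throughout, matching GFF3 and the table
dialect used for transcript contigs. A feature may wrap the origin of the
circular molecule (``wraps_origin``); all interval arithmetic is performed on
the rotation that makes the operands contiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CircularGenome",
    "GeneFeature",
    "GenomeAnnotation",
    "CompositionStats",
    "RegionCatalogue",
    "Location",
    "composition_stats",
    "gap_between",
    "region_catalogue",
    "intron_count_table",
    "locate",
    "reverse_complement",
    "circular_span_length",
    "circular_contains",
    "circular_overlap",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Intron count table columns in the order mitochondrial genes host introns
# in Beauveria; extra host genes get appended columns.
DEFAULT_INTRON_HOSTS = ("rnl", "cox2", "nad5", "cob", "cox1", "nad1")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# circular interval arithmetic
# ---------------------------------------------------------------------------

def circular_span_length(start: int, end: int, length: int) -> int:
    """Number of bases in the 1-based inclusive interval [start, end] on a
    circle of ``length`` bp; the interval may wrap the origin (end < start)."""
    if start <= end:
        return end - start + 1
    return (length - start + 1) + end


def _unroll(start: int, end: int, length: int) -> tuple[int, int]:
    """Linearize an interval: returns (start, end') with end' >= start,
    where end' may exceed ``length`` for a wrapping interval."""
    if start <= end:
        return start, end
    return start, end + length


def circular_contains(start: int, end: int, pos: int, length: int) -> bool:
    s, e = _unroll(start, end, length)
    return s <= pos <= e or s <= pos + length <= e


def circular_overlap(a: tuple[int, int], b: tuple[int, int], length: int) -> int:
    """Number of positions shared by two circular intervals."""
    s1, e1 = _unroll(*a, length)
    s2, e2 = _unroll(*b, length)
    shared = 0
    # compare on three rotations to catch wrap alignment
    for shift in (-length, 0, length):
        lo = max(s1, s2 + shift)
        hi = min(e1, e2 + shift)
        if hi >= lo:
            shared += hi - lo + 1
    # intervals longer than the circle are invalid; shared can't exceed spans
    return min(shared, circular_span_length(*a, length), circular_span_length(*b, length))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA molecule with 1-based coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for the (possibly wrapping) interval [start, end]."""
        L = self.length
        if not (1 <= start <= L and 1 <= end <= L):
            raise ValueError(f"interval ({start}, {end}) outside 1..{L}")
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def base(self, pos: int) -> str:
        """Base at 1-based position, with circular wrap for out-of-range."""
        return self.sequence[(pos - 1) % self.length]


@dataclass(frozen=True)
class GeneFeature:
    """A gene (or control region) on the positive strand of the mitogenome.

    ``introns`` are (start, end) 1-based inclusive genomic intervals inside
    the feature span, ordered 5'->3'. ``nested_in`` marks features encoded
    inside another feature's intron (rps3 inside the conserved rnl intron);
    nested features are excluded from top-level gene order.
    """

    name: str
    kind: str  # PCG | tRNA | rRNA | control
    start: int
    end: int
    wraps_origin: bool = False
    nested_in: str | None = None
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("PCG", "tRNA", "rRNA", "control"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(f"{self.name}: start > end without wraps_origin")

    def span_length(self, genome_length: int) -> int:
        return circular_span_length(self.start, self.end, genome_length)

    def intron_length(self, genome_length: int) -> int:
        return sum(circular_span_length(s, e, genome_length) for s, e in self.introns)

    def exon_intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Exonic genomic intervals (feature span minus introns), 5'->3'."""
        s, e = _unroll(self.start, self.end, genome_length)
        cursor = s
        out: list[tuple[int, int]] = []
        for i_start, i_end in self.introns:
            i_s, i_e = _unroll(i_start, i_end, genome_length)
            if i_s < s:
                i_s += genome_length
                i_e += genome_length
            if not (s <= i_s <= i_e <= e):
                raise ValueError(f"{self.name}: intron ({i_start},{i_end}) outside span")
            if i_s > cursor:
                out.append((cursor, i_s - 1))
            cursor = i_e + 1
        if cursor <= e:
            out.append((cursor, e))
        # fold back onto the circle
        folded = []
        for a, b in out:
            a2 = (a - 1) % genome_length + 1
            b2 = (b - 1) % genome_length + 1
            folded.append((a2, b2))
        return folded


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered single-strand feature set over a circular genome."""

    genome: CircularGenome
    features: tuple[GeneFeature, ...]

    def __post_init__(self) -> None:
        L = self.genome.length
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in annotation")
        for f in self.features:
            if not (1 <= f.start <= L and 1 <= f.end <= L):
                raise ValueError(f"{f.name}: coordinates outside 1..{L}")
        controls = [f for f in self.features if f.kind == "control"]
        if len(controls) > 1:
            raise ValueError("annotation must contain at most one control region")

    @property
    def length(self) -> int:
        return self.genome.length

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def control(self) -> GeneFeature | None:
        for f in self.features:
            if f.kind == "control":
                return f
        return None

    def top_level(self, include_control: bool = True) -> list[GeneFeature]:
        """Features in genomic order (by start, wrap-aware), nested excluded."""
        feats = [f for f in self.features if f.nested_in is None]
        if not include_control:
            feats = [f for f in feats if f.kind != "control"]
        return sorted(feats, key=lambda f: f.start)

    def genes(self) -> list[GeneFeature]:
        """Top-level genes (control region excluded) in genomic order."""
        return self.top_level(include_control=False)

    def gene_names(self) -> list[str]:
        return [f.name for f in self.genes()]

    def nested_map(self) -> dict[str, str]:
        """host name -> nested feature name (e.g. rnl -> rps3)."""
        return {f.nested_in: f.name for f in self.features if f.nested_in}


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionStats:
    counts: dict[str, int]
    at_percent: float
    at_skew: float | None
    gc_skew: float | None

    @property
    def gc_percent(self) -> float:
        a, c, g, t = (self.counts[b] for b in "ACGT")
        total = a + c + g + t
        return 100.0 * (g + c) / total if total else math.nan


def composition_stats(seq: str) -> CompositionStats:
    """Base counts, AT%, and Perna & Kocher strand-skew statistics.

    AT-skew = (A - T)/(A + T); GC-skew = (G - C)/(G + C). N bases are
    excluded from every denominator; a skew with zero denominator is
    reported as missing (None).
    """
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    counts = {b: up.count(b) for b in "ACGTN"}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    acgt = a + c + g + t
    at_percent = 100.0 * (a + t) / acgt if acgt else math.nan
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionStats(counts=counts, at_percent=at_percent, at_skew=at_skew, gc_skew=gc_skew)


# ---------------------------------------------------------------------------
# gaps, overlaps and the region catalogue
# ---------------------------------------------------------------------------

def _as_interval(x) -> tuple[int, int]:
    if isinstance(x, GeneFeature):
        return x.start, x.end
    s, e = x
    return int(s), int(e)


def gap_between(a, b, genome: CircularGenome | int) -> int:
    """Bases strictly between interval/feature ``a`` and its circular
    successor ``b``: start(b) - end(a) - 1 on the rotation making the pair
    contiguous. Overlapping operands yield a negative value whose magnitude
    is the overlap in bp.
    """
    L = genome if isinstance(genome, int) else genome.length
    ia, ib = _as_interval(a), _as_interval(b)
    if ia == ib:
        raise ValueError("gap_between: identical intervals")
    shared = circular_overlap(ia, ib, L)
    if shared:
        return -shared
    return (ib[0] - ia[1] - 1) % L


@dataclass(frozen=True)
class RegionCatalogue:
    """Classification of every adjacent top-level feature pair."""

    intergenic: tuple[tuple[str, str, int], ...]
    overlaps: tuple[tuple[str, str, int], ...]
    abutting: tuple[tuple[str, str], ...]
    total_intergenic_bp: int
    intron_total_bp: int
    intron_fraction: float
    genome_length: int

    @property
    def intergenic_fraction(self) -> float:
        return 100.0 * self.total_intergenic_bp / self.genome_length


def region_catalogue(ann: GenomeAnnotation) -> RegionCatalogue:
    """Catalogue intergenic gaps, overlaps and abutments between circularly
    adjacent top-level features, plus intron totals.

    Raises if two *non-adjacent* top-level features overlap (a corrupt
    annotation rather than the 1-bp overlaps seen between abutting ORFs).
    """
    L = ann.length
    feats = ann.top_level()
    n = len(feats)
    intergenic, overlaps, abutting = [], [], []
    for i in range(n):
        a, b = feats[i], feats[(i + 1) % n]
        g = gap_between(a, b, L) if n > 1 else L - a.span_length(L)
        if g > 0:
            intergenic.append((a.name, b.name, g))
        elif g < 0:
            overlaps.append((a.name, b.name, -g))
        else:
            abutting.append((a.name, b.name))
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue
            a, b = feats[i], feats[j]
            if circular_overlap((a.start, a.end), (b.start, b.end), L):
                raise ValueError(f"non-adjacent features overlap: {a.name}, {b.name}")
    intron_bp = sum(f.intron_length(L) for f in ann.features if f.nested_in is None)
    return RegionCatalogue(
        intergenic=tuple(intergenic),
        overlaps=tuple(overlaps),
        abutting=tuple(abutting),
        total_intergenic_bp=sum(g for _, _, g in intergenic),
        intron_total_bp=intron_bp,
        intron_fraction=100.0 * intron_bp / L,
        genome_length=L,
    )


def intron_count_table(annotations: dict[str, GenomeAnnotation] | Sequence[GenomeAnnotation]) -> pd.DataFrame:
    """Per-strain intron counts by host gene, with a Total column.

    Accepts a mapping strain -> annotation or a sequence (ids taken from the
    genome ids). Host genes beyond the canonical six get appended columns.
    """
    if not isinstance(annotations, dict):
        annotations = {ann.genome.id: ann for ann in annotations}
    hosts = list(DEFAULT_INTRON_HOSTS)
    rows = {}
    for strain, ann in annotations.items():
        counts: dict[str, int] = {}
        for f in ann.features:
            if f.introns:
                counts[f.name] = len(f.introns)
                if f.name not in hosts:
                    hosts.append(f.name)
        rows[strain] = counts
    df = (
        pd.DataFrame.from_dict(rows, orient="index")
        .reindex(index=list(annotations), columns=hosts)
        .fillna(0)
        .astype(int)
    )
    df["Total"] = df.sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# point location
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Location:
    """Region label for a single genomic position."""

    kind: str  # exon | intron | intergenic | control
    gene: str | None = None
    intron_index: int | None = None  # 1-based
    nested_gene: str | None = None  # rps3-style gene overlapping the position

    def __str__(self) -> str:
        if self.kind == "control":
            return "control"
        if self.kind == "intergenic":
            return "intergenic"
        if self.kind == "intron":
            base = f"intron {self.intron_index} of {self.gene}"
            if self.nested_gene:
                return f"{self.nested_gene} ({base})"
            return base
        return f"exon of {self.gene}"


def locate(position: int, ann: GenomeAnnotation) -> Location:
    """Deterministic region label for a 1-based genomic position.

    Positions inside a nested gene (rps3 within the rnl intron) report both
    the nested gene and the host intron.
    """
    L = ann.length
    if not (1 <= position <= L):
        raise ValueError(f"position {position} outside 1..{L}")
    nested = [f for f in ann.features if f.nested_in]
    for f in ann.top_level():
        if not circular_contains(f.start, f.end, position, L):
            continue
        if f.kind == "control":
            return Location(kind="control")
        for k, (s, e) in enumerate(f.introns, start=1):
            if circular_contains(s, e, position, L):
                inner = next(
                    (g.name for g in nested
                     if g.nested_in == f.name and circular_contains(g.start, g.end, position, L)),
                    None,
                )
                return Location(kind="intron", gene=f.name, intron_index=k, nested_gene=inner)
        return Location(kind="exon", gene=f.name)
    return Location(kind="intergenic")
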