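"""Gene-junction evidence graph and polycistronic-unit inference.

Adjacent gene pairs of the circular annotation form junctions; transcript
contigs supply evidence per junction via an ordered rule set (strongest
first), and maximal runs of evidenced junctions are the inferred
polycistronic transcription units. The tRNA-punctuation processing model
motivates the bridge rules: a cleaved punctuation tRNA leaves no read
evidence, so a junction may be bridged when the only uncovered features in
its neighbourhood are tRNAs separated by short unannotated gaps.

The control region never carries a bridge: the junction that passes through
it stays unsupported unless a contig literally spans it, which is exactly
the break that makes the single-unit inference falsifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .evidence import ContigAlignment, gene_read_coverage, resolve_gene_content
from .genome import GenomeAnnotation, circular_contains, circular_overlap, gap_between, locate

__all__ = [
    "GeneJunction",
    "JunctionStatus",
    "JunctionEvidence",
    "PolycistronicUnit",
    "TssInference",
    "MergeParams",
    "build_junctions",
    "assess_junction",
    "assess_all_junctions",
    "infer_units",
    "infer_tss",
    "render_report",
    "unit_gene_string",
]


@dataclass(frozen=True)
class MergeParams:
    """Tunable thresholds of the merge rules.

    delta: largest bridgeable unannotated (intergenic) stretch, bp.
    epsilon: slack when matching an evidence gap to a tRNA span, bp.
    junction_tolerance: alignment jitter allowed at splice junctions, bp.
    """

    delta: int = 60
    epsilon: int = 2
    junction_tolerance: int = 3
    enable_trna_bridge: bool = True
    enable_small_gap_bridge: bool = True


class JunctionStatus(str, Enum):
    SUPPORTED = "supported"
    OVERLAP_MERGE = "overlap_merge"
    SAME_GENE_BRIDGE = "same_gene_bridge"
    VALIDATED = "validated"
    TRNA_BRIDGE = "trna_bridge"
    SMALL_GAP_BRIDGE = "small_gap_bridge"
    UNSUPPORTED = "unsupported"


@dataclass(frozen=True)
class GeneJunction:
    upstream: str
    downstream: str
    gap_bp: int  # negative magnitude = overlap
    crosses_control: bool = False
    gap_composition: tuple[float, float, float] = (0.0, 0.0, 1.0)  # tRNA/other/unannotated


@dataclass(frozen=True)
class JunctionEvidence:
    junction: GeneJunction
    status: JunctionStatus
    supporting_contigs: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class PolycistronicUnit:
    genes: tuple[str, ...]
    circular: bool = False
    junction_status: tuple[tuple[str, str, str], ...] = ()  # (up, down, status)

    @property
    def start_gene(self) -> str:
        return self.genes[0]

    @property
    def end_gene(self) -> str:
        return self.genes[-1]


@dataclass(frozen=True)
class TssInference:
    contig_id: str
    extension_bp: int
    candidate_region: tuple[int, int] | None


# ---------------------------------------------------------------------------
# junction construction
# ---------------------------------------------------------------------------

def build_junctions(ann: GenomeAnnotation) -> list[GeneJunction]:
    """One junction per circularly adjacent top-level gene pair. The control
    region is not a junction endpoint: it lies inside the gap of the wrap
    junction between the genes flanking it."""
    genes = ann.genes()
    L = ann.length
    control = ann.control
    out = []
    for i, up in enumerate(genes):
        down = genes[(i + 1) % len(genes)]
        gap = gap_between(up, down, L)
        crosses = False
        comp = (0.0, 0.0, 1.0)
        if gap > 0:
            trna = other = unann = 0
            for k in range(gap):
                pos = (up.end + k) % L + 1
                loc = locate(pos, ann)
                if loc.kind == "intergenic":
                    unann += 1
                elif loc.kind == "control":
                    other += 1
                    crosses = True
                else:
                    host = ann.feature(loc.gene)
                    trna += host.kind == "tRNA"
                    other += host.kind != "tRNA"
            comp = (trna / gap, other / gap, unann / gap)
        if control is not None and not crosses and gap > 0:
            crosses = circular_overlap(
                ((up.end % L) + 1, (down.start - 2) % L + 1), (control.start, control.end), L
            ) > 0
        out.append(GeneJunction(
            upstream=up.name, downstream=down.name, gap_bp=gap,
            crosses_control=crosses, gap_composition=comp,
        ))
    return out


# ---------------------------------------------------------------------------
# contig chains (per strain)
# ---------------------------------------------------------------------------

def _resolved(c: ContigAlignment, ann: GenomeAnnotation, cache: dict) -> list[str]:
    if c.contig_id not in cache:
        if c.gene_content:
            names, _ = resolve_gene_content(c.gene_content, ann)
        else:
            from .evidence import gene_content_label

            names = gene_content_label((c.start, c.end), ann)
        cache[c.contig_id] = names
    return cache[c.contig_id]


def _pair_links(
    contigs: list[ContigAlignment], ann: GenomeAnnotation, cache: dict
) -> dict[tuple[str, str], tuple[str, tuple[str, ...]]]:
    """Map (gene, next gene) -> (strongest evidence kind, contig ids).

    Kinds: 'single' (one contig spans the pair), 'overlap' (two overlapping
    contigs), 'same_gene' (two contigs broken inside one gene). Links are
    only drawn between contigs of the same strain, whose coordinates are
    mutually consistent.
    """
    rank = {"single": 0, "overlap": 1, "same_gene": 2}
    links: dict[tuple[str, str], tuple[str, tuple[str, ...]]] = {}

    def record(pair: tuple[str, str], kind: str, ids: tuple[str, ...]) -> None:
        cur = links.get(pair)
        if cur is None or rank[kind] < rank[cur[0]]:
            links[pair] = (kind, ids)

    by_strain: dict[str, list[ContigAlignment]] = {}
    for c in contigs:
        by_strain.setdefault(c.strain, []).append(c)
    def matches_ann(c: ContigAlignment) -> bool:
        # whitespace-insensitive: FASTA ids cannot carry the spaces strain
        # names print with
        return c.strain.replace(" ", "_") == ann.genome.id.replace(" ", "_")
    L = ann.length
    for strain, group in by_strain.items():
        group = sorted(group, key=lambda c: c.start)
        for c in group:
            names = _resolved(c, ann, cache)
            for a, b in zip(names, names[1:]):
                record((a, b), "single", (c.contig_id,))
        for c1, c2 in zip(group, group[1:]):
            n1, n2 = _resolved(c1, ann, cache), _resolved(c2, ann, cache)
            if not n1 or not n2:
                continue
            if c2.start <= c1.end:  # interval overlap >= 1 bp
                kind = "overlap"
            elif n1[-1] == n2[0]:
                kind = "same_gene"
            elif matches_ann(c1):
                g1 = locate(min(c1.end, L), ann)
                g2 = locate(min(c2.start, L), ann)
                if g1.gene is not None and g1.gene == g2.gene:
                    kind = "same_gene"
                else:
                    continue
            else:
                continue
            if n1[-1] == n2[0]:
                continue  # shared gene: adjacency already covered by 'single' pairs
            record((n1[-1], n2[0]), kind, (c1.contig_id, c2.contig_id))
    return links


# ---------------------------------------------------------------------------
# junction assessment
# ---------------------------------------------------------------------------

def _trna_bridgeable(
    j: GeneJunction,
    ann: GenomeAnnotation,
    covered: dict[str, bool],
    params: MergeParams,
) -> tuple[bool, list[str]]:
    """tRNA-punctuation bridge for one junction: at least one flanking gene
    is an uncovered tRNA (a cleaved punctuation tRNA leaves no evidence),
    every uncovered flank is a tRNA, and the junction gap contains no
    non-tRNA annotation and at most delta unannotated bases."""
    uncovered = [g for g in (j.upstream, j.downstream) if not covered.get(g, False)]
    if not uncovered:
        return False, []  # both flanks covered: the small-gap rule's case
    kinds = {f.name: f.kind for f in ann.features}
    if any(kinds[g] != "tRNA" for g in uncovered):
        return False, []
    gap = max(j.gap_bp, 0)
    trna_frac, other_frac, unann_frac = j.gap_composition
    if gap and round(gap * other_frac):
        return False, []
    if round(gap * unann_frac) > params.delta:
        return False, []
    # transcription context: the maximal run of uncovered genes around the
    # junction must consist of tRNAs only and be terminated on each side by
    # a covered gene or by the control region, with at least one covered
    # terminator -- a bridge needs an expressed neighbourhood to belong to
    order = [f.name for f in ann.top_level()]  # includes the control region
    n = len(order)
    is_cov = lambda name: covered.get(name, False)
    is_control = lambda name: kinds.get(name) == "control"
    start = order.index(uncovered[0])
    run = {order[start]}
    terminators = []
    for step in (-1, 1):
        i = start
        for _ in range(n):
            i = (i + step) % n
            name = order[i]
            if is_control(name) or is_cov(name):
                terminators.append("covered" if is_cov(name) else "control")
                break
            if kinds[name] != "tRNA":
                return False, []
            run.add(name)
        else:
            return False, []
    if "covered" not in terminators:
        return False, []
    notes = [f"uncovered punctuation tRNA(s): {', '.join(sorted(run))}"]
    return True, notes


def assess_junction(
    j: GeneJunction,
    contigs: list[ContigAlignment],
    ann: GenomeAnnotation,
    validated: tuple[tuple[str, str], ...] = (),
    params: MergeParams = MergeParams(),
    _links=None,
    _covered=None,
    _cache=None,
) -> JunctionEvidence:
    """Assign the strongest matching evidence status to one junction.

    Rule order: supported (a contig's content spans the pair) >
    overlap_merge (overlapping contigs jointly span it) > same_gene_bridge
    (contigs broken inside one gene chain across it) > validated (externally
    demonstrated pair) > trna_bridge > small_gap_bridge > unsupported.
    The junction through the control region only accepts the first three.
    """
    cache = _cache if _cache is not None else {}
    links = _links if _links is not None else _pair_links(contigs, ann, cache)
    if _covered is None:
        cov = gene_read_coverage(contigs, ann)
        covered = {g: flag for g, (flag, _) in cov.per_gene.items()}
    else:
        covered = _covered
    pair = (j.upstream, j.downstream)
    notes: list[str] = []

    hit = links.get(pair)
    if hit:
        kind, ids = hit
        status = {
            "single": JunctionStatus.SUPPORTED,
            "overlap": JunctionStatus.OVERLAP_MERGE,
            "same_gene": JunctionStatus.SAME_GENE_BRIDGE,
        }[kind]
        return JunctionEvidence(junction=j, status=status, supporting_contigs=ids)

    if not j.crosses_control:
        vset = {tuple(p) for p in validated}
        if pair in vset:
            return JunctionEvidence(junction=j, status=JunctionStatus.VALIDATED,
                                    notes=("externally demonstrated junction",))
        if params.enable_trna_bridge:
            ok, bnotes = _trna_bridgeable(j, ann, covered, params)
            if ok:
                return JunctionEvidence(junction=j, status=JunctionStatus.TRNA_BRIDGE,
                                        notes=tuple(bnotes))
        if (params.enable_small_gap_bridge
                and covered.get(j.upstream, False) and covered.get(j.downstream, False)
                and j.gap_bp <= params.delta):
            return JunctionEvidence(
                junction=j, status=JunctionStatus.SMALL_GAP_BRIDGE,
                notes=(f"both genes covered, {j.gap_bp} bp apart",),
            )
    else:
        notes.append("junction through control region: bridges disabled")
    return JunctionEvidence(junction=j, status=JunctionStatus.UNSUPPORTED, notes=tuple(notes))


def assess_all_junctions(
    ann: GenomeAnnotation,
    contigs: list[ContigAlignment],
    validated: tuple[tuple[str, str], ...] = (),
    params: MergeParams = MergeParams(),
) -> list[JunctionEvidence]:
    cache: dict = {}
    links = _pair_links(contigs, ann, cache)
    cov = gene_read_coverage(contigs, ann)
    covered = {g: flag for g, (flag, _) in cov.per_gene.items()}
    return [
        assess_junction(j, contigs, ann, validated, params,
                        _links=links, _covered=covered, _cache=cache)
        for j in build_junctions(ann)
    ]


# ---------------------------------------------------------------------------
# unit inference
# ---------------------------------------------------------------------------

def infer_units(evidence: list[JunctionEvidence]) -> list[PolycistronicUnit]:
    """Maximal runs of genes whose internal junctions are all evidenced.

    The input is the complete circular junction list (junction i joins gene
    i to gene i+1). With zero unsupported junctions the result is a single
    unit flagged circular. Units partition the genes.
    """
    if not evidence:
        return []
    genes = [ev.junction.upstream for ev in evidence]
    n = len(genes)
    broken = [ev.status is JunctionStatus.UNSUPPORTED for ev in evidence]
    if not any(broken):
        return [PolycistronicUnit(
            genes=tuple(genes), circular=True,
            junction_status=tuple(
                (ev.junction.upstream, ev.junction.downstream, ev.status.value)
                for ev in evidence
            ),
        )]
    units = []
    starts = [(i + 1) % n for i, b in enumerate(broken) if b]
    starts.sort()
    for s in starts:
        run = [s]
        while not broken[run[-1] % n]:
            run.append((run[-1] + 1) % n)
        members = run  # indices; last junction of run is broken
        unit_genes = tuple(genes[i] for i in members)
        internal = tuple(
            (evidence[i].junction.upstream, evidence[i].junction.downstream,
             evidence[i].status.value)
            for i in members[:-1]
        )
        units.append(PolycistronicUnit(genes=unit_genes, circular=False,
                                       junction_status=internal))
    return units


def infer_tss(
    contigs: list[ContigAlignment],
    ann: GenomeAnnotation,
) -> list[TssInference]:
    """Contigs extending past the control-flanking genes into the control
    region, reported as candidate transcription start/termination evidence."""
    control = ann.control
    if control is None:
        raise ValueError("annotation has no control region")
    L = ann.length
    genes = ann.top_level()
    idx = next(i for i, f in enumerate(genes) if f.kind == "control")
    prev_gene = genes[(idx - 1) % len(genes)]
    next_gene = genes[(idx + 1) % len(genes)]
    out = []
    for c in contigs:
        touches_prev = circular_overlap((c.start, c.end), (prev_gene.start, prev_gene.end), L)
        touches_next = circular_overlap((c.start, c.end), (next_gene.start, next_gene.end), L)
        if touches_prev and circular_contains(prev_gene.end, control.end, c.end, L):
            ext = (c.end - prev_gene.end) % L
            region = (prev_gene.end + 1, c.end) if ext else None
            out.append(TssInference(contig_id=c.contig_id, extension_bp=ext,
                                    candidate_region=region))
        elif touches_next and circular_contains(control.start, next_gene.start, c.start, L):
            ext = (next_gene.start - c.start) % L
            region = (c.start, next_gene.start - 1) if ext else None
            out.append(TssInference(contig_id=c.contig_id, extension_bp=ext,
                                    candidate_region=region))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def unit_gene_string(unit: PolycistronicUnit, ann: GenomeAnnotation | None = None) -> str:
    """Dash-separated gene order, nested genes shown as host(nested)."""
    nested = ann.nested_map() if ann is not None else {}
    return "-".join(f"{g}({nested[g]})" if g in nested else g for g in unit.genes)


def render_report(
    units: list[PolycistronicUnit],
    evidence: list[JunctionEvidence],
    tss: list[TssInference] | None = None,
    ann: GenomeAnnotation | None = None,
) -> tuple[str, dict]:
    """Human-readable summary plus a JSON-serializable dict."""
    data = {
        "n_units": len(units),
        "units": [
            {
                "genes": unit_gene_string(u, ann),
                "n_genes": len(u.genes),
                "circular": u.circular,
            }
            for u in units
        ],
        "junctions": [
            {
                "upstream": ev.junction.upstream,
                "downstream": ev.junction.downstream,
                "gap_bp": ev.junction.gap_bp,
                "status": ev.status.value,
                "supporting_contigs": list(ev.supporting_contigs),
                "notes": list(ev.notes),
            }
            for ev in evidence
        ],
        "tss_candidates": [
            {
                "contig": t.contig_id,
                "extension_bp": t.extension_bp,
                "candidate_region": list(t.candidate_region) if t.candidate_region else None,
            }
            for t in (tss or [])
        ],
    }
    lines = [f"Polycistronic units: {len(units)}"]
    for i, u in enumerate(units, 1):
        tag = " (circular)" if u.circular else ""
        lines.append(f"  unit {i}{tag} [{len(u.genes)} genes]: {unit_gene_string(u, ann)}")
    lines.append("Junction evidence:")
    for ev in evidence:
        sup = f" [{','.join(ev.supporting_contigs)}]" if ev.supporting_contigs else ""
        lines.append(
            f"  {ev.junction.upstream} -> {ev.junction.downstream}"
            f" (gap {ev.junction.gap_bp} bp): {ev.status.value}{sup}"
        )
    for t in tss or []:
        lines.append(
            f"TSS candidate: contig {t.contig_id} extends {t.extension_bp} bp"
            f" into the control region"
        )
    return "\n".join(lines), data
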