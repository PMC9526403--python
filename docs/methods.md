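# Methods

## The model

A compact circular mitogenome is annotated as an ordered set of single-
strand features: protein-coding genes (PCGs), tRNAs, rRNAs, one control
region, group-I introns inside their host genes, and optionally a gene
nested inside an intron (rps3 inside the conserved rnl intron). All
coordinates are 1-based inclusive; a feature may wrap the origin, and every
interval operation is performed on the rotation that makes its operands
contiguous. The gap between circularly adjacent features a → b is
`start(b) − end(a) − 1`; overlapping operands yield a negative value whose
magnitude is the overlap (the two published 1-bp overlaps, nad2/nad3 and
nad4L/nad5, are stop/start codon sharing).

Transcription is modelled as one or more polycistronic units — contiguous
runs of genes transcribed together — whose maturation proceeds, in order:
polyadenylation of the growing polycistron, intron splicing, and cleavage
at the punctuation tRNAs, which releases tRNAs plus mono-/di-/tri- and
longer oligocistronic RNAs. Because polyadenylation precedes splicing, a
polyadenylated molecule can still contain introns; that intermediate is the
observable difference between the two stage orders, and the package's
simulator and classifiers operationalize it: under polyA-before-splicing,
at least one intron-containing contig traces to a polyA-confirmed molecule,
under splice-first none can.

## Junction inference

Adjacent gene pairs form a circular junction list (the control region is
not a junction endpoint; it sits inside the gap of the wrap junction
between the genes flanking it). Evidence statuses are assigned by the
first matching rule, strongest first: a single contig spanning the pair;
two interval-overlapping contigs jointly spanning it; two contigs broken
inside the same gene whose chain crosses it; an externally validated pair;
a cleaved-tRNA bridge; a small-gap bridge. Units are maximal runs of
non-unsupported junctions — equivalent to connected components of the
cycle graph, which an independent graph-library oracle confirms on random
instances in the test suite.

The cleaved-tRNA bridge encodes the tRNA-punctuation model: a punctuation
tRNA excised from the transcript before library preparation leaves no
reads, so an uncovered tRNA must not break a unit. The rule demands that
every uncovered flank of the junction is a tRNA, that the junction gap
contains no non-tRNA annotation and at most δ unannotated bases, and that
the surrounding run of uncovered genes consists of tRNAs only and is
terminated by a covered gene (the control region may terminate one side).
The last condition gives the bridge its transcription context: with no
evidence at all, nothing merges, and the inference degrades to one
singleton unit per gene rather than hallucinating a polycistron.

Two deliberate asymmetries: the control-region junction accepts only
literal contig support (rules 1–3), never a bridge — the single-unit
conclusion should be breakable exactly there; and `validated` is kept as a
distinct status so the inference's dependence on external (PCR) evidence
stays visible in every report.

## Parameters

| parameter | default | meaning |
|---|---|---|
| δ (`delta`) | 60 bp | largest bridgeable unannotated stretch per intergenic gap; the largest published bridged distance is 53 bp |
| ε (`epsilon`) | 2 bp | slack when matching an evidence gap to a tRNA span (the published 70 bp contig gap vs the 71 bp tRNA) |
| `junction_tolerance` | 3 bp | alignment jitter allowed when a split read's segments are matched to intron boundaries |
| `min_tail` | 6 nt | minimum 3′ soft-clip A-run for a polyA call; ≤ 1 mismatch; the call is rejected if the genomic continuation could template the run |
| min wrap arm | 20 nt | both arms of a wrap-around read must reach this length |
| ORF `min_aa` | 50 aa | minimum intron-ORF length (homing-endonuclease ORFs are long); forward strand, ATG starts, TAA/TAG/TGA stops |
| intron-site tolerance | 10 bp | exon-space distance within which insertion sites in the same host gene are treated as homologous |

Duplicate tRNA names (three trnM, two each of trnR/trnL/trnS) are
disambiguated by a subscript assigned in genomic order; printed labels are
resolved to canonical copies by finding the contiguous window of the gene
order that matches the label, so a printed subscript contradicting its
neighbours (the known trnM3-for-trnM2 anomaly in one contig label) is
overridden positionally and flagged in the output.

Coverage flags for labelled contigs come from the labels rather than from
interval intersection: one published contig's interval touches the last
base of an adjacent tRNA that its label (correctly) omits, and positional
flags would erase the punctuation signal. Positional exon-space fractions
are reported alongside.

## The synthetic generator

`simulate.SimConfig` defines one strain's study conditions: the canonical
41-gene order (control region after the last gene), a target of ~73% AT,
71-bp tRNAs, PCGs of 300–1,500 nt filled with sense codons (ATG…TAA),
rRNAs of 3.6/1.4 kb, and an intron plan mapping host genes to counts (the
published per-strain profiles are available via `intron_plan_for`). Introns
are inserted after a U/T residue with GT..AG ends at fixed exon-space
fractions of the host gene, so strains generated from the same layout seed
have homologous insertion sites; the first rnl intron embeds a 900-nt rps3
ORF as a nested gene.

Intergenic gaps follow the punctuation geometry: 2–3 bp between adjacent
tRNAs, 5–55 bp where a tRNA borders another gene (within δ, as in the
published 25/26/53-bp distances), 25–150 bp between non-tRNA genes, and
120–360 bp (2δ–6δ) at planted unit boundaries so that a break is not
trivially re-bridged. Evidence emission mirrors the processing model:
oligocistronic molecules are tiled into overlapping contigs whose assembly
breakpoints fall inside genes (mimicking contig pairs broken within one
coding region); each cleaved tRNA independently drops out of the evidence
with probability 0.5 by default; the polyA-unspliced intermediate
contributes only intron-boundary-localized contigs plus a polyA-tailed 3′
read, as short-read data actually shows; wrap-around reads are emitted for
molecules crossing the genome origin. All randomness flows from a single
integer seed and outputs are byte-identical across runs.

What the generator does **not** emulate: sequencing errors and quality
scores, depth variation, strand-ambiguous libraries, nuclear background
transcripts, chimeric mis-assemblies, or secondary-structure effects on
splicing. Passing recovery tests therefore show that the merge rules invert
the modelled fragmentation/cleavage process, not that they are robust to
every artifact of real Trinity assemblies.

## Numerical and design choices

- N bases are excluded from all skew and AT% denominators; a sequence with
  an empty denominator reports the skew as missing rather than 0.
- Boundary checks run on the DNA sense strand (U ≡ T), since all genes lie
  on the positive strand; "GT-AG" is evaluated on the intron's first/last
  genomic dinucleotides. Both group-I and GT-AG checks are flags, never
  filters — they describe tendencies of the intron class.
- Problem sizes in the test and acceptance suites: the unit-recovery check
  runs 20 seeded simulations per planted K ∈ {1, 2, 3} (60 genomes of
  ~20–27 kb); the inference oracle is exercised on 1,000 random circular
  instances of up to 64 genes. These sizes give stable pass/fail behaviour
  at sub-minute cost.
- The packaged deterministic annotation honors every printed coordinate
  anchor simultaneously. One printed interval implies five tRNAs within
  236 bp, which cannot hold at 71 bp per tRNA; the fixture uses 50-bp tRNAs
  in that cluster (tRNA length is otherwise unconstrained) while trnR_2
  keeps its printed 71-bp span. The control-region length is not published;
  the fixture derives it from the flanking anchors (581 bp) and the
  generator defaults to 300 bp, configurable.
- Ties and degenerate inputs: identical intervals are rejected by
  `gap_between`; an annotation with overlapping non-adjacent features is
  rejected with the offending pair; a content label that is not a
  contiguous run of the gene order raises an error naming the tokens.

## Known limitations

- Junction assessment pools gene-content evidence across strains (as the
  published analysis pools three strains' contigs) but only compares
  coordinates within one strain; cross-strain coordinate-level merging
  would require whole-genome alignment, which is out of scope.
- The TSS inference reports contig extensions into the control region; it
  does not model promoters or pick a base-precise start site.
- Intron ORF scanning is forward-strand, single-start (ATG); it reports
  frames and lengths but does not classify LAGLIDADG/GIY-YIG families.
- Wrap-around read emission in the simulator requires the rotated origin to
  fall inside a transcription unit; the default layout places the origin in
  the control region, where no wrap evidence arises.
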