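"""Readers and writers for the pipeline's standard formats.

FASTA goes through Biopython, GFF3 parsing through gffutils, SAM through
pysam, and tabular data through pandas. The contig-table dialect mirrors
the published layout: tab-separated columns contig_id, strain, start, end,
gene_content, with dash-separated gene content; positions may also arrive
as a single en-dash/hyphen "position" column with thousands separators,
which is normalized on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evidence import ContigAlignment, ReadAlignment, parse_gene_content
from .genome import CircularGenome, GeneFeature, GenomeAnnotation

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "read_contig_table",
    "write_contig_table",
    "read_validated_junctions",
    "write_validated_junctions",
    "read_sam_reads",
    "write_sam_reads",
]

_KIND_TO_GFF = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "control": "region"}
_GFF_TO_KIND = {v: k for k, v in _KIND_TO_GFF.items()}


def read_fasta(path: str | Path) -> CircularGenome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: CircularGenome, path: str | Path, description: str = "") -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=description)
    SeqIO.write([rec], str(path), "fasta")


def write_annotation(ann: GenomeAnnotation, gff_path: str | Path) -> None:
    """GFF3 writer: one line per feature plus child intron lines."""
    lines = ["##gff-version 3",
             f"##sequence-region {ann.genome.id} 1 {ann.length}"]
    sid = ann.genome.id
    for f in ann.features:
        attrs = [f"ID={f.name}", f"Name={f.name}"]
        if f.nested_in:
            attrs.append(f"nested_in={f.nested_in}")
        if f.wraps_origin:
            attrs.append("wraps_origin=true")
        lines.append("\t".join([
            sid, "mitocistron", _KIND_TO_GFF[f.kind], str(f.start), str(f.end),
            ".", "+", ".", ";".join(attrs),
        ]))
        for k, (s, e) in enumerate(f.introns, start=1):
            lines.append("\t".join([
                sid, "mitocistron", "intron", str(s), str(e), ".", "+", ".",
                f"ID={f.name}.intron{k};Parent={f.name}",
            ]))
    Path(gff_path).write_text("\n".join(lines) + "\n")


def read_annotation(gff_path: str | Path, fasta_path: str | Path) -> GenomeAnnotation:
    """Load and validate an annotation; coordinates are checked against the
    genome and intron children are attached to their parents."""
    genome = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    introns: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("intron"):
        parent = feat.attributes.get("Parent", [None])[0]
        if parent is None:
            raise ValueError(f"intron without Parent at line for {feat.id}")
        introns.setdefault(parent, []).append((feat.start, feat.end))
    feats = []
    for feat in db.all_features():
        if feat.featuretype == "intron":
            continue
        kind = _GFF_TO_KIND.get(feat.featuretype)
        if kind is None:
            continue
        if feat.seqid != genome.id:
            raise ValueError(f"feature {feat.id} on {feat.seqid}, genome is {genome.id}")
        wraps = feat.attributes.get("wraps_origin", ["false"])[0] == "true"
        if feat.end < feat.start and not wraps:
            raise ValueError(f"feature {feat.id}: end < start without circular flag")
        if not (1 <= feat.start <= genome.length and 1 <= feat.end <= genome.length):
            raise ValueError(f"feature {feat.id}: coordinates outside 1..{genome.length}")
        name = feat.attributes.get("ID", [feat.id])[0]
        nested = feat.attributes.get("nested_in", [None])[0]
        feats.append(GeneFeature(
            name=name, kind=kind, start=feat.start, end=feat.end,
            wraps_origin=wraps, nested_in=nested,
            introns=tuple(sorted(introns.get(name, []))),
        ))
    return GenomeAnnotation(genome=genome, features=tuple(feats))


_POSITION = re.compile(r"^\s*([\d,]+)\s*[–-]\s*([\d,]+)\s*$")


def _parse_int(x) -> int:
    return int(str(x).replace(",", "").strip())


def read_contig_table(path: str | Path) -> list[ContigAlignment]:
    """Parse a contig table (tab-separated, header row required).

    Accepts either explicit start/end columns or a combined position column
    ("6,198–6,433"); gene content is dash-separated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        return []
    out = []
    for i, row in df.iterrows():
        if "position" in df.columns and pd.notna(row.get("position")):
            m = _POSITION.match(row["position"])
            if not m:
                raise ValueError(f"row {i}: unparseable position {row['position']!r}")
            start, end = _parse_int(m.group(1)), _parse_int(m.group(2))
        else:
            start, end = _parse_int(row["start"]), _parse_int(row["end"])
        content = tuple(parse_gene_content(row["gene_content"])) if pd.notna(row.get("gene_content")) else ()
        out.append(ContigAlignment(
            contig_id=str(row["contig_id"]).strip(),
            strain=str(row.get("strain", "")).strip(),
            start=start, end=end, gene_content=content,
            wraps_origin=start > end,
        ))
    return out


def write_contig_table(contigs: list[ContigAlignment], path: str | Path) -> None:
    rows = [
        {
            "contig_id": c.contig_id, "strain": c.strain,
            "start": c.start, "end": c.end,
            "gene_content": "-".join(c.gene_content),
        }
        for c in contigs
    ]
    pd.DataFrame(rows, columns=["contig_id", "strain", "start", "end", "gene_content"]).to_csv(
        path, sep="\t", index=False
    )


def read_validated_junctions(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Two-column TSV (upstream, downstream), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("validated-junction file needs two columns")
    return tuple((a.strip(), b.strip()) for a, b in zip(df[0], df[1]))


def write_validated_junctions(pairs, path: str | Path) -> None:
    Path(path).write_text("".join(f"{a}\t{b}\n" for a, b in pairs))


# ---------------------------------------------------------------------------
# SAM dialect
# ---------------------------------------------------------------------------

def read_sam_reads(path: str | Path) -> list[ReadAlignment]:
    """Read alignments from a SAM file: gapped (N) alignments yield split
    segments; leading/trailing soft clips are captured as clip sequences."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                out.append(ReadAlignment(read_id=rec.query_name, segments=()))
                continue
            seq = rec.query_sequence or ""
            segments = []
            gpos = rec.reference_start + 1
            rpos = 1
            head = tail = ""
            seg_g = gpos
            seg_r = rpos
            glen = rlen = 0
            for op, ln in rec.cigartuples:
                if op == 4:  # soft clip
                    if not segments and glen == 0:
                        head = seq[:ln]
                        rpos += ln
                        seg_r = rpos
                    else:
                        tail = seq[len(seq) - ln:]
                elif op in (0, 7, 8):  # aligned block
                    glen += ln
                    rlen += ln
                elif op == 1:  # insertion
                    rlen += ln
                elif op == 2:  # deletion
                    glen += ln
                elif op == 3:  # skip: close the segment
                    segments.append((seg_g, seg_g + glen - 1, seg_r, seg_r + rlen - 1))
                    seg_g = seg_g + glen + ln
                    seg_r = seg_r + rlen
                    glen = rlen = 0
            if glen:
                segments.append((seg_g, seg_g + glen - 1, seg_r, seg_r + rlen - 1))
            out.append(ReadAlignment(
                read_id=rec.query_name, segments=tuple(segments),
                softclip_head=head, softclip_tail=tail,
            ))
    return out


def write_sam_reads(reads: list[ReadAlignment], genome: CircularGenome, path: str | Path) -> None:
    """Minimal single-reference SAM writer (gapped alignments via N ops)."""
    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:{genome.id}\tLN:{genome.length}"]
    for r in reads:
        if not r.segments:
            lines.append(f"{r.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
            continue
        cigar = []
        if r.softclip_head:
            cigar.append(f"{len(r.softclip_head)}S")
        prev_end = None
        rlen = 0
        for (gs, ge, rs, re_) in r.segments:
            if prev_end is not None:
                skip = gs - prev_end - 1
                if skip > 0:
                    cigar.append(f"{skip}N")
            cigar.append(f"{ge - gs + 1}M")
            prev_end = ge
            rlen += re_ - rs + 1
        if r.softclip_tail:
            cigar.append(f"{len(r.softclip_tail)}S")
        aligned = "".join(
            genome.fetch(gs, ge) if gs <= ge else genome.fetch(gs, genome.length) + genome.fetch(1, ge)
            for gs, ge, _, _ in r.segments
        )
        seq = r.softclip_head + aligned + r.softclip_tail
        lines.append("\t".join([
            r.read_id, "0", genome.id, str(r.segments[0][0]), "60",
            "".join(cigar), "*", "0", "0", seq, "*",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
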