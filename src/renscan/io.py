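"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 files are
1-based inclusive and BED files 0-based half-open, converted only here.
All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator

import numpy as np
import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AA_ORDER,
    AlignmentRecord,
    CandidateLocus,
    GapRecord,
    GeneModel,
    GenomeSequence,
    MotifModel,
    ParseError,
    VALID_RESIDUES,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read DNA records; lowercase is normalized to uppercase, any residue
    outside ACGTN is a parse error naming the offending line."""
    seqs: list[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        residues = str(rec.seq).upper()
        bad = set(residues) - VALID_RESIDUES
        if bad:
            lineno = _find_offending_line(path, rec.id, bad)
            raise ParseError(
                f"{path}:{lineno}: illegal residue(s) {sorted(bad)} in record {rec.id!r}")
        seqs.append(GenomeSequence(rec.id, residues))
    return seqs


def _find_offending_line(path, seq_id: str, bad: set) -> int:
    in_rec = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == seq_id if line[1:].strip() else False
                continue
            if in_rec and (set(line.strip().upper()) & bad):
                return lineno
    return 0


def write_fasta(seqs: Iterable, path, wrap: int = 60) -> None:
    records = []
    for s in seqs:
        if isinstance(s, GenomeSequence):
            records.append(SeqRecord(Seq(s.residues), id=s.seq_id, description=""))
        else:  # (id, sequence) pair, e.g. peptides or baits
            sid, residues = s
            records.append(SeqRecord(Seq(residues), id=sid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# SAM

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_read_length(cigar: str) -> int:
    """Read bases consumed by a CIGAR string (M/I/S/=/X)."""
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "MIS=X")


def cigar_ref_spans(cigar: str, start: int) -> list[tuple[int, int]]:
    """Reference intervals consumed by the alignment (M/=/X/D all consume
    reference; a deletion still spans its reference bases)."""
    spans, pos = [], start
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in "M=XD":
            spans.append((pos, pos + n))
            pos += n
        elif op == "N":
            pos += n
    # merge adjacent spans
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _validate_sam_references(path) -> None:
    """For plain-text SAM, reject mapped records naming a reference absent
    from the header (a parser that silently unmaps them would hide the
    inconsistency)."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == b"\x1f\x8b" or magic == b"BAM\x01":
        return
    refs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t"):
                        if field.startswith("SN:"):
                            refs.add(field[3:])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                continue
            flag, rname = int(fields[1]), fields[2]
            if not (flag & _FLAG_UNMAPPED) and rname != "*" and rname not in refs:
                raise ParseError(f"{path}:{lineno}: mapped record references "
                                 f"unknown sequence {rname!r}")


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a (plain-text or binary) SAM file.

    Unmapped records are skipped.  ``n_best_hits`` is taken from the NH tag
    (number of reported alignments) or the X0 tag when present, else 1.
    """
    _validate_sam_references(path)
    with pysam.AlignmentFile(str(path), check_sq=True) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.reference_id < 0:
                raise ParseError(f"{path}: mapped record {aln.query_name!r} without reference")
            if aln.is_paired:
                mate = "first" if aln.is_read1 else "second"
            else:
                mate = "unpaired"
            n_best = 1
            for tag in ("NH", "X0"):
                if aln.has_tag(tag):
                    n_best = int(aln.get_tag(tag))
                    break
            seq = aln.query_sequence or ""
            exp = cigar_read_length(aln.cigarstring or "")
            if seq and exp != len(seq):
                raise ParseError(
                    f"{path}: {aln.query_name!r} CIGAR consumes {exp} read bases, "
                    f"sequence has {len(seq)}")
            yield AlignmentRecord(
                read_id=aln.query_name,
                mate_flag=mate,
                seq_id=aln.reference_name,
                start=aln.reference_start,
                cigar=aln.cigarstring or "",
                mapq=aln.mapping_quality,
                read_seq=seq.upper(),
                n_best_hits=n_best,
            )


def write_sam(records, references: dict[str, int], path) -> None:
    """Write plain-text SAM.  ``records`` are tuples
    (read_id, mate_flag, seq_id, start, cigar, mapq, seq, is_reverse, n_best_hits,
    mate_seq_id, mate_start, tlen)."""
    header = pysam.AlignmentHeader.from_references(
        list(references.keys()), list(references.values()))
    ref_ids = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for (read_id, mate_flag, seq_id, start, cigar, mapq, seq, is_reverse,
             n_best, mate_seq_id, mate_start, tlen) in records:
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            flag = 0
            if mate_flag != "unpaired":
                flag |= _FLAG_PAIRED | (_FLAG_FIRST if mate_flag == "first" else _FLAG_SECOND)
            if is_reverse:
                flag |= _FLAG_REVERSE
            a.flag = flag
            a.reference_id = ref_ids[seq_id]
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_sequence = seq
            if mate_seq_id is not None:
                a.next_reference_id = ref_ids[mate_seq_id]
                a.next_reference_start = mate_start
                a.template_length = tlen
            a.set_tag("NH", n_best)
            out.write(a)


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "renscan"


def write_gff3(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = [
                f"ID={m.gene_id}",
                f"gene_class={m.gene_class}",
                f"completeness={m.completeness}",
                f"expressed={m.expressed}",
            ]
            if m.truncated:
                attrs.append(f"truncated={m.truncated}")
            fh.write("\t".join([
                m.seq_id, _GFF_SOURCE, "gene",
                str(m.start + 1), str(m.end),        # 1-based inclusive
                ".", m.strand, str(m.frame),
                ";".join(attrs),
            ]) + "\n")


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error", from_string=False)
    models = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise ParseError(f"{path}: feature {feat.id!r} has end < start")
        attrs = feat.attributes
        frame = int(feat.frame) if feat.frame in ("0", "1", "2") else 0
        models.append(GeneModel(
            gene_id=feat.id,
            seq_id=feat.seqid,
            strand=feat.strand,
            start=feat.start - 1,                    # back to 0-based half-open
            end=feat.end,
            gene_class=attrs.get("gene_class", ["none"])[0],
            completeness=attrs.get("completeness", ["partial"])[0],
            frame=frame,
            expressed=attrs.get("expressed", ["unknown"])[0],
            truncated=attrs.get("truncated", [""])[0],
        ))
    return models


# ---------------------------------------------------------------------------
# BED / TSV

def write_bed(loci: Iterable[CandidateLocus], path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.seq_id}\t{loc.start}\t{loc.end}\tseed_runs={loc.n_seed_runs}\n")


def write_gap_report(gaps: Iterable[GapRecord], path, liftover=None) -> None:
    """TSV gap report; ``liftover`` optionally maps original to patched
    coordinates ((seq_id, start, end) -> (start, end))."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstatus\tfill_len\tn_support_pairs"
                 "\tpatched_start\tpatched_end\n")
        for g in gaps:
            if liftover is not None:
                ps, pe = liftover(g)
            else:
                ps, pe = g.start, g.end
            fh.write(f"{g.seq_id}\t{g.start}\t{g.end}\t{g.status}\t"
                     f"{len(g.fill_seq)}\t{g.n_support_pairs}\t{ps}\t{pe}\n")


# ---------------------------------------------------------------------------
# Motif-set file
#
# Plain text, one motif per block: a header line
#   >motif_id domain_class threshold_bits
# followed by `width` rows of 20 whitespace-separated probabilities in
# alphabetical amino-acid order (A C D ... Y).


def write_motif_file(motifs: Iterable[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# amino-acid column order: {' '.join(AA_ORDER)}\n")
        for m in motifs:
            fh.write(f">{m.motif_id} {m.domain_class} {m.score_threshold:.6g}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{p:.8g}" for p in row) + "\n")


def read_motif_file(path) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    header = None
    rows: list[list[float]] = []

    def flush():
        if header is None:
            return
        mid, dclass, thr = header
        motifs.append(MotifModel(mid, dclass, np.array(rows), float(thr)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                if len(parts) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: motif header needs 'id domain_class threshold'")
                header, rows = (parts[0], parts[1], parts[2]), []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: probability row before any header")
                vals = line.split()
                if len(vals) != 20:
                    raise ParseError(f"{path}:{lineno}: expected 20 probabilities, "
                                     f"got {len(vals)}")
                rows.append([float(v) for v in vals])
    flush()
    return motifs
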