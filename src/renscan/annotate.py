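"""Motif scanning and gene-model building over candidate loci.

Loci are translated in all six frames and scored against a set of amino-acid
position-probability matrices (a MAST-like scan): the score of a placement
is the per-position log2-odds sum against a uniform 1/20 background, and
placements at or above the motif's bit threshold become hits.  Hits on one
strand are chained into motif series (a new series starts when the gap
between consecutive hits exceeds ``max_intra_series_gap``), each series is
classified by its domain-presence set, and full-length models get start/stop
codons predicted from the motif positions and reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .model import (
    AA_INDEX,
    CandidateLocus,
    GeneModel,
    GenomeSequence,
    MotifHit,
    MotifModel,
    PipelineParams,
    RenscanError,
    classify_presence,
    revcomp,
)

BACKGROUND = 1.0 / 20.0

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def translate(seq: str) -> str:
    """Translate a DNA string, standard code; codons containing N give X."""
    return "".join(
        _CODON_TABLE.get(seq[i:i + 3], "X")
        for i in range(0, len(seq) - 2, 3)
    )


def _encode_peptide(pep: str) -> np.ndarray:
    # indices 0..19 = amino acids, 20 = X (unknown), 21 = stop
    out = np.full(len(pep), 20, dtype=np.int64)
    for i, aa in enumerate(pep):
        if aa in AA_INDEX:
            out[i] = AA_INDEX[aa]
        elif aa == "*":
            out[i] = 21
    return out


def _logodds(motif: MotifModel) -> np.ndarray:
    """width x 22 log2-odds table: column 20 (X) scores as background (0),
    column 21 (stop) is prohibitive — a motif cannot span a stop codon."""
    with np.errstate(divide="ignore"):
        lo = np.log2(np.maximum(motif.matrix, 1e-300) / BACKGROUND)
    ext = np.zeros((motif.width, 22))
    ext[:, :20] = lo
    ext[:, 21] = -1e6
    return ext


def _window_scores(pep_idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    n = len(pep_idx) - w + 1
    if n <= 0:
        return np.empty(0)
    acc = np.zeros(n)
    for i in range(w):
        acc += lo[i][pep_idx[i:i + n]]
    return acc


def scan_motifs(
    locus_sequence: str,
    motif_set: Sequence[MotifModel],
    params: PipelineParams,
    seq_id: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan all six frames of ``locus_sequence`` against ``motif_set``.

    Genomic coordinates are ``offset`` + local position; minus-strand hits
    are reported on forward-genome coordinates with strand '-'.  Hits are
    sorted by nt_start.
    """
    if not motif_set:
        raise RenscanError("empty motif set")
    seq = locus_sequence.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in (0, 1, 2):
            pep = translate(s[frame:])
            if not pep:
                continue
            pep_idx = _encode_peptide(pep)
            for motif in motif_set:
                lo = _logodds(motif)
                scores = _window_scores(pep_idx, lo)
                for j in np.flatnonzero(scores >= motif.score_threshold):
                    local = frame + 3 * int(j)
                    span = 3 * motif.width
                    if strand == "+":
                        nt_start, nt_end = local, local + span
                    else:
                        nt_end = L - local
                        nt_start = nt_end - span
                    hits.append(MotifHit(
                        motif_id=motif.motif_id,
                        domain_class=motif.domain_class,
                        seq_id=seq_id,
                        strand=strand,
                        frame=frame,
                        nt_start=offset + nt_start,
                        nt_end=offset + nt_end,
                        score=float(scores[j]),
                    ))
    hits.sort(key=lambda h: (h.nt_start, h.nt_end, h.motif_id))
    return hits


def score_tail_probability(motif: MotifModel, n_bins: int = 4000) -> float:
    """Probability that a single random-background placement scores at or
    above the motif's threshold, by discretized convolution of the exact
    per-position score distribution."""
    lo = np.log2(np.maximum(motif.matrix, 1e-300) / BACKGROUND)
    lo_min, lo_max = lo.min() * motif.width, lo.max() * motif.width
    width_bin = (lo_max - lo_min) / n_bins
    dist = np.zeros(n_bins + 1)
    dist[int(round(-lo_min / width_bin))] = 1.0  # start at score 0 offset
    for row in lo:
        nxt = np.zeros_like(dist)
        for v in row:
            shift = int(round(v / width_bin))
            contrib = np.roll(dist, shift) * BACKGROUND
            if shift > 0:
                contrib[:shift] = 0
            elif shift < 0:
                contrib[shift:] = 0
            nxt += contrib
        dist = nxt
    thr_bin = int(np.floor((motif.score_threshold - lo_min) / width_bin))
    return float(dist[thr_bin:].sum())


# ---------------------------------------------------------------------------
# Series assembly and classification


def build_gene_models(
    hits: Sequence[MotifHit],
    locus: CandidateLocus,
    params: PipelineParams,
) -> list[GeneModel]:
    """Chain hits into motif series and classify each series.

    Hits are grouped per strand (opposite-strand hits never share a series),
    ordered by position; a gap larger than ``max_intra_series_gap`` between
    consecutive hits starts a new series.  Series spanning frames are kept
    as one model when colinear (frameshifted pseudogene tolerance).  The
    class is a pure function of the domain-presence set; completeness is
    ``full`` iff NB and LRR are both present.
    """
    for h in hits:
        if h.nt_start < locus.start or h.nt_end > locus.end:
            raise RenscanError(f"hit {h.motif_id} at [{h.nt_start},{h.nt_end}) "
                               f"outside locus [{locus.start},{locus.end})")
    models: list[GeneModel] = []
    for strand in "+-":
        shits = sorted((h for h in hits if h.strand == strand),
                       key=lambda h: (h.nt_start, h.nt_end))
        series: list[list[MotifHit]] = []
        for h in shits:
            if series and h.nt_start - series[-1][-1].nt_end <= params.max_intra_series_gap:
                series[-1].append(h)
            else:
                series.append([h])
        for group in series:
            cls, completeness = classify_presence(h.domain_class for h in group)
            models.append(GeneModel(
                gene_id=f"series:{locus.seq_id}:{group[0].nt_start}:{strand}",
                seq_id=locus.seq_id,
                strand=strand,
                start=min(h.nt_start for h in group),
                end=max(h.nt_end for h in group),
                gene_class=cls,
                completeness=completeness,
                frame=group[0].frame,
                motif_series=[h.motif_id for h in group],
            ))
    models.sort(key=lambda m: (m.start, m.end, m.strand))
    return models


# keep the operation name used elsewhere singular-friendly
build_gene_model = build_gene_models


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def predict_cds_bounds(
    model: GeneModel,
    hits: Sequence[MotifHit],
    genome: Sequence[GenomeSequence],
    params: PipelineParams,
) -> GeneModel:
    """Predict start and stop codons for a full-length model.

    The start codon is the nearest in-frame ATG upstream of the first motif
    hit with no intervening in-frame stop; the stop is the first in-frame
    stop codon downstream of the last LRR hit.  If either end cannot be
    established the model is demoted to partial and flagged truncated.
    """
    if model.completeness != "full":
        raise RenscanError(f"{model.gene_id}: CDS bounds are defined only for "
                           "full-length models")
    seq = next((g.residues for g in genome if g.seq_id == model.seq_id), None)
    if seq is None:
        raise RenscanError(f"unknown sequence {model.seq_id!r}")
    L = len(seq)
    s = _oriented(seq, model.strand)
    mine = [h for h in hits if h.strand == model.strand and h.seq_id == model.seq_id
            and h.nt_start >= model.start and h.nt_end <= model.end]
    if not mine:
        raise RenscanError(f"{model.gene_id}: no hits supplied")
    if model.strand == "+":
        o = [(h.nt_start, h.nt_end, h.domain_class) for h in mine]
    else:
        o = [(L - h.nt_end, L - h.nt_start, h.domain_class) for h in mine]
    first_start = min(x[0] for x in o)
    lrr_ends = [x[1] for x in o if x[2] == "LRR"]
    if not lrr_ends:
        raise RenscanError(f"{model.gene_id}: full model without LRR hit")
    last_lrr_end = max(lrr_ends)

    cds_start = None
    p = first_start
    while p >= 0:
        codon = s[p:p + 3]
        if codon == "ATG":
            cds_start = p
            break
        if codon in STOP_CODONS:
            break
        p -= 3
    cds_end = None
    p = last_lrr_end
    while p + 3 <= L:
        codon = s[p:p + 3]
        if codon in STOP_CODONS:
            cds_end = p + 3
            break
        p += 3

    out = GeneModel(**{**model.__dict__})
    if cds_start is None or cds_end is None:
        out.completeness = "partial"
        out.truncated = "5prime" if cds_start is None else "3prime"
        return out
    if model.strand == "+":
        out.start, out.end = cds_start, cds_end
    else:
        out.start, out.end = L - cds_end, L - cds_start
    out.frame = cds_start % 3
    return out


def extract_nbarc(
    model: GeneModel,
    hits: Sequence[MotifHit],
    genome: Sequence[GenomeSequence],
    reference_nbarc_len: int,
    min_fraction: float = 0.5,
) -> str | None:
    """Translate the first-to-last NB-motif span of a model.

    Returns the peptide, or None when it covers less than ``min_fraction``
    of the full-length NB-ARC domain (exactly the fraction is retained:
    strictly-less-than excludes).
    """
    nb = [h for h in hits if h.domain_class == "NB" and h.strand == model.strand
          and h.seq_id == model.seq_id
          and h.nt_start >= model.start and h.nt_end <= model.end]
    if not nb:
        raise RenscanError(f"{model.gene_id}: no NB hit in model span")
    seq = next((g.residues for g in genome if g.seq_id == model.seq_id), None)
    if seq is None:
        raise RenscanError(f"unknown sequence {model.seq_id!r}")
    start = min(h.nt_start for h in nb)
    end = max(h.nt_end for h in nb)
    sub = seq[start:end]
    pep = translate(_oriented(sub, model.strand))
    if len(pep) < min_fraction * reference_nbarc_len:
        return None
    return pep


# ---------------------------------------------------------------------------
# Bait design


@dataclass
class BaitSet:
    """Unique hybridization baits of one fixed length."""

    bait_len: int
    baits: set = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = [b for b in self.baits if len(b) != self.bait_len]
        if bad:
            raise RenscanError(f"{len(bad)} baits deviate from length {self.bait_len}")

    def __len__(self) -> int:
        return len(self.baits)


def design_baits(sequences: Iterable, params: PipelineParams) -> BaitSet:
    """Tile unique ``bait_len``-mers at stride ``bait_step`` over each
    sequence, adding a final window flush with the 3' end when the tiling
    does not land on it; windows containing N are skipped and duplicates
    collapse (set semantics)."""
    bl, step = params.bait_len, params.bait_step
    baits: set[str] = set()
    for s in sequences:
        seq = s.residues if isinstance(s, GenomeSequence) else str(s)
        seq = seq.upper()
        if len(seq) < bl:
            continue  # too short: contributes no baits
        starts = list(range(0, len(seq) - bl + 1, step))
        if starts[-1] != len(seq) - bl:
            starts.append(len(seq) - bl)
        for st in starts:
            window = seq[st:st + bl]
            if "N" in window:
                continue
            baits.add(window)
    return BaitSet(bl, baits)
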