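"""Synthetic truth sets: genomes with planted NB-LRR genes, assembly gaps,
clusters and annotation errors, plus enriched gDNA and cDNA read sets.

Planted genes are intron-free, built from 15-residue consensus motif blocks
(with optional per-position substitution noise) joined by in-frame linkers
that contain no ATG and no stop codon, so the true CDS bounds are
unambiguous.  The released genome masks planted gap intervals with N; reads
are drawn from the pre-masking sequence so gap closing is possible.  Every
generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import write_sam
from .model import (
    AA_ORDER,
    AlignmentRecord,
    GeneModel,
    GenomeSequence,
    MotifModel,
    PipelineParams,
    RenscanError,
    revcomp,
)

BASES = "ACGT"

# ---------------------------------------------------------------------------
# Planted motif set: consensus blocks for the canonical NB-LRR domains
# (TIR, coiled-coil, NB-ARC core motifs, LRR repeats), 15 residues each.

_MOTIF_CONSENSUS = [
    # (motif_id, domain_class, consensus)
    ("tir_1", "TIR", "FLSFRGEDTRKTFTG"),
    ("tir_2", "TIR", "YASSSWCLDELVKIM"),
    ("cc_edvid", "CC", "LKKLEDVADELDVLA"),
    ("nb_ploop", "NB", "GGVGKTTLAQLVYND"),
    ("nb_kin2", "NB", "KRYLIVLDDVWNEDR"),
    ("nb_glpl", "NB", "CGGLPLALKVWGDLL"),
    ("lrr_1", "LRR", "LPDSLGKLKHLRYLD"),
    ("lrr_2", "LRR", "LSGLNLSGSIPSELG"),
]

CONSENSUS_PROB = 0.9
DEFAULT_THRESHOLD_BITS = 25.0

DOMAIN_ORDER = {"TIR": 0, "CC": 1, "NB": 2, "LRR": 3}

# class -> domain blocks planted (classification needs the presence set)
_CLASS_DOMAINS = {
    "CC-NB-LRR": ("CC", "NB", "LRR"),
    "TIR-NB-LRR": ("TIR", "NB", "LRR"),
    "CC-NB": ("CC", "NB"),
    "TIR-NB": ("TIR", "NB"),
    "TIR-LRR": ("TIR", "LRR"),
    "NB": ("NB",),
    "TIR": ("TIR",),
    "LRR": ("LRR",),
}


def default_motif_set(threshold_bits: float = DEFAULT_THRESHOLD_BITS) -> list[MotifModel]:
    """The planted position-probability matrices: consensus residue at
    probability 0.9, the remaining mass uniform over the other 19."""
    motifs = []
    off = (1.0 - CONSENSUS_PROB) / 19.0
    for mid, dclass, cons in _MOTIF_CONSENSUS:
        mat = np.full((len(cons), 20), off)
        for i, aa in enumerate(cons):
            mat[i, AA_ORDER.index(aa)] = CONSENSUS_PROB
        motifs.append(MotifModel(mid, dclass, mat, threshold_bits))
    return motifs


# ---------------------------------------------------------------------------
# Codon machinery for gene construction

_CODONS_FOR = {}
from Bio.Data.CodonTable import standard_dna_table as _tab  # noqa: E402
for _codon, _aa in _tab.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()
_STOPS = sorted(_tab.stop_codons)
# linker codons: anything that is neither ATG nor a stop
_LINKER_CODONS = sorted(
    c for c in (a + b + d for a in BASES for b in BASES for d in BASES)
    if c != "ATG" and c not in _tab.stop_codons
)


def _encode_peptide(pep: str, rng) -> str:
    return "".join(_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in pep)


def _linker(n_codons: int, rng) -> str:
    idx = rng.integers(0, len(_LINKER_CODONS), size=n_codons)
    return "".join(_LINKER_CODONS[i] for i in idx)


def _noisy_consensus(cons: str, sub_rate: float, rng) -> str:
    out = []
    for aa in cons:
        if sub_rate > 0 and rng.random() < sub_rate:
            alts = [a for a in AA_ORDER if a != aa]
            out.append(alts[rng.integers(19)])
        else:
            out.append(aa)
    return "".join(out)


@dataclass
class _Construct:
    dna: str                # forward-orientation construct
    cds_start: int          # offsets into dna; for full genes = ATG..stop end
    cds_end: int
    motif_ids: list
    gene_class: str
    completeness: str


def _build_construct(gene_class: str, motifs: Sequence[MotifModel],
                     sub_rate: float, rng) -> _Construct:
    domains = _CLASS_DOMAINS[gene_class]
    by_class: dict[str, list[MotifModel]] = {}
    for m in motifs:
        by_class.setdefault(m.domain_class, []).append(m)
    blocks = []
    for dom in sorted(domains, key=DOMAIN_ORDER.__getitem__):
        for m in by_class[dom]:
            blocks.append(m)
    full = "NB" in domains and "LRR" in domains

    parts: list[str] = []
    motif_offsets: list[tuple[str, int, int]] = []
    if full:
        parts.append("ATG" + _linker(int(rng.integers(2, 6)), rng))
    pos = sum(len(p) for p in parts)
    first_block_start = None
    for i, m in enumerate(blocks):
        pep = _noisy_consensus(m.consensus, sub_rate, rng)
        dna = _encode_peptide(pep, rng)
        if first_block_start is None:
            first_block_start = pos
        motif_offsets.append((m.motif_id, pos, pos + len(dna)))
        parts.append(dna)
        pos += len(dna)
        if i < len(blocks) - 1:
            link = _linker(int(rng.integers(5, 16)), rng)
            parts.append(link)
            pos += len(link)
    if full:
        tail = _linker(int(rng.integers(2, 5)), rng)
        parts.append(tail)
        pos += len(tail)
        parts.append(_STOPS[rng.integers(len(_STOPS))])
        pos += 3
    dna = "".join(parts)
    if full:
        cds_start, cds_end = 0, len(dna)
    else:
        cds_start = motif_offsets[0][1]
        cds_end = motif_offsets[-1][2]
    return _Construct(dna, cds_start, cds_end, [m.motif_id for m in blocks],
                      gene_class, "full" if full else "partial")


# ---------------------------------------------------------------------------
# Truth set


@dataclass
class TruthSet:
    genome: list                    # released genome (gaps masked with N)
    true_models: list
    prior_models: list
    gaps: list                      # (seq_id, start, end, true_fill)
    expression_levels: dict
    motif_set: list
    targets: list = field(default_factory=list)   # enriched intervals (seq_id, s, e)
    true_genome: list = field(default_factory=list)  # pre-masking sequence


def simulate_truth(
    params: PipelineParams,
    n_genes_per_class: dict | None = None,
    n_gaps: int = 3,
    gap_len_range: tuple = (97, 1500),
    cluster_spec: Sequence[tuple] = ((4, 150_000),),
    seed: int = 0,
    genome_len: int = 1_000_000,
    seq_id: str = "chr1",
    motif_sub_rate: float = 0.02,
    id_prefix: str = "RDC0002NLR",
    expressed_fraction: float = 0.5,
) -> TruthSet:
    """Plant NB-LRR genes of the requested classes on a random genome.

    ``cluster_spec`` is a sequence of (n_genes, span_nt) physical clusters;
    remaining genes are placed singly.  ``n_gaps`` N-runs with lengths drawn
    from ``gap_len_range`` are masked into inter-gene sequence near genes
    (inside what will become candidate loci).  The prior annotation carries
    one planted fused pair, one split gene and one missing gene; all other
    priors match the truth exactly.
    """
    rng = np.random.default_rng(seed)
    if n_genes_per_class is None:
        n_genes_per_class = {
            "CC-NB-LRR": 8, "TIR-NB-LRR": 6, "CC-NB": 3, "TIR-NB": 3,
            "TIR-LRR": 2, "NB": 4, "TIR": 2, "LRR": 2,
        }
    for cls in n_genes_per_class:
        if cls not in _CLASS_DOMAINS:
            raise RenscanError(f"unknown gene class {cls!r}")
    motifs = default_motif_set()

    constructs: list[_Construct] = []
    for cls in sorted(n_genes_per_class):
        for _ in range(n_genes_per_class[cls]):
            constructs.append(_build_construct(cls, motifs, motif_sub_rate, rng))
    order = rng.permutation(len(constructs))
    constructs = [constructs[i] for i in order]

    # ---- placement -------------------------------------------------------
    margin = params.flank_ext + 2000
    placements: list[tuple[int, _Construct, str]] = []   # (genome start, construct, strand)
    cursor = margin
    idx = 0
    n_clustered = sum(n for n, _ in cluster_spec)
    if n_clustered > len(constructs):
        raise RenscanError("cluster_spec requests more genes than are planted")
    for n_in_cluster, span in cluster_spec:
        members = constructs[idx:idx + n_in_cluster]
        idx += n_in_cluster
        need = sum(len(c.dna) + 2500 for c in members)
        if need > span:
            raise RenscanError(f"cluster span {span} too small for {n_in_cluster} genes")
        if cursor + span + margin > genome_len:
            raise RenscanError("cluster_spec infeasible on requested genome length")
        pos = cursor
        for c in members:
            pos += int(rng.integers(2000, 2500))
            strand = "+-"[rng.integers(2)]
            placements.append((pos, c, strand))
            pos += len(c.dna)
        cursor += span + 25_000
    for c in constructs[idx:]:
        cursor += int(rng.integers(4000, 12_000))
        if cursor + len(c.dna) + margin > genome_len:
            raise RenscanError("genome_len too small for the requested genes")
        strand = "+-"[rng.integers(2)]
        placements.append((cursor, c, strand))
        cursor += len(c.dna)

    # ---- assemble genome -------------------------------------------------
    background = rng.integers(0, 4, size=genome_len)
    genome_arr = np.frombuffer("".join(BASES[b] for b in background).encode(), dtype="S1").copy()
    true_models: list[GeneModel] = []
    placements.sort(key=lambda p: p[0])
    for serial, (start, c, strand) in enumerate(placements, 1):
        dna = c.dna if strand == "+" else revcomp(c.dna)
        genome_arr[start:start + len(dna)] = np.frombuffer(dna.encode(), dtype="S1")
        if strand == "+":
            g_start, g_end = start + c.cds_start, start + c.cds_end
            frame = g_start % 3
        else:
            g_start = start + len(c.dna) - c.cds_end
            g_end = start + len(c.dna) - c.cds_start
            frame = (genome_len - g_end) % 3
        true_models.append(GeneModel(
            gene_id=f"{id_prefix}{serial:04d}",
            seq_id=seq_id, strand=strand, start=g_start, end=g_end,
            gene_class=c.gene_class, completeness=c.completeness,
            frame=frame, motif_series=list(c.motif_ids),
        ))
    true_seq = genome_arr.tobytes().decode()

    # ---- gaps: mask N-runs in inter-gene sequence near genes -------------
    gaps: list[tuple] = []
    gap_candidates = []
    for i, m in enumerate(true_models):
        nxt_start = true_models[i + 1].start if i + 1 < len(true_models) else genome_len - margin
        room = nxt_start - m.end - 400
        if room > gap_len_range[0] + 100:
            gap_candidates.append((m.end + 150, room - 100))
    if n_gaps > len(gap_candidates):
        raise RenscanError("not enough inter-gene room for the requested gaps")
    chosen = rng.choice(len(gap_candidates), size=n_gaps, replace=False)
    for ci in sorted(int(x) for x in chosen):
        gstart, room = gap_candidates[ci]
        glen = int(rng.integers(gap_len_range[0], min(gap_len_range[1], room) + 1))
        fill = true_seq[gstart:gstart + glen]
        genome_arr[gstart:gstart + glen] = b"N"
        gaps.append((seq_id, gstart, gstart + glen, fill))
    released = genome_arr.tobytes().decode()

    # ---- prior annotation with planted errors ----------------------------
    prior_models: list[GeneModel] = []
    fusable = next((i for i in range(len(true_models) - 1)
                    if true_models[i].seq_id == true_models[i + 1].seq_id
                    and true_models[i].strand == true_models[i + 1].strand), None)
    if fusable is None or len(true_models) < 4:
        raise RenscanError("need at least 4 genes incl. an adjacent same-strand pair "
                           "to plant annotation errors")
    used = {fusable, fusable + 1}
    splittable = next(i for i in range(len(true_models))
                      if i not in used and true_models[i].end - true_models[i].start > 300)
    used.add(splittable)
    missing = next(i for i in range(len(true_models)) if i not in used)
    used.add(missing)

    pserial = 0
    for i, m in enumerate(true_models):
        pserial += 1
        pid = f"Solyc01g{pserial * 10:06d}"
        if i == fusable:
            nxt = true_models[i + 1]
            prior_models.append(GeneModel(
                gene_id=pid, seq_id=m.seq_id, strand=m.strand,
                start=m.start, end=nxt.end, gene_class=m.gene_class,
                completeness=m.completeness, frame=m.frame,
                truncated=m.truncated))
        elif i == fusable + 1:
            continue                      # covered by the fused prior model
        elif i == splittable:
            mid = (m.start + m.end) // 2
            for half, (s, e) in enumerate(((m.start, mid), (mid + 1, m.end))):
                prior_models.append(GeneModel(
                    gene_id=f"{pid}.{half + 1}", seq_id=m.seq_id, strand=m.strand,
                    start=s, end=e, gene_class="NB", completeness="partial",
                    frame=m.frame))
        elif i == missing:
            continue                      # planted missing gene
        else:
            prior_models.append(GeneModel(
                gene_id=pid, seq_id=m.seq_id, strand=m.strand,
                start=m.start, end=m.end, gene_class=m.gene_class,
                completeness=m.completeness, frame=m.frame,
                truncated=m.truncated))

    # ---- expression truth ------------------------------------------------
    expression_levels = {}
    n_expressed = int(round(expressed_fraction * len(true_models)))
    zero_idx = set(int(i) for i in rng.choice(len(true_models),
                                              size=len(true_models) - n_expressed,
                                              replace=False))
    for i, m in enumerate(true_models):
        if i in zero_idx:
            expression_levels[m.gene_id] = 0
        else:
            expression_levels[m.gene_id] = int(rng.integers(20, 400))

    # ---- capture targets: genes plus masked gaps (bait territory) --------
    targets = [(seq_id, m.start, m.end) for m in true_models]
    targets += [(sid, max(0, s - 300), min(genome_len, e + 300)) for sid, s, e, _ in gaps]
    targets.sort(key=lambda t: t[1])

    return TruthSet(
        genome=[GenomeSequence(seq_id, released)],
        true_models=true_models,
        prior_models=prior_models,
        gaps=gaps,
        expression_levels=expression_levels,
        motif_set=motifs,
        targets=targets,
        true_genome=[GenomeSequence(seq_id, true_seq)],
    )


# ---------------------------------------------------------------------------
# gDNA read simulation


def _mutate(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    for i in range(len(arr)):
        if rng.random() < error_rate:
            alts = [b for b in BASES if b != arr[i]]
            arr[i] = alts[rng.integers(3)]
    return "".join(arr)


class _MultiplicityIndex:
    """Exact-match placement counter.

    A 2-bit-packed 32-mer table over both strands of the released genome
    serves as prefilter (k = 32 packs exactly into uint64, so codes are
    collision-free); a full string scan runs only for reads whose leading
    32-mer is non-unique."""

    K = 32
    _CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(self, genome: list[GenomeSequence]):
        self.seqs = {g.seq_id: g.residues for g in genome}
        dup_codes: set[int] = set()
        all_codes = []
        for s in self.seqs.values():
            for strand_seq in (s, revcomp(s)):
                codes = self._pack(strand_seq)
                if codes is not None:
                    all_codes.append(codes)
        if all_codes:
            cat = np.concatenate(all_codes)
            uniq, counts = np.unique(cat, return_counts=True)
            dup_codes = set(int(c) for c in uniq[counts > 1])
        self._dups = dup_codes

    @classmethod
    def _pack(cls, seq: str) -> np.ndarray | None:
        n = len(seq)
        if n < cls.K:
            return None
        vals = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint64)
        for b, v in cls._CODE.items():
            lut[ord(b)] = v
        is_n = vals == ord("N")
        v2 = lut[vals]
        m = n - cls.K + 1
        codes = np.zeros(m, dtype=np.uint64)
        for j in range(cls.K):
            codes = (codes << np.uint64(2)) | v2[j:j + m]
        if is_n.any():
            from numpy.lib.stride_tricks import sliding_window_view
            bad = sliding_window_view(is_n, cls.K).any(axis=1)
            codes = codes[~bad]
        return codes

    def _lead_code(self, read: str) -> int | None:
        head = read[:self.K]
        if len(head) < self.K or "N" in head:
            return None
        c = 0
        for b in head:
            c = ((c << 2) | self._CODE[b]) & 0xFFFFFFFFFFFFFFFF
        return c

    def n_best_hits(self, read: str) -> int:
        code = self._lead_code(read)
        if code is None or code not in self._dups:
            return 1
        total = 0
        rc = revcomp(read)
        for s in self.seqs.values():
            total += s.count(read) + s.count(rc)
        return max(total, 1)


def _merge_intervals(intervals):
    out = []
    for sid, s, e in sorted(intervals):
        if out and out[-1][0] == sid and s <= out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([sid, s, e])
    return [tuple(x) for x in out]


def simulate_gdna_reads(
    truth: TruthSet,
    read_len: int = 250,
    insert_mean: int = 700,
    insert_sd: int = 70,
    depth_on_target: float = 30.0,
    on_target_fraction: float = 0.5,
    error_rate: float = 0.0,
    seed: int = 0,
    sam_path=None,
    fastq_prefix=None,
) -> list[AlignmentRecord]:
    """Paired-end enriched gDNA reads.

    With probability ``on_target_fraction`` a fragment is drawn to overlap a
    capture target, otherwise uniformly from non-target genome.  Fragment
    sequences come from the pre-masking genome (so gap interiors carry real
    sequence), but each read is placed in the SAM at its true origin and its
    ``n_best_hits`` is the number of exact-match placements of the read
    against the released genome.
    """
    if insert_mean < read_len:
        raise RenscanError("insert_mean must be at least read_len")
    rng = np.random.default_rng(seed)
    true_seqs = {g.seq_id: g.residues for g in (truth.true_genome or truth.genome)}
    lengths = {sid: len(s) for sid, s in true_seqs.items()}
    targets = truth.targets or [(m.seq_id, m.start, m.end) for m in truth.true_models]
    targets = _merge_intervals(targets)   # overlapping targets must not double-sample
    target_len = sum(e - s for _, s, e in targets)
    if target_len == 0:
        raise RenscanError("truth set has no capture targets")
    # A fragment only needs to overlap its target, so per-target pair counts
    # scale with (length + insert - 1): that makes the interior depth of
    # every target equal to depth_on_target in expectation.
    eff = np.array([(e - s) + insert_mean - 1 for _, s, e in targets], dtype=float)
    n_target_pairs = int(np.ceil(depth_on_target * eff.sum() / (2 * read_len)))
    n_pairs = int(np.ceil(n_target_pairs / on_target_fraction))
    weights = eff / eff.sum()
    index = _MultiplicityIndex(truth.genome)

    def overlaps_target(sid, fs, fe):
        return any(sid == t_sid and fs < te and fe > ts for t_sid, ts, te in targets)

    records: list[AlignmentRecord] = []
    sam_rows = []
    fastq1, fastq2 = [], []
    for p in range(n_pairs):
        frag_len = max(read_len, int(round(rng.normal(insert_mean, insert_sd))))
        if rng.random() < on_target_fraction:
            ti = rng.choice(len(targets), p=weights)
            sid, ts, te = targets[ti]
            lo = max(0, ts - frag_len + 1)
            hi = min(lengths[sid] - frag_len, te - 1)
            if hi < lo:
                lo = hi = max(0, min(ts, lengths[sid] - frag_len))
            fs = int(rng.integers(lo, hi + 1))
        else:
            for _ in range(200):
                sid = list(lengths)[int(rng.integers(len(lengths)))]
                fs = int(rng.integers(0, lengths[sid] - frag_len + 1))
                if not overlaps_target(sid, fs, fs + frag_len):
                    break
        fe = fs + frag_len
        frag = true_seqs[sid][fs:fe]
        r1 = _mutate(frag[:read_len], error_rate, rng)
        r2_fwd = frag[-read_len:]
        r2 = _mutate(revcomp(r2_fwd), error_rate, rng)
        rid = f"sim_pair_{p:07d}"
        n1 = index.n_best_hits(r1)
        n2 = index.n_best_hits(revcomp(r2))
        cig = f"{read_len}M"
        records.append(AlignmentRecord(rid, "first", sid, fs, cig, 60, r1, n1))
        records.append(AlignmentRecord(rid, "second", sid, fe - read_len, cig, 60,
                                       revcomp(r2), n2))
        if sam_path is not None:
            sam_rows.append((rid, "first", sid, fs, cig, 60, r1, False, n1,
                             sid, fe - read_len, frag_len))
            sam_rows.append((rid, "second", sid, fe - read_len, cig, 60,
                             revcomp(r2), True, n2, sid, fs, -frag_len))
        if fastq_prefix is not None:
            fastq1.append((rid, r1))
            fastq2.append((rid, r2))
    if sam_path is not None:
        write_sam(sam_rows, lengths, sam_path)
    if fastq_prefix is not None:
        for suffix, reads in (("_R1.fastq", fastq1), ("_R2.fastq", fastq2)):
            with open(f"{fastq_prefix}{suffix}", "w") as fh:
                for rid, seq in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return records


# ---------------------------------------------------------------------------
# cDNA read simulation


def simulate_cdna_reads(
    truth: TruthSet,
    seed: int = 0,
    total_reads: int = 20_000,
    read_len: int = 250,
    sam_path=None,
) -> list[AlignmentRecord]:
    """Single-end cDNA reads against the gene-model sequence set (one
    reference per gene).  Per-gene counts are multinomial around the truth
    expression levels; genes at level 0 receive no reads.  Reads from genes
    whose transcript sequence is duplicated verbatim carry n_best_hits > 1.
    """
    rng = np.random.default_rng(seed)
    genome = {g.seq_id: g.residues for g in (truth.true_genome or truth.genome)}
    transcripts = {}
    for m in truth.true_models:
        t = genome[m.seq_id][m.start:m.end]
        transcripts[m.gene_id] = t if m.strand == "+" else revcomp(t)
    # verbatim-duplicate groups share multi-mapping status
    groups: dict[str, int] = {}
    for gid, t in transcripts.items():
        groups[t] = groups.get(t, 0) + 1
    levels = np.array([truth.expression_levels.get(m.gene_id, 0)
                       for m in truth.true_models], dtype=float)
    records: list[AlignmentRecord] = []
    sam_rows = []
    if levels.sum() > 0 and total_reads > 0:
        counts = rng.multinomial(total_reads, levels / levels.sum())
        for m, c in zip(truth.true_models, counts):
            t = transcripts[m.gene_id]
            nh = groups[t]
            rl = min(read_len, len(t))
            for j in range(int(c)):
                start = int(rng.integers(0, len(t) - rl + 1))
                seq = t[start:start + rl]
                rid = f"cdna_{m.gene_id}_{j:05d}"
                rec = AlignmentRecord(rid, "unpaired", m.gene_id, start,
                                      f"{rl}M", 42, seq, nh)
                records.append(rec)
                sam_rows.append((rid, "unpaired", m.gene_id, start, f"{rl}M",
                                 42, seq, False, nh, None, 0, 0))
    if sam_path is not None:
        refs = {gid: len(t) for gid, t in transcripts.items()}
        write_sam(sam_rows, refs, sam_path)
    return records
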