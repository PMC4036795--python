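"""Assembly-gap detection and closure by bidirectional read "arches".

An N-run inside a candidate locus is closed by iterative consensus
extension: the flank left of the gap seeds a contig that is extended
rightwards by reads overlapping its end (at least ``min_overlap`` nt, at
most ``max_mismatch_rate`` mismatches), taking a majority vote per new
column; a second contig grows symmetrically leftwards from the right flank.
When the two contigs overlap by ``min_overlap`` the gap is closed and the
sequence between the flanks becomes the fill — whose length need not equal
the N-run, since assembly gap lengths are estimates.  A closure additionally
requires mate-pair support: at least one read pair with one mate in each
flank contig at a plausible insert distance.
"""

from __future__ import annotations

import re
from typing import Sequence

from .model import (
    AlignmentRecord,
    CandidateLocus,
    GapRecord,
    GenomeSequence,
    PipelineParams,
    RenscanError,
    revcomp,
)

_N_RUN = re.compile(r"N+")


def find_gaps(
    genome: Sequence[GenomeSequence],
    loci: Sequence[CandidateLocus],
    params: PipelineParams,
) -> list[GapRecord]:
    """Maximal N-runs of length >= min_gap_run intersecting any locus."""
    by_seq: dict[str, list] = {}
    for loc in loci:
        by_seq.setdefault(loc.seq_id, []).append((loc.start, loc.end))
    gaps: list[GapRecord] = []
    for g in genome:
        spans = by_seq.get(g.seq_id, [])
        if not spans:
            continue
        for m in _N_RUN.finditer(g.residues):
            s, e = m.start(), m.end()
            if e - s < params.min_gap_run:
                continue
            if any(s < le and e > ls for ls, le in spans):
                gaps.append(GapRecord(g.seq_id, s, e))
    gaps.sort(key=lambda r: (r.seq_id, r.start))
    return gaps


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_extension_reads(contig: str, reads: Sequence[str], params: PipelineParams):
    """Reads (already oriented) whose prefix overlaps the contig's 3' end.

    Candidate overlaps are located by exact match of the contig's terminal
    ``min_overlap``-mer within the read; the full overlap is then verified
    under ``max_mismatch_rate``.  Returns (overlap_len, read) pairs for reads
    extending at least one base beyond the contig end.
    """
    mo = params.min_overlap
    if len(contig) < mo:
        return []
    tail = contig[-mo:]
    out = []
    for r in reads:
        start = 0
        while True:
            p = r.find(tail, start)
            if p < 0:
                break
            o = p + mo            # implied overlap with the contig end
            if o < len(r):
                o_eff = min(o, len(contig))
                mm = _mismatches(contig[-o_eff:], r[o - o_eff:o])
                if mm <= params.max_mismatch_rate * o_eff:
                    out.append((o, r))
                    break
            start = p + 1
    return out


def _extend_right(contig: str, reads: Sequence[str], params: PipelineParams):
    """One consensus-extension round.  Returns (new_contig, tie_aborted)."""
    ext_reads = _best_extension_reads(contig, reads, params)
    if not ext_reads:
        return contig, False
    columns: dict[int, dict] = {}
    for o, r in ext_reads:
        for i, base in enumerate(r[o:]):
            columns.setdefault(i, {}).setdefault(base, 0)
            columns[i][base] += 1
    new = []
    tie = False
    for i in range(len(columns)):
        votes = columns.get(i)
        if not votes:
            break
        ordered = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ordered) > 1 and ordered[0][1] == ordered[1][1]:
            tie = True      # 50/50 column: stop rather than guess
            break
        new.append(ordered[0][0])
    return contig + "".join(new), tie


def _try_merge(left: str, right: str, params: PipelineParams) -> str | None:
    """Merge two contigs when left's tail overlaps right's head by at least
    min_overlap; candidates are anchored on right's leading min_overlap-mer."""
    mo = params.min_overlap
    if len(left) < mo or len(right) < mo:
        return None
    head = right[:mo]
    best = None
    start = 0
    while True:
        p = left.find(head, start)
        if p < 0:
            break
        o = len(left) - p
        if o >= mo:
            o_eff = min(o, len(right))
            mm = _mismatches(left[p:p + o_eff], right[:o_eff])
            if mm <= params.max_mismatch_rate * o_eff:
                best = left[:p] + right   # prefer leftmost anchor (largest overlap)
                break
        start = p + 1
    return best


def close_gap(
    gap: GapRecord,
    reads: Sequence[AlignmentRecord],
    genome: Sequence[GenomeSequence],
    params: PipelineParams,
) -> GapRecord:
    """Attempt closure of an open gap from flanking reads.

    Reads are used strand-aware: every read contributes both its stored
    orientation and its reverse complement to the candidate pool.  Status is
    ``closed`` only when the two flank contigs merge with >= min_overlap
    overlap *and* at least one read pair supports the joint at a plausible
    insert distance (within 3 insert s.d.); otherwise ``reduced`` when any
    bases were recovered, else ``open``.
    """
    if gap.status != "open":
        raise RenscanError(f"gap at {gap.seq_id}:{gap.start} is not open")
    seq = next((g.residues for g in genome if g.seq_id == gap.seq_id), None)
    if seq is None:
        raise RenscanError(f"unknown sequence {gap.seq_id!r}")
    seed = params.read_len  # anchor length taken from each flank
    left_seed = seq[max(0, gap.start - seed):gap.start].lstrip("N")
    right_seed = seq[gap.end:gap.end + seed].rstrip("N")
    if len(left_seed) < params.min_overlap or len(right_seed) < params.min_overlap:
        return GapRecord(gap.seq_id, gap.start, gap.end, "open", "", 0)

    pool: list[str] = []
    by_pair: dict[str, dict] = {}
    for r in reads:
        if not r.read_seq or "N" in r.read_seq:
            continue
        pool.append(r.read_seq)
        pool.append(revcomp(r.read_seq))
        by_pair.setdefault(r.read_id, {})[r.mate_flag] = r.read_seq
    pool = sorted(set(pool))
    if not pool:
        return GapRecord(gap.seq_id, gap.start, gap.end, "open", "", 0)

    # grow left contig rightwards; grow the right contig leftwards by
    # extending its reverse complement rightwards with the same routine
    left = left_seed
    right_rc = revcomp(right_seed)
    merged = None
    tie_hit = False
    for _ in range(params.max_close_iters):
        right = revcomp(right_rc)
        merged = _try_merge(left, right, params)
        if merged is not None:
            break
        new_left, tie_l = _extend_right(left, pool, params)
        new_right_rc, tie_r = _extend_right(right_rc, pool, params)
        tie_hit = tie_hit or tie_l or tie_r
        if new_left == left and new_right_rc == right_rc:
            break
        left, right_rc = new_left, new_right_rc
    if merged is None:
        right = revcomp(right_rc)
        merged = _try_merge(left, right, params)

    # pair validation runs in genome context: mates may sit in the flanking
    # sequence beyond the contigs, so embed the assembly between its flanks
    ctx_w = params.insert_mean + 3 * params.insert_sd
    ctx_left = seq[max(0, gap.start - len(left_seed) - ctx_w):gap.start - len(left_seed)]
    ctx_right = seq[gap.end + len(right_seed):gap.end + len(right_seed) + ctx_w]

    if merged is not None:
        fill = merged[len(left_seed):len(merged) - len(right_seed)]
        ctx = ctx_left + merged + ctx_right
        lo = len(ctx_left) + len(left_seed)
        n_pairs = _count_support_pairs(ctx, lo, lo + len(fill), by_pair, params)
        if n_pairs == 0:
            # pair validation is mandatory: an unsupported joint stays reduced
            return _reduced_record(gap, left, right_rc, left_seed, right_seed, 0)
        if not fill:
            # flanks directly adjacent in truth: borrow one flank base so the
            # record carries the joint context
            return GapRecord(gap.seq_id, gap.start - 1, gap.end, "closed",
                             left_seed[-1], n_pairs)
        return GapRecord(gap.seq_id, gap.start, gap.end, "closed", fill, n_pairs)

    left_ext = left[len(left_seed):]
    right_ext = revcomp(right_rc)[:max(0, len(right_rc) - len(right_seed))]
    if not left_ext and not right_ext:
        return GapRecord(gap.seq_id, gap.start, gap.end, "open", "", 0)
    partial = left + "N" + revcomp(right_rc)
    ctx = ctx_left + partial + ctx_right
    lo = len(ctx_left) + len(left_seed)
    hi = len(ctx_left) + len(partial) - len(right_seed)
    return _reduced_record(gap, left, right_rc, left_seed, right_seed,
                           _count_support_pairs(ctx, lo, hi, by_pair, params))


def _reduced_record(gap, left, right_rc, left_seed, right_seed, n_pairs):
    left_ext = left[len(left_seed):]
    right = revcomp(right_rc)
    right_ext = right[:max(0, len(right) - len(right_seed))]
    remaining = max(1, gap.length - len(left_ext) - len(right_ext))
    fill = left_ext + "N" * remaining + right_ext
    return GapRecord(gap.seq_id, gap.start, gap.end, "reduced", fill, n_pairs)


def _count_support_pairs(context: str, fill_lo: int, fill_hi: int,
                         by_pair: dict, params: PipelineParams) -> int:
    """Read pairs whose fragment spans into the filled interval of the
    assembled context at a plausible insert distance (within 3 insert s.d.
    of the mean).  Mates may lie in the flanking sequence: the pair is the
    arch that ties the fill to both sides."""
    n = 0
    lo = params.insert_mean - 3 * params.insert_sd
    hi = params.insert_mean + 3 * params.insert_sd
    fill_hi = max(fill_hi, fill_lo + 1)   # empty fill: the joint itself
    for mates in by_pair.values():
        if "first" not in mates or "second" not in mates:
            continue
        r1, r2 = mates["first"], mates["second"]
        placed = []
        for r in (r1, r2):
            p = context.find(r)
            if p < 0:
                p = context.find(revcomp(r))
            placed.append(p)
        if placed[0] < 0 or placed[1] < 0:
            continue
        frag_lo = min(placed)
        frag_hi = max(placed[0] + len(r1), placed[1] + len(r2))
        if lo <= frag_hi - frag_lo <= hi and frag_lo < fill_hi and frag_hi > fill_lo:
            n += 1
    return n


def close_all_gaps(gaps, reads, genome, params) -> list[GapRecord]:
    """Close each gap using the reads mapped near its flanks."""
    window = params.insert_mean + 3 * params.insert_sd + params.read_len
    out = []
    for gap in gaps:
        near = [r for r in reads
                if r.seq_id == gap.seq_id
                and r.start + params.read_len > gap.start - window
                and r.start < gap.end + window]
        out.append(close_gap(gap, near, genome, params))
    return out


def apply_patches(
    genome: Sequence[GenomeSequence],
    gaps: Sequence[GapRecord],
) -> tuple[list[GenomeSequence], list[tuple]]:
    """Replace closed gap intervals with their fills.

    Returns the patched genome and a liftover table of
    (seq_id, old_start, old_end, new_start, new_end) per closed gap.
    """
    patched = []
    liftover: list[tuple] = []
    for g in genome:
        mine = sorted((x for x in gaps if x.seq_id == g.seq_id and x.status == "closed"),
                      key=lambda x: x.start)
        parts = []
        pos = 0
        shift = 0
        for gap in mine:
            parts.append(g.residues[pos:gap.start])
            new_start = gap.start + shift
            parts.append(gap.fill_seq)
            new_end = new_start + len(gap.fill_seq)
            liftover.append((g.seq_id, gap.start, gap.end, new_start, new_end))
            shift += len(gap.fill_seq) - gap.length
            pos = gap.end
        parts.append(g.residues[pos:])
        patched.append(GenomeSequence(g.seq_id, "".join(parts)))
    return patched, liftover


def write_liftover(liftover, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\told_start\told_end\tnew_start\tnew_end\n")
        for row in liftover:
            fh.write("\t".join(str(x) for x in row) + "\n")
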