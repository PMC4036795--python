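"""Per-base read depth and candidate-locus calling.

The locus rule: maximal runs with depth strictly above ``min_depth`` and
length at least ``min_run`` nt are extended by ``flank_ext`` nt on both
sides, clipped to the sequence, and overlapping or book-ended extensions are
merged.  "Higher than 20x" is read literally as > 20 (a run at exactly 20x
never seeds a locus).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .io import cigar_ref_spans
from .model import CandidateLocus, CoverageTrack, GenomeSequence, PipelineParams, RenscanError


def compute_coverage(alignments: Iterable, genome: list[GenomeSequence]) -> list[CoverageTrack]:
    """Per-base depth from alignment records.

    A position's depth is the number of alignments whose CIGAR consumes that
    reference base; deletions (D) count as consumed — a spanning read is
    evidence the region was captured.  Mates are counted independently and
    duplicates are not collapsed.
    """
    lengths = {g.seq_id: len(g) for g in genome}
    diffs = {sid: np.zeros(n + 1, dtype=np.int64) for sid, n in lengths.items()}
    for aln in alignments:
        if aln.seq_id not in diffs:
            raise RenscanError(f"alignment {aln.read_id!r} references unknown "
                               f"sequence {aln.seq_id!r}")
        d = diffs[aln.seq_id]
        n = lengths[aln.seq_id]
        for s, e in cigar_ref_spans(aln.cigar, aln.start):
            if s >= n:
                continue
            d[s] += 1
            d[min(e, n)] -= 1
    return [CoverageTrack(sid, np.cumsum(diffs[sid][:-1])) for sid in lengths]


def call_candidate_loci(track: CoverageTrack, params: PipelineParams) -> list[CandidateLocus]:
    """Call extended, merged candidate loci from one coverage track."""
    above = track.depth > params.min_depth
    if not above.any():
        return []
    # maximal runs of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= params.min_run
    starts, ends = starts[keep], ends[keep]
    n = len(track.depth)
    loci: list[CandidateLocus] = []
    for s, e in zip(starts, ends):
        s = max(0, int(s) - params.flank_ext)
        e = min(n, int(e) + params.flank_ext)
        if loci and s <= loci[-1].end:        # overlap or book-ended: merge
            prev = loci[-1]
            prev.end = max(prev.end, e)
            prev.n_seed_runs += 1
        else:
            loci.append(CandidateLocus(track.seq_id, s, e, 1))
    return loci


def call_all_loci(tracks: list[CoverageTrack], params: PipelineParams) -> list[CandidateLocus]:
    out = []
    for t in tracks:
        out.extend(call_candidate_loci(t, params))
    return out
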