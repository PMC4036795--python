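"""Domain types shared across the pipeline.

All genomic intervals are 0-based half-open internally.  Conversion to the
1-based inclusive convention of GFF3 (and back) happens only in :mod:`renscan.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

# Table 2 taxonomy: domain-presence classes of the NB-LRR (NLR) complement.
FULL_CLASSES = ("CC-NB-LRR", "TIR-NB-LRR")
PARTIAL_CLASSES = ("CC-NB", "TIR-LRR", "TIR-NB", "NB", "TIR", "LRR")
GENE_CLASSES = FULL_CLASSES + PARTIAL_CLASSES + ("none",)

DOMAIN_CLASSES = ("TIR", "CC", "NB", "LRR", "other")

VALID_RESIDUES = frozenset("ACGTN")

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter amino-acid order
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class RenscanError(Exception):
    """Base class for pipeline errors."""


class ParseError(RenscanError):
    """Malformed input file."""


class ValidationError(RenscanError):
    """A domain-type invariant was violated."""


@dataclass
class PipelineParams:
    """Tunable pipeline parameters.

    The depth/run/flank thresholds implement the candidate-locus rule
    (coverage strictly above ``min_depth`` over at least ``min_run`` nt,
    extended by ``flank_ext`` on both sides).  Bait design tiles unique
    ``bait_len``-mers at stride ``bait_step``.  Cluster detection uses the
    "``cluster_min_genes`` or more genes within ``cluster_window`` nt" rule.
    NB-ARC peptides shorter than ``nbarc_min_fraction`` of the reference
    domain length are excluded from phylogenetic export.  The gap-closing
    knobs (``min_gap_run`` .. ``max_close_iters``) control N-run detection
    and the bidirectional read-overlap extension; ``insert_mean`` and
    ``insert_sd`` define the plausible mate-pair distance used to validate a
    closure.
    """

    min_depth: int = 20          # reads; locus rule is strictly > min_depth
    min_run: int = 45            # nt
    flank_ext: int = 500         # nt
    bait_len: int = 120          # nt
    bait_step: int = 60          # nt
    cluster_min_genes: int = 4
    cluster_window: int = 200_000    # nt, inclusive at the boundary
    nbarc_min_fraction: float = 0.5  # strictly-less-than excludes
    min_gap_run: int = 10        # nt
    min_overlap: int = 30        # nt, gap-closing seed overlap
    max_mismatch_rate: float = 0.02
    max_close_iters: int = 50
    rng_seed: int = 0
    # plumbing knobs beyond the headline constants
    max_intra_series_gap: int = 1500  # nt between consecutive motif hits
    insert_mean: int = 700       # nt, paired-end insert size
    insert_sd: int = 70          # nt
    read_len: int = 250          # nt

    _POSITIVE_INTS = (
        "min_depth", "min_run", "bait_len", "bait_step",
        "cluster_min_genes", "cluster_window", "min_gap_run", "min_overlap",
        "max_close_iters", "max_intra_series_gap", "insert_mean", "insert_sd",
        "read_len",
    )
    _FRACTIONS = ("nbarc_min_fraction", "max_mismatch_rate")

    def __post_init__(self) -> None:
        for name in self._POSITIVE_INTS:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v <= 0:
                raise ValidationError(f"{name} must be a strictly positive integer, got {v!r}")
        # flank_ext=0 is allowed: it disables flank extension entirely
        if not isinstance(self.flank_ext, (int, np.integer)) or self.flank_ext < 0:
            raise ValidationError(f"flank_ext must be a non-negative integer, "
                                  f"got {self.flank_ext!r}")
        for name in self._FRACTIONS:
            v = float(getattr(self, name))
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v!r}")
        if not isinstance(self.rng_seed, (int, np.integer)):
            raise ValidationError(f"rng_seed must be an integer, got {self.rng_seed!r}")
        if self.bait_step > self.bait_len:
            raise ValidationError("bait_step must not exceed bait_len")

    # flat key=value config round-trip -------------------------------------
    def to_config(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_config(cls, path) -> "PipelineParams":
        kwargs = {}
        names = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ParseError(f"line {lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in names:
                    raise ParseError(f"line {lineno}: unknown parameter {key!r}")
                typ = names[key].type
                if typ in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = int(value)
        return cls(**kwargs)


@dataclass
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}; N is a first-class residue
    (assembly gaps are N-runs)."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValidationError("empty seq_id")
        if not self.residues:
            raise ValidationError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"{self.seq_id}: illegal residue(s) {sorted(bad)!r} (alphabet is ACGTN)")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentRecord:
    """One mapped read.  ``n_best_hits`` carries the number of equally-best
    placements (reads mapping more than once are dropped by the expression
    filter)."""

    read_id: str
    mate_flag: str          # {first, second, unpaired}
    seq_id: str
    start: int              # 0-based reference position
    cigar: str
    mapq: int
    read_seq: str
    n_best_hits: int = 1

    def __post_init__(self) -> None:
        if self.mate_flag not in ("first", "second", "unpaired"):
            raise ValidationError(f"bad mate_flag {self.mate_flag!r}")
        if self.start < 0:
            raise ValidationError(f"{self.read_id}: negative start")
        if self.n_best_hits < 1:
            raise ValidationError(f"{self.read_id}: n_best_hits < 1")


@dataclass
class MotifHit:
    """A scored occurrence of an amino-acid motif, mapped back to genomic
    nucleotide coordinates through frame and strand."""

    motif_id: str
    domain_class: str
    seq_id: str
    strand: str             # {+, -}
    frame: int              # {0, 1, 2}
    nt_start: int
    nt_end: int
    score: float            # bits

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValidationError(f"bad frame {self.frame!r}")
        if self.nt_end <= self.nt_start:
            raise ValidationError("empty motif hit interval")


@dataclass
class GeneModel:
    """A classified NB-LRR gene model.

    ``completeness`` is ``full`` only for models with both NB and LRR
    evidence (the minimal domain structure of a full-length gene); a
    full-class model whose start/stop prediction failed is demoted to
    ``partial`` with a ``truncated`` flag.
    """

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    gene_class: str
    completeness: str       # {full, partial}
    frame: int = 0
    motif_series: list = field(default_factory=list)
    expressed: str = "unknown"   # {yes, no, unknown}
    truncated: str = ""          # "", "5prime", "3prime"

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(f"{self.gene_id}: unknown gene_class {self.gene_class!r}")
        if self.completeness not in ("full", "partial"):
            raise ValidationError(f"{self.gene_id}: bad completeness {self.completeness!r}")
        if self.start >= self.end:
            raise ValidationError(f"{self.gene_id}: start >= end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.completeness == "full" and self.gene_class not in FULL_CLASSES:
            raise ValidationError(
                f"{self.gene_id}: completeness=full requires a full-length class, "
                f"got {self.gene_class}")
        if self.gene_class in FULL_CLASSES and self.completeness == "partial" \
                and not self.truncated:
            raise ValidationError(
                f"{self.gene_id}: partial {self.gene_class} only allowed when truncated")
        if self.expressed not in ("yes", "no", "unknown"):
            raise ValidationError(f"{self.gene_id}: bad expressed {self.expressed!r}")


@dataclass
class MotifModel:
    """Position-probability matrix over the 20 amino acids with a bit-score
    threshold; ``domain_class`` ties the motif to an NB-LRR domain."""

    motif_id: str
    domain_class: str
    matrix: np.ndarray      # width x 20, rows sum to 1
    score_threshold: float  # bits

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValidationError(f"{self.motif_id}: unknown domain_class {self.domain_class!r}")
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValidationError(f"{self.motif_id}: matrix must be width x 20")
        if self.matrix.shape[0] < 4:
            raise ValidationError(f"{self.motif_id}: motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError(f"{self.motif_id}: matrix rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.matrix.argmax(axis=1))


@dataclass
class CandidateLocus:
    """Depth-supported interval after flank extension and merging; the unit
    handed to motif annotation."""

    seq_id: str
    start: int
    end: int
    n_seed_runs: int = 1


@dataclass
class CoverageTrack:
    seq_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValidationError(f"{self.seq_id}: negative depth")


@dataclass
class CorrectionEvent:
    """Reconciliation outcome of new models versus a prior annotation."""

    event_type: str         # {split, merge, boundary, novel, confirmed, unsupported}
    prior_ids: list
    new_ids: list
    seq_id: str = ""
    span: tuple = (0, 0)
    needs_review: bool = False

    def __post_init__(self) -> None:
        t, np_, nn = self.event_type, len(self.prior_ids), len(self.new_ids)
        ok = {
            "split": np_ == 1 and nn >= 2,
            "merge": np_ >= 2 and nn == 1,
            "boundary": np_ >= 1 and nn >= 1,
            "novel": np_ == 0 and nn == 1,
            "confirmed": np_ == 1 and nn == 1,
            "unsupported": np_ == 1 and nn == 0,
        }
        if t not in ok:
            raise ValidationError(f"unknown event_type {t!r}")
        if not ok[t]:
            raise ValidationError(f"{t}: bad cardinality |prior|={np_}, |new|={nn}")


@dataclass
class GapRecord:
    """An assembly N-run with its closure status.

    ``fill_seq`` replaces ``[start, end)`` when closed (its length need not
    equal the N-run: real gap lengths are estimates); a ``reduced`` record
    keeps a shorter internal N-run.
    """

    seq_id: str
    start: int
    end: int
    status: str = "open"    # {closed, reduced, open}
    fill_seq: str = ""
    n_support_pairs: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("closed", "reduced", "open"):
            raise ValidationError(f"bad gap status {self.status!r}")
        if self.status == "closed" and ("N" in self.fill_seq or not self.fill_seq):
            raise ValidationError("closed gap must carry an N-free fill_seq")
        if self.status == "open" and self.fill_seq:
            raise ValidationError("open gap must not carry fill_seq")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionRecord:
    gene_id: str
    unique_reads: int
    expressed: bool

    def __post_init__(self) -> None:
        if self.unique_reads < 0:
            raise ValidationError(f"{self.gene_id}: negative read count")
        if self.expressed != (self.unique_reads >= 1):
            raise ValidationError(f"{self.gene_id}: expressed flag contradicts count")


@dataclass
class ClusterRecord:
    """A physical gene cluster: cluster_min_genes or more NB-LRRs whose
    first-start-to-last-end span fits within cluster_window."""

    seq_id: str
    member_ids: list
    span_start: int
    span_end: int


@dataclass
class DistributionTest:
    chi2: float
    df: int
    p_value: float
    observed: dict
    expected: dict


def classify_presence(domains: Iterable[str]) -> tuple[str, str]:
    """Map a domain-class presence set to (gene_class, completeness).

    TIR takes precedence: with TIR present the CC signal is ignored.  In the
    non-TIR branch NB+LRR defaults to CC-NB-LRR even without a CC hit (the
    CNL class is less sharply defined at the N-terminus and the taxonomy has
    no plain NB-LRR class).  Full-length means NB and LRR both present.
    """
    present = set(domains) & {"TIR", "CC", "NB", "LRR"}
    nb, lrr, tir, cc = "NB" in present, "LRR" in present, "TIR" in present, "CC" in present
    if tir:
        if nb and lrr:
            cls = "TIR-NB-LRR"
        elif nb:
            cls = "TIR-NB"
        elif lrr:
            cls = "TIR-LRR"
        else:
            cls = "TIR"
    else:
        if nb and lrr:
            cls = "CC-NB-LRR"
        elif cc and nb:
            cls = "CC-NB"
        elif nb:
            cls = "NB"
        elif lrr:
            cls = "LRR"
        else:
            cls = "none"
    return cls, ("full" if (nb and lrr) else "partial")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
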