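"""Genome-distribution analyses, complement tallies and the end-to-end
pipeline driver.

Clusters follow the "four or more genes within 200 kb or less" rule:
maximal greedy-left runs of genes (sorted by start, strand-agnostic) whose
first-start-to-last-end span stays within the window, inclusive at exactly
the window size; a gene belongs to at most one cluster.  The chromosomal
distribution test compares observed per-chromosome counts with expectations
proportional to chromosome length (chi-square, df = #chromosomes - 1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import annotate as _annotate
from . import coverage as _coverage
from . import expression as _expression
from . import gapfill as _gapfill
from . import io as _io
from .reconcile import reconcile as _reconcile_models, write_event_table
from .model import (
    ClusterRecord,
    DistributionTest,
    FULL_CLASSES,
    GeneModel,
    PARTIAL_CLASSES,
    PipelineParams,
    RenscanError,
)

logger = logging.getLogger("renscan")


# ---------------------------------------------------------------------------
# Physical clusters


def detect_clusters(models: Sequence[GeneModel], params: PipelineParams) -> list[ClusterRecord]:
    """Greedy-left maximal clustering per chromosome (strand-agnostic)."""
    clusters: list[ClusterRecord] = []
    by_seq: dict[str, list] = {}
    for m in models:
        by_seq.setdefault(m.seq_id, []).append(m)
    for seq_id in sorted(by_seq):
        genes = sorted(by_seq[seq_id], key=lambda m: (m.start, m.end))
        i = 0
        while i < len(genes):
            j = i
            span_end = genes[i].end
            while j + 1 < len(genes):
                cand_end = max(span_end, genes[j + 1].end)
                if cand_end - genes[i].start <= params.cluster_window:
                    j += 1
                    span_end = cand_end
                else:
                    break
            if j - i + 1 >= params.cluster_min_genes:
                members = genes[i:j + 1]
                clusters.append(ClusterRecord(
                    seq_id, [m.gene_id for m in members],
                    members[0].start, span_end))
                i = j + 1
            else:
                i += 1
    return clusters


def unclustered_genes(models: Sequence[GeneModel],
                      clusters: Sequence[ClusterRecord]) -> list[str]:
    member = {gid for c in clusters for gid in c.member_ids}
    return [m.gene_id for m in models if m.gene_id not in member]


# ---------------------------------------------------------------------------
# Chromosomal distribution test


def chromosome_distribution_test(
    models: Sequence[GeneModel],
    chromosome_lengths: dict,
) -> DistributionTest:
    """Chi-square test of gene counts against chromosome-length shares."""
    chroms = sorted(chromosome_lengths)
    if len(chroms) < 2:
        raise RenscanError("distribution test needs at least 2 chromosomes (df >= 1)")
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    if (lengths <= 0).any():
        raise RenscanError("all chromosome lengths must be positive")
    observed = np.array([sum(1 for m in models if m.seq_id == c) for c in chroms],
                        dtype=float)
    n = observed.sum()
    expected = n * lengths / lengths.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum()) if n > 0 else 0.0
    df = len(chroms) - 1
    p = float(stats.chi2.sf(chi2, df))
    return DistributionTest(
        chi2=chi2, df=df, p_value=p,
        observed={c: int(o) for c, o in zip(chroms, observed)},
        expected={c: float(e) for c, e in zip(chroms, expected)},
    )


# ---------------------------------------------------------------------------
# Tallies


def tally_complement(
    models: Sequence[GeneModel],
    events=None,
) -> dict:
    """Per-class and per-chromosome tallies with computed totals.

    Returns {"by_class": DataFrame, "by_chromosome": DataFrame}.  Totals are
    always sums of the displayed rows, never independently stored.  Models
    of class ``none`` are excluded with a warning.
    """
    usable = []
    for m in models:
        if m.gene_class == "none":
            logger.warning("model %s has class 'none'; excluded from tally", m.gene_id)
            continue
        usable.append(m)

    class_rows = []
    for cls in FULL_CLASSES + PARTIAL_CLASSES:
        full = sum(1 for m in usable if m.gene_class == cls and m.completeness == "full")
        part = sum(1 for m in usable if m.gene_class == cls and m.completeness == "partial")
        class_rows.append({"gene_class": cls, "full": full, "partial": part,
                           "total": full + part})
    by_class = pd.DataFrame(class_rows).set_index("gene_class")

    novel_ids = set()
    if events is not None:
        for e in events:
            if e.event_type == "novel":
                novel_ids.update(e.new_ids)
    chrom_rows = []
    for seq_id in sorted({m.seq_id for m in usable}):
        mine = [m for m in usable if m.seq_id == seq_id]
        row = {"seq_id": seq_id, "total": len(mine)}
        if events is not None:
            row["novel"] = sum(1 for m in mine if m.gene_id in novel_ids)
            row["known"] = row["total"] - row["novel"]
        chrom_rows.append(row)
    by_chrom = pd.DataFrame(chrom_rows).set_index("seq_id") if chrom_rows \
        else pd.DataFrame(columns=["total"])
    return {"by_class": by_class, "by_chromosome": by_chrom}


def tally_totals(tally: dict) -> dict:
    """Grand totals computed from the per-class table."""
    bc = tally["by_class"]
    full_classes = [c for c in FULL_CLASSES if c in bc.index]
    return {
        "total": int(bc["total"].sum()),
        "total_full": int(bc.loc[full_classes, "full"].sum()),
        "total_partial": int(bc["total"].sum() - bc.loc[full_classes, "full"].sum()),
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline


def assign_ids(models: Sequence[GeneModel], prefix: str = "RDC0002NLR") -> list[GeneModel]:
    """Serial IDs in genomic order."""
    ordered = sorted(models, key=lambda m: (m.seq_id, m.start, m.end))
    for i, m in enumerate(ordered, 1):
        m.gene_id = f"{prefix}{i:04d}"
    return ordered


def annotate_genome(genome, loci, motif_set, params):
    """Scan loci, build models, predict CDS bounds for full models."""
    seqs = {g.seq_id: g.residues for g in genome}
    all_models, all_hits = [], []
    for locus in loci:
        sub = seqs[locus.seq_id][locus.start:locus.end]
        hits = _annotate.scan_motifs(sub, motif_set, params,
                                     seq_id=locus.seq_id, offset=locus.start)
        models = _annotate.build_gene_models(hits, locus, params)
        refined = []
        for m in models:
            if m.completeness == "full":
                m = _annotate.predict_cds_bounds(m, hits, genome, params)
            refined.append(m)
        all_models.extend(refined)
        all_hits.extend(hits)
    return all_models, all_hits


def run_pipeline(
    params: PipelineParams,
    genome_fasta,
    gdna_sam,
    out_dir,
    prior_gff3=None,
    cdna_sam=None,
    motif_file=None,
    motif_set=None,
    id_prefix: str = "RDC0002NLR",
) -> dict:
    """Run coverage -> annotation -> reconciliation -> gap closing ->
    re-annotation of patched regions -> expression -> report.

    Every stage's outputs are written under ``out_dir`` before the next
    stage begins; the returned dict carries the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"param {k}={v}" for k, v in sorted(vars(params).items())]

    genome = _io.read_fasta(genome_fasta)
    alignments = list(_io.read_sam(gdna_sam))
    if motif_set is None:
        if motif_file is None:
            raise RenscanError("need motif_file or motif_set")
        motif_set = _io.read_motif_file(motif_file)

    # stage: coverage and candidate loci
    tracks = _coverage.compute_coverage(alignments, genome)
    loci = _coverage.call_all_loci(tracks, params)
    _io.write_bed(loci, out / "candidate_loci.bed")
    log_lines.append(f"stage coverage: {len(loci)} candidate loci")

    # stage: annotation
    models, hits = annotate_genome(genome, loci, motif_set, params)
    models = assign_ids(models, id_prefix)
    _io.write_gff3(models, out / "models_initial.gff3")
    log_lines.append(f"stage annotate: {len(models)} models")

    # stage: reconciliation against prior annotation
    events = []
    if prior_gff3 is not None:
        prior = _io.read_gff3(prior_gff3)
        events = _reconcile_models(prior, models, params)
        write_event_table(events, out / "correction_events.tsv")
        log_lines.append(f"stage reconcile: {len(events)} events")

    # stage: gap closing
    gaps = _gapfill.find_gaps(genome, loci, params)
    gaps = _gapfill.close_all_gaps(gaps, alignments, genome, params)
    patched, liftover = _gapfill.apply_patches(genome, gaps)
    _io.write_gap_report(gaps, out / "gaps.tsv")
    _gapfill.write_liftover(liftover, out / "liftover.tsv")
    _io.write_fasta(patched, out / "genome_patched.fasta")
    n_closed = sum(1 for g in gaps if g.status == "closed")
    log_lines.append(f"stage gapfill: {n_closed}/{len(gaps)} gaps closed")

    # stage: re-annotate loci touching patched gaps on the patched genome
    if n_closed:
        shift_by_seq: dict[str, list] = {}
        for sid, os_, oe, ns, ne in liftover:
            shift_by_seq.setdefault(sid, []).append((os_, oe, ns, ne))

        def lift(sid, pos):
            delta = 0
            for os_, oe, ns, ne in shift_by_seq.get(sid, []):
                if pos >= oe:
                    delta += (ne - ns) - (oe - os_)
            return pos + delta

        closed_spans = {(g.seq_id, g.start, g.end) for g in gaps if g.status == "closed"}
        touched, kept = [], []
        for locus in loci:
            if any(sid == locus.seq_id and s < locus.end and e > locus.start
                   for sid, s, e in closed_spans):
                touched.append(locus)
            else:
                kept.append(locus)
        kept_models = [m for m in models
                       if not any(l.seq_id == m.seq_id and m.start < l.end and m.end > l.start
                                  for l in touched)]
        if touched:
            lifted = [type(l)(l.seq_id, lift(l.seq_id, l.start),
                              lift(l.seq_id, l.end), l.n_seed_runs) for l in touched]
            re_models, re_hits = annotate_genome(patched, lifted, motif_set, params)
            models = assign_ids(kept_models + re_models, id_prefix)
            hits = hits + re_hits
        log_lines.append(f"stage reannotate: {len(touched)} loci rescanned")
    _io.write_gff3(models, out / "models_final.gff3")

    # stage: expression
    records = None
    if cdna_sam is not None:
        cdna = _io.read_sam(cdna_sam)
        records = _expression.count_expression(cdna, models)
        by_id = {r.gene_id: r for r in records}
        for m in models:
            m.expressed = "yes" if by_id[m.gene_id].expressed else "no"
        _expression.write_expression_table(records, out / "expression.tsv")
        summary = _expression.complexity_reduction(records)
        log_lines.append(f"stage expression: {summary['n_expressed']}/"
                         f"{summary['n_total']} expressed")
        _io.write_gff3(models, out / "models_final.gff3")

    # stage: report
    clusters = detect_clusters(models, params)
    tally = tally_complement(models, events if prior_gff3 is not None else None)
    tally["by_class"].to_csv(out / "tally_by_class.tsv", sep="\t")
    tally["by_chromosome"].to_csv(out / "tally_by_chromosome.tsv", sep="\t")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("seq_id\tspan_start\tspan_end\tn_genes\tmember_ids\n")
        for c in clusters:
            fh.write(f"{c.seq_id}\t{c.span_start}\t{c.span_end}\t"
                     f"{len(c.member_ids)}\t{','.join(c.member_ids)}\n")
    dist = None
    if len({m.seq_id for m in models}) >= 2:
        dist = chromosome_distribution_test(models, {g.seq_id: len(g) for g in genome})
    log_lines.append(f"stage report: {len(clusters)} clusters")
    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return {
        "loci": loci, "models": models, "hits": hits, "events": events,
        "gaps": gaps, "patched_genome": patched, "expression": records,
        "clusters": clusters, "tally": tally, "distribution": dist,
    }
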