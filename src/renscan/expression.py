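"""cDNA expression filter: unique-mapping read counts per gene model.

Reads with more than one equally-best placement are omitted entirely; every
model receives a record and any gene with at least one uniquely-mapping
read counts as expressed — no read-count cut-off is applied.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import AlignmentRecord, ExpressionRecord, GeneModel, RenscanError


def count_expression(
    cdna_alignments: Iterable[AlignmentRecord],
    models: Sequence[GeneModel],
) -> list[ExpressionRecord]:
    """Count uniquely-mapping cDNA reads per gene.

    Alignments are against the gene-model sequence set (one reference per
    model); a reference not present among the models is an error.  Mates of
    a pair count as two reads.
    """
    known = {m.gene_id for m in models}
    counts = {gid: 0 for gid in known}
    for aln in cdna_alignments:
        if aln.seq_id not in known:
            raise RenscanError(f"cDNA alignment {aln.read_id!r} references unknown "
                               f"model {aln.seq_id!r}")
        if aln.n_best_hits > 1:
            continue
        counts[aln.seq_id] += 1
    return [ExpressionRecord(m.gene_id, counts[m.gene_id], counts[m.gene_id] >= 1)
            for m in models]


def complexity_reduction(records: Sequence[ExpressionRecord]) -> dict:
    """Summary of how much the expression filter shrinks the complement.

    reduction_fraction = 1 - n_expressed / n_total: the fraction of the
    annotated complement with no uniquely-mapping cDNA support.
    """
    n_total = len(records)
    if n_total == 0:
        raise RenscanError("no expression records")
    expressed = [r for r in records if r.expressed]
    n_expressed = len(expressed)
    total_reads = sum(r.unique_reads for r in expressed)
    return {
        "n_total": n_total,
        "n_expressed": n_expressed,
        "mean_reads_per_expressed": (total_reads / n_expressed) if n_expressed else 0.0,
        "reduction_fraction": 1.0 - n_expressed / n_total,
    }


def write_expression_table(records: Sequence[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tunique_reads\texpressed\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.unique_reads}\t{'yes' if r.expressed else 'no'}\n")
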