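"""Cluster detection, distribution test, tallies and the pipeline driver."""

import numpy as np
import pytest
from scipy import stats

import renscan as rs
from renscan.report import (
    assign_ids,
    chromosome_distribution_test,
    detect_clusters,
    run_pipeline,
    tally_complement,
    tally_totals,
    unclustered_genes,
)

from conftest import random_models


def _gene(gid, start, end=None, seq="chr1"):
    return rs.GeneModel(gid, seq, "+", start, end if end is not None else start + 200,
                        "NB", "partial")


def brute_force_clusters(starts_ends, window, min_genes):
    """Greedy-left maximal window clustering on one chromosome."""
    genes = sorted(starts_ends)
    out = []
    i = 0
    while i < len(genes):
        j = i
        span_end = genes[i][1]
        while j + 1 < len(genes) and max(span_end, genes[j + 1][1]) - genes[i][0] <= window:
            j += 1
            span_end = max(span_end, genes[j][1])
        if j - i + 1 >= min_genes:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


class TestDetectClusters:
    def test_four_genes_within_200kb_inclusive(self, params):
        """Genes at 0, 50k, 100k, 199k (span end 199,200) form one cluster."""
        models = [_gene(f"g{i}", s) for i, s in enumerate([0, 50_000, 100_000, 199_000])]
        clusters = detect_clusters(models, params)
        assert len(clusters) == 1
        assert clusters[0].member_ids == [m.gene_id for m in models]

    def test_window_exceeded_no_cluster(self, params):
        models = [_gene(f"g{i}", s) for i, s in enumerate([0, 50_000, 100_000, 201_000])]
        assert detect_clusters(models, params) == []

    def test_span_inclusive_at_exactly_200kb(self, params):
        models = [_gene(f"g{i}", s) for i, s in enumerate([0, 50_000, 100_000])]
        models.append(_gene("g3", 199_800))   # span end exactly 200,000
        assert len(detect_clusters(models, params)) == 1
        models[-1] = _gene("g3", 199_801)     # span end 200,001
        assert detect_clusters(models, params) == []

    def test_membership_is_a_partition(self, params):
        rng = np.random.default_rng(70)
        models = random_models(rng, 60, seq_ids=("chr1",), span=800_000)
        models = assign_ids(models, "x")
        clusters = detect_clusters(models, params)
        clustered = [gid for c in clusters for gid in c.member_ids]
        assert len(clustered) == len(set(clustered))
        assert len(clustered) + len(unclustered_genes(models, clusters)) == len(models)

    def test_matches_brute_force_on_random_placements(self, params):
        rng = np.random.default_rng(71)
        for _ in range(200):
            n = int(rng.integers(2, 25))
            models = sorted(random_models(rng, n, seq_ids=("chr1",), span=600_000),
                            key=lambda m: (m.start, m.end))
            for i, m in enumerate(models):
                m.gene_id = f"g{i:03d}"
            clusters = detect_clusters(models, params)
            want = brute_force_clusters([(m.start, m.end) for m in models],
                                        params.cluster_window, params.cluster_min_genes)
            got = [(int(c.member_ids[0][1:]), int(c.member_ids[-1][1:]))
                   for c in clusters]
            assert got == want

    def test_planted_cluster_recovered(self, default_truth, params):
        clusters = detect_clusters(default_truth.true_models, params)
        assert any(len(c.member_ids) >= 4 for c in clusters)


class TestDistributionTest:
    def test_proportional_counts_give_zero(self):
        models = [_gene(f"g{i}", i, seq="chr1") for i in range(10)] + \
                 [_gene(f"h{i}", i, seq="chr2") for i in range(20)]
        d = chromosome_distribution_test(models, {"chr1": 1_000_000, "chr2": 2_000_000})
        assert d.chi2 == pytest.approx(0.0)
        assert d.p_value == pytest.approx(1.0)

    def test_two_equal_chromosomes_closed_form(self):
        """Observed (10, 30) on equal-length chromosomes: chi2 = 10, df = 1,
        p = 1.57e-3."""
        models = [_gene(f"g{i}", i, seq="chr1") for i in range(10)] + \
                 [_gene(f"h{i}", i, seq="chr2") for i in range(30)]
        d = chromosome_distribution_test(models, {"chr1": 5_000_000, "chr2": 5_000_000})
        assert d.chi2 == pytest.approx(10.0)
        assert d.df == 1
        assert d.p_value == pytest.approx(1.5654e-3, rel=1e-3)

    def test_matches_textbook_computation_on_random_tables(self):
        rng = np.random.default_rng(72)
        for _ in range(100):
            k = int(rng.integers(2, 13))
            lengths = {f"c{i}": int(rng.integers(10_000, 1_000_000)) for i in range(k)}
            counts = rng.integers(0, 50, size=k)
            models = [_gene(f"g{i}_{j}", j, seq=f"c{i}")
                      for i in range(k) for j in range(counts[i])]
            d = chromosome_distribution_test(models, lengths)
            # independent, pure-python textbook computation
            total_len = sum(lengths.values())
            n = counts.sum()
            chi2 = sum((counts[i] - n * lengths[f"c{i}"] / total_len) ** 2
                       / (n * lengths[f"c{i}"] / total_len) for i in range(k))
            assert abs(d.chi2 - chi2) < 1e-9
            assert d.df == k - 1
            assert d.p_value == pytest.approx(float(stats.chi2.sf(chi2, k - 1)))

    def test_single_chromosome_rejected(self):
        with pytest.raises(rs.RenscanError):
            chromosome_distribution_test([_gene("g", 0)], {"chr1": 1000})


def _models_from_counts(counts):
    """counts: {(class, completeness): n} -> synthetic positioned models."""
    models = []
    pos = 0
    for (cls, compl), n in counts.items():
        for i in range(n):
            models.append(rs.GeneModel(
                f"{cls}_{compl}_{i}", "chr1", "+", pos, pos + 100, cls, compl,
                truncated="" if (compl == "full" or cls not in
                                 ("CC-NB-LRR", "TIR-NB-LRR")) else "3prime"))
            pos += 200
    return models


# Per-class complements as published for the two tomato genomes.
LA1589_COUNTS = {
    ("CC-NB-LRR", "full"): 110, ("TIR-NB-LRR", "full"): 14,
    ("CC-NB", "partial"): 33, ("TIR-LRR", "partial"): 1,
    ("TIR-NB", "partial"): 7, ("NB", "partial"): 122,
    ("TIR", "partial"): 12, ("LRR", "partial"): 56,
}
HEINZ_COUNTS = {
    ("CC-NB-LRR", "full"): 195, ("TIR-NB-LRR", "full"): 26,
    ("CC-NB", "partial"): 14, ("TIR-LRR", "partial"): 1,
    ("TIR-NB", "partial"): 3, ("NB", "partial"): 57,
    ("TIR", "partial"): 10, ("LRR", "partial"): 20,
}


class TestTally:
    def test_la1589_grand_total(self):
        tally = tally_complement(_models_from_counts(LA1589_COUNTS))
        assert tally_totals(tally)["total"] == 355

    def test_heinz_full_length_total(self):
        tally = tally_totals(tally_complement(_models_from_counts(HEINZ_COUNTS)))
        assert tally["total_full"] == 221
        assert tally["total"] == 326

    def test_empty_model_list(self):
        tally = tally_complement([])
        assert tally["by_class"]["total"].sum() == 0

    def test_class_none_excluded(self):
        models = _models_from_counts({("NB", "partial"): 2})
        models.append(rs.GeneModel("x", "chr1", "+", 0, 10, "none", "partial"))
        tally = tally_totals(tally_complement(models))
        assert tally["total"] == 2

    def test_totals_always_sum_of_parts(self):
        rng = np.random.default_rng(73)
        classes = ["CC-NB-LRR", "TIR-NB-LRR", "NB", "LRR", "TIR"]
        for _ in range(30):
            counts = {}
            for cls in classes:
                compl = "full" if cls in ("CC-NB-LRR", "TIR-NB-LRR") else "partial"
                counts[(cls, compl)] = int(rng.integers(0, 20))
            counts = {k: v for k, v in counts.items() if v}
            tally = tally_complement(_models_from_counts(counts))
            totals = tally_totals(tally)
            assert totals["total"] == sum(counts.values())
            assert totals["total"] == totals["total_full"] + totals["total_partial"]


@pytest.fixture(scope="module")
def inputs(tmp_path_factory):
    p = rs.PipelineParams()
    truth = rs.simulate_truth(
        p, n_genes_per_class={"CC-NB-LRR": 3, "TIR-NB-LRR": 2, "NB": 2, "LRR": 1},
        n_gaps=1, gap_len_range=(150, 400), cluster_spec=(), seed=11,
        genome_len=150_000)
    tmp = tmp_path_factory.mktemp("pipe")
    rs.write_fasta(truth.genome, tmp / "genome.fasta")
    rs.write_gff3(truth.prior_models, tmp / "prior.gff3")
    from renscan.io import write_motif_file
    write_motif_file(truth.motif_set, tmp / "motifs.txt")
    rs.simulate_gdna_reads(truth, seed=2, sam_path=tmp / "gdna.sam")
    rs.simulate_cdna_reads(truth, seed=3, sam_path=tmp / "cdna.sam")
    return p, truth, tmp


class TestRunPipeline:
    def test_recovers_planted_models(self, inputs):
        p, truth, tmp = inputs
        res = run_pipeline(p, tmp / "genome.fasta", tmp / "gdna.sam", tmp / "out",
                           prior_gff3=tmp / "prior.gff3", cdna_sam=tmp / "cdna.sam",
                           motif_file=tmp / "motifs.txt")
        assert len(res["models"]) == len(truth.true_models)
        for t in truth.true_models:
            match = [m for m in res["models"]
                     if m.strand == t.strand and m.start < t.end and m.end > t.start]
            assert len(match) == 1
            assert match[0].gene_class == t.gene_class

    def test_rerun_is_byte_identical(self, inputs):
        p, truth, tmp = inputs
        common = dict(prior_gff3=tmp / "prior.gff3", cdna_sam=tmp / "cdna.sam",
                      motif_file=tmp / "motifs.txt")
        run_pipeline(p, tmp / "genome.fasta", tmp / "gdna.sam", tmp / "out_a", **common)
        run_pipeline(p, tmp / "genome.fasta", tmp / "gdna.sam", tmp / "out_b", **common)
        files_a = sorted(x.name for x in (tmp / "out_a").iterdir())
        assert files_a == sorted(x.name for x in (tmp / "out_b").iterdir())
        for name in files_a:
            assert (tmp / "out_a" / name).read_bytes() == \
                (tmp / "out_b" / name).read_bytes(), name

    def test_missing_cdna_leaves_expression_unknown(self, inputs):
        p, truth, tmp = inputs
        res = run_pipeline(p, tmp / "genome.fasta", tmp / "gdna.sam", tmp / "out_nocdna",
                           motif_file=tmp / "motifs.txt")
        assert res["expression"] is None
        assert all(m.expressed == "unknown" for m in res["models"])
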