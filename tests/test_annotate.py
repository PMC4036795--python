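"""Motif scanning, series assembly, CDS-bound prediction, NB-ARC
extraction and bait design."""

import math

import numpy as np
import pytest

import renscan as rs
from renscan.annotate import (
    BACKGROUND,
    BaitSet,
    build_gene_models,
    design_baits,
    extract_nbarc,
    predict_cds_bounds,
    scan_motifs,
    score_tail_probability,
    translate,
)
from renscan.model import AA_ORDER, CandidateLocus, GenomeSequence, MotifHit

# codon helpers -------------------------------------------------------------

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def encode(pep):
    return "".join(_CODON[aa] for aa in pep)


def brute_force_score(motif, pep):
    """Independent log2-odds sum for one placement."""
    total = 0.0
    for i, aa in enumerate(pep):
        if aa in AA_ORDER:
            total += math.log2(motif.matrix[i, AA_ORDER.index(aa)] / BACKGROUND)
        elif aa == "*":
            total += -1e6
    return total


@pytest.fixture(scope="module")
def motifs():
    return rs.default_motif_set()


class TestScanMotifs:
    def test_empty_motif_set_is_an_error(self, params):
        with pytest.raises(rs.RenscanError):
            scan_motifs("ACGTACGT", [], params)

    def test_planted_consensus_on_minus_strand(self, params, motifs):
        m = motifs[3]  # NB P-loop
        rng = np.random.default_rng(0)
        bg = "".join("ACGT"[b] for b in rng.integers(0, 4, 600))
        coding = encode(m.consensus)
        seq = bg[:300] + rs.revcomp(coding) + bg[300:]
        hits = [h for h in scan_motifs(seq, motifs, params) if h.motif_id == m.motif_id]
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        assert (h.nt_start, h.nt_end) == (300, 300 + len(coding))
        assert h.nt_end - h.nt_start == 3 * m.width

    def test_scores_match_brute_force(self, params, motifs):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 3000))
        # permissive threshold to get a spread of reported scores
        loose = [rs.MotifModel(m.motif_id, m.domain_class, m.matrix, -30.0)
                 for m in motifs]
        hits = scan_motifs(seq, loose, params)
        assert hits, "permissive scan should report hits"
        by_id = {m.motif_id: m for m in loose}
        for h in hits[:200]:
            sub = seq[h.nt_start:h.nt_end]
            pep = translate(sub if h.strand == "+" else rs.revcomp(sub))
            assert h.score == pytest.approx(brute_force_score(by_id[h.motif_id], pep),
                                            abs=1e-9)

    def test_reverse_complement_symmetry(self, params, motifs):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 1500)) \
            + encode(motifs[0].consensus) + encode(motifs[4].consensus)
        L = len(seq)
        fwd = scan_motifs(seq, motifs, params)
        rev = scan_motifs(rs.revcomp(seq), motifs, params)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((h.motif_id, flip[h.strand], L - h.nt_end, L - h.nt_start,
                           round(h.score, 9)) for h in rev)
        assert mirrored == sorted((h.motif_id, h.strand, h.nt_start, h.nt_end,
                                   round(h.score, 9)) for h in fwd)

    def test_stringent_threshold_never_fires_on_background(self, params, motifs):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 3000))
            assert scan_motifs(seq, motifs, params) == []

    def test_false_positive_rate_matches_score_tail(self, params):
        """Observed background hits agree with the exact score-tail
        probability of the threshold (Poisson 3-sigma band)."""
        base = rs.default_motif_set()[3]
        motif = rs.MotifModel("m", "NB", base.matrix, -19.0)
        p_tail = score_tail_probability(motif)
        rng = np.random.default_rng(4)
        n_hits = 0
        n_placements = 0
        for _ in range(150):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 3000))
            hits = scan_motifs(seq, [motif], params)
            n_hits += len(hits)
            for strand in range(2):
                for frame in range(3):
                    n_pep = (3000 - frame) // 3
                    n_placements += max(0, n_pep - motif.width + 1)
        expect = n_placements * p_tail
        assert expect > 20, "test needs a measurable expectation"
        assert abs(n_hits - expect) <= 3 * math.sqrt(expect)


class TestBuildGeneModels:
    def _hit(self, motif_id, dclass, start, strand="+", frame=0):
        return MotifHit(motif_id, dclass, "chr1", strand, frame,
                        start, start + 45, 30.0)

    def test_cc_nb_lrr_series_is_full(self, params):
        locus = CandidateLocus("chr1", 0, 10_000)
        hits = [self._hit("cc", "CC", 100), self._hit("nb", "NB", 400),
                self._hit("lrr", "LRR", 900)]
        models = build_gene_models(hits, locus, params)
        assert len(models) == 1
        assert (models[0].gene_class, models[0].completeness) == ("CC-NB-LRR", "full")
        assert (models[0].start, models[0].end) == (100, 945)

    def test_nb_only_series_is_partial(self, params):
        locus = CandidateLocus("chr1", 0, 10_000)
        models = build_gene_models([self._hit("nb", "NB", 100)], locus, params)
        assert (models[0].gene_class, models[0].completeness) == ("NB", "partial")

    def test_gap_beyond_threshold_splits_series(self, params):
        """Two motif groups separated by more than the intra-series gap are
        two models (the fusion-splitting behaviour)."""
        locus = CandidateLocus("chr1", 0, 20_000)
        second = 600 + 45 + params.max_intra_series_gap + 1
        hits = [self._hit("nb", "NB", 100), self._hit("lrr", "LRR", 600),
                self._hit("nb", "NB", second), self._hit("lrr", "LRR", second + 500)]
        models = build_gene_models(hits, locus, params)
        assert len(models) == 2
        assert all(m.gene_class == "CC-NB-LRR" for m in models)

    def test_opposite_strand_hits_never_merge(self, params):
        locus = CandidateLocus("chr1", 0, 10_000)
        hits = [self._hit("nb", "NB", 100), self._hit("lrr", "LRR", 600, strand="-")]
        models = build_gene_models(hits, locus, params)
        assert len(models) == 2
        assert {m.strand for m in models} == {"+", "-"}

    def test_hit_outside_locus_rejected(self, params):
        locus = CandidateLocus("chr1", 0, 100)
        with pytest.raises(rs.RenscanError):
            build_gene_models([self._hit("nb", "NB", 200)], locus, params)

    def test_empty_hits_empty_models(self, params):
        assert build_gene_models([], CandidateLocus("chr1", 0, 100), params) == []


def _orf_sequence(rng, length=1200):
    """Background with no in-frame ATG or stop in frame 0 (linker codons)."""
    from renscan.simulate import _LINKER_CODONS
    n = length // 3
    return "".join(_LINKER_CODONS[i] for i in rng.integers(0, len(_LINKER_CODONS), n))


class TestPredictCdsBounds:
    def _setup(self, seq):
        genome = [GenomeSequence("chr1", seq)]
        hits = [MotifHit("nb", "NB", "chr1", "+", 0, 300, 345, 30.0),
                MotifHit("lrr", "LRR", "chr1", "+", 0, 600, 645, 30.0)]
        model = rs.GeneModel("g", "chr1", "+", 300, 645, "CC-NB-LRR", "full")
        return genome, hits, model

    def test_constructed_orf(self, params):
        """ATG at 240, clean ORF, first in-frame stop at [900,903)."""
        rng = np.random.default_rng(5)
        seq = list(_orf_sequence(rng))
        seq[240:243] = "ATG"
        seq[900:903] = "TAA"
        genome, hits, model = self._setup("".join(seq))
        out = predict_cds_bounds(model, hits, genome, params)
        assert (out.start, out.end) == (240, 903)
        assert out.completeness == "full"

    def test_intervening_stop_rejects_atg(self, params):
        rng = np.random.default_rng(6)
        seq = list(_orf_sequence(rng))
        seq[240:243] = "ATG"
        seq[270:273] = "TGA"      # in-frame stop between the ATG and the motif
        seq[900:903] = "TAA"
        genome, hits, model = self._setup("".join(seq))
        out = predict_cds_bounds(model, hits, genome, params)
        assert out.completeness == "partial"
        assert out.truncated == "5prime"

    def test_atg_at_first_motif_codon(self, params):
        rng = np.random.default_rng(7)
        seq = list(_orf_sequence(rng))
        seq[300:303] = "ATG"      # the motif's own first codon
        seq[900:903] = "TAA"
        genome, hits, model = self._setup("".join(seq))
        out = predict_cds_bounds(model, hits, genome, params)
        assert out.start == 300

    def test_missing_stop_demotes_3prime(self, params):
        rng = np.random.default_rng(8)
        seq = list(_orf_sequence(rng))
        seq[240:243] = "ATG"      # no stop anywhere downstream (linker codons)
        genome, hits, model = self._setup("".join(seq))
        out = predict_cds_bounds(model, hits, genome, params)
        assert (out.completeness, out.truncated) == ("partial", "3prime")

    def test_partial_model_is_an_error(self, params):
        genome = [GenomeSequence("chr1", "ACGT" * 100)]
        model = rs.GeneModel("g", "chr1", "+", 10, 100, "NB", "partial")
        with pytest.raises(rs.RenscanError):
            predict_cds_bounds(model, [], genome, params)

    def test_matches_simulated_truth_bounds(self, default_truth, params):
        """On planted genes the predicted CDS equals the planted CDS."""
        genome = default_truth.true_genome
        full = [m for m in default_truth.true_models if m.completeness == "full"][:6]
        for t in full:
            pad = 600
            sub = genome[0].residues[max(0, t.start - pad):t.end + pad]
            hits = scan_motifs(sub, default_truth.motif_set, params,
                               seq_id="chr1", offset=max(0, t.start - pad))
            locus = CandidateLocus("chr1", max(0, t.start - pad), t.end + pad)
            models = [m for m in build_gene_models(hits, locus, params)
                      if m.completeness == "full" and m.strand == t.strand]
            assert len(models) == 1
            out = predict_cds_bounds(models[0], hits, genome, params)
            assert (out.start, out.end) == (t.start, t.end)


class TestExtractNbarc:
    def _fixture(self, n_nb_codons):
        rng = np.random.default_rng(9)
        pep = "".join(AA_ORDER[i] for i in rng.integers(0, 20, n_nb_codons))
        seq = encode(pep)
        genome = [GenomeSequence("chr1", seq)]
        hits = [MotifHit("nb1", "NB", "chr1", "+", 0, 0, 45, 30.0),
                MotifHit("nb2", "NB", "chr1", "+", 0, len(seq) - 45, len(seq), 30.0)]
        model = rs.GeneModel("g", "chr1", "+", 0, len(seq), "NB", "partial")
        return genome, hits, model, pep

    def test_below_half_reference_excluded(self):
        genome, hits, model, _ = self._fixture(116)   # 0.4 x 290
        assert extract_nbarc(model, hits, genome, reference_nbarc_len=290) is None

    def test_exactly_half_reference_retained(self):
        genome, hits, model, pep = self._fixture(145)  # 0.5 x 290
        assert extract_nbarc(model, hits, genome, reference_nbarc_len=290) == pep

    def test_peptide_equals_independent_translation(self):
        from Bio.Seq import Seq
        genome, hits, model, _ = self._fixture(200)
        pep = extract_nbarc(model, hits, genome, reference_nbarc_len=290)
        assert pep == str(Seq(genome[0].residues[:600]).translate())

    def test_no_nb_hit_is_an_error(self):
        genome = [GenomeSequence("chr1", "ACGT" * 100)]
        model = rs.GeneModel("g", "chr1", "+", 0, 100, "LRR", "partial")
        with pytest.raises(rs.RenscanError):
            extract_nbarc(model, [], genome, reference_nbarc_len=290)


class TestDesignBaits:
    def test_exact_length_sequence_one_bait(self, params):
        assert len(design_baits(["A" * 120], params)) == 1

    def test_tiling_count(self, params):
        """(360 - 120)/60 + 1 = 5 windows, the last flush with the end."""
        rng = np.random.default_rng(10)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 360))
        assert len(design_baits([seq], params)) == 5

    def test_flush_final_window(self, params):
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
        baits = design_baits([seq], params).baits
        assert seq[-120:] in baits

    def test_duplicate_sequences_do_not_add_baits(self, params):
        rng = np.random.default_rng(12)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 500))
        assert len(design_baits([seq], params)) == len(design_baits([seq, seq], params))

    def test_windows_with_n_skipped(self, params):
        seq = "A" * 120 + "N" + "C" * 120
        baits = design_baits([seq], params).baits
        assert all("N" not in b for b in baits)
        assert "A" * 120 in baits and "C" * 120 in baits

    def test_short_sequence_contributes_nothing(self, params):
        assert len(design_baits(["ACGT"], params)) == 0

    def test_bait_length_enforced(self):
        with pytest.raises(rs.RenscanError):
            BaitSet(120, {"ACGT"})
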