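"""Unit and property tests for transcript annotation and motif scanning."""

import numpy as np
import pandas as pd
import pytest

from texrip import transcripts as tr
from texrip.io import Feature, GenomeAnnotation
from texrip.sites import SiteCall, reverse_complement
from texrip.synthetic import make_genome


def _tss(pos, strand="+", tss_class="oTSS"):
    return SiteCall(pos, strand, 100, 0, 1e4, 100, 1e-12, "TSS", tss_class)


class TestMatchTts:
    def test_window_rule_plus_strand(self):
        cand = tr.match_tts(_tss(1000), [(1200, "+")])
        assert (cand.start, cand.end) == (1000, 1201)
        assert len(cand) == 201 and cand.category == "sRNA"

    def test_nearest_downstream_wins(self):
        cand = tr.match_tts(_tss(1000), [(1300, "+"), (1100, "+")])
        assert cand.matched_tts == 1100

    def test_outside_window_yields_none(self):
        assert tr.match_tts(_tss(1000), [(1450, "+")]) is None

    def test_window_boundary_inclusive(self):
        cand = tr.match_tts(_tss(1000), [(1400, "+")])
        assert cand is not None and len(cand) == 401

    def test_upstream_tts_ignored(self):
        assert tr.match_tts(_tss(1000), [(900, "+")]) is None

    def test_opposite_strand_tts_ignored(self):
        assert tr.match_tts(_tss(1000), [(1100, "-")]) is None

    def test_minus_strand_downstream_is_decreasing_coordinate(self):
        cand = tr.match_tts(_tss(1000, "-"), [(850, "-"), (700, "-")])
        assert cand.matched_tts == 850
        assert (cand.start, cand.end) == (850, 1001)

    def test_atss_yields_asrna(self):
        cand = tr.match_tts(_tss(1000, tss_class="aTSS"), [(1100, "+")])
        assert cand.category == "asRNA"


class TestFindOrfs:
    def _candidate(self, seq, prefix="", suffix=""):
        genome = prefix + seq + suffix
        return (
            tr.TranscriptCandidate(
                "t1", len(prefix), len(prefix) + len(seq), "+", len(prefix),
                len(prefix) + len(seq) - 1, "sRNA",
            ),
            genome,
        )

    def test_thirty_codon_orf_upgrades_to_smorf(self):
        orf = "ATG" + "GCT" * 30 + "TAA"
        cand, genome = self._candidate("TTTT" + orf + "TTTT")
        out = tr.find_orfs(cand, genome)
        assert out.category == "smORF"
        assert out.orf[2] == 30

    def test_no_stop_codon_means_no_orf(self):
        cand, genome = self._candidate("ATG" + "GCA" * 40)
        out = tr.find_orfs(cand, genome)
        assert out.orf is None and out.category == "sRNA"

    def test_long_orf_does_not_upgrade(self):
        orf = "ATG" + "GCT" * 60 + "TAA"
        cand, genome = self._candidate("AA" + orf + "AA")
        out = tr.find_orfs(cand, genome)
        assert out.category == "sRNA" and out.orf[2] == 60

    def test_alternative_start_codons_accepted(self):
        orf = "GTG" + "GCT" * 20 + "TGA"
        cand, genome = self._candidate("CC" + orf)
        out = tr.find_orfs(cand, genome)
        assert out.category == "smORF" and out.orf[2] == 20

    def test_minus_strand_orf_read_on_transcript(self):
        orf = "ATG" + "GCT" * 15 + "TAA"
        transcript = "TT" + orf + "TT"
        genome = "A" * 10 + reverse_complement(transcript) + "A" * 10
        cand = tr.TranscriptCandidate(
            "t1", 10, 10 + len(transcript), "-", 10 + len(transcript) - 1, 10,
            "sRNA",
        )
        out = tr.find_orfs(cand, genome)
        assert out.category == "smORF" and out.orf[2] == 15


class TestValidateExpression:
    def _cands(self):
        return [
            tr.TranscriptCandidate("a", 0, 100, "+", 0, 99, "sRNA"),
        ]

    def test_single_qualifying_condition_validates(self):
        tpm = pd.DataFrame([[0.0, 0.0, 3.2]], index=["a"])
        [c] = tr.validate_expression(self._cands(), tpm)
        assert c.expression_validated

    def test_all_zero_not_validated(self):
        tpm = pd.DataFrame([[0.0, 0.0, 0.0]], index=["a"])
        [c] = tr.validate_expression(self._cands(), tpm)
        assert not c.expression_validated

    def test_min_conditions_two_counts_qualifying_conditions(self):
        tpm = pd.DataFrame([[1.5, 0.2, 0.9]], index=["a"])
        [c] = tr.validate_expression(self._cands(), tpm, min_conditions=2)
        assert not c.expression_validated

    def test_missing_candidate_treated_unvalidated(self):
        tpm = pd.DataFrame([[5.0]], index=["other"])
        [c] = tr.validate_expression(self._cands(), tpm)
        assert not c.expression_validated


class TestExtractPromoters:
    def test_length_contract(self):
        genome = "ACGT" * 50
        [p] = tr.extract_promoters([_tss(100)], genome, upstream=50)
        assert len(p.seq) == 50 and not p.truncated
        assert p.seq == genome[50:100]

    def test_minus_strand_is_reverse_complement(self):
        genome = "ACGT" * 50
        [p] = tr.extract_promoters([_tss(100, "-")], genome, upstream=10)
        assert p.seq == reverse_complement(genome[101:111])

    def test_edge_truncation_flagged(self):
        [p] = tr.extract_promoters([_tss(5)], "ACGT" * 10, upstream=50)
        assert p.truncated and len(p.seq) == 5

    def test_planted_tata_recovered_at_expected_offset(self):
        # plant TATA at positions -27..-24 upstream of 150 synthetic TSSs
        rng = np.random.default_rng(5)
        genome, _ = make_genome(length=60_000, gc_fraction=0.5, n_genes=5, seed=5)
        genome = list(genome)
        tss_positions = rng.choice(np.arange(100, 59_900), size=150, replace=False)
        for pos in tss_positions:
            genome[pos - 27:pos - 23] = list("TATA")
        genome = "".join(genome)
        proms = tr.extract_promoters(
            [_tss(int(p)) for p in tss_positions], genome, upstream=50
        )
        # offset from the 3' end of the 50-nt extract: promoter[-27:-23] == TATA
        freq = np.mean([p.seq[23:27] == "TATA" for p in proms])
        assert freq > 0.95


def brute_force_scan(seq, consensus):
    """Sliding set-membership comparison (no regex)."""
    seq = seq.upper().replace("U", "T")
    consensus = consensus.upper().replace("U", "T")
    hits = []
    for i in range(len(seq) - len(consensus) + 1):
        if all(
            seq[i + j] in tr.IUPAC[c] for j, c in enumerate(consensus)
        ):
            hits.append(i)
    return hits


class TestScanMotif:
    def test_reported_motif_found_once_by_construction(self):
        target = "AACGACAAGAAACTAAAAC"
        seq = "GG" + target + "GG"
        hits = tr.scan_motif({"s": seq}, tr.PROCESSING_MOTIFS["Motif-1"])
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and plus[0].offset == 2

    @pytest.mark.parametrize("base,matches", [("G", False), ("A", True),
                                              ("C", True), ("T", True)])
    def test_iupac_h_semantics(self, base, matches):
        motif = tr.IupacMotif("h", "H", strandedness="sense")
        assert bool(tr.scan_motif({"s": base}, motif)) == matches

    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            tr.IupacMotif("bad", "ACGX")

    def test_u_treated_as_t(self):
        motif = tr.IupacMotif("u", "UUU", strandedness="sense")
        assert len(tr.scan_motif({"s": "TTT"}, motif)) == 1

    def test_strand_symmetry_total_count(self):
        rng = np.random.default_rng(11)
        letters = np.array(list("ACGT"))
        iupac = np.array(list(tr.IUPAC))
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=60))
            consensus = "".join(rng.choice(iupac, size=int(rng.integers(2, 6))))
            motif = tr.IupacMotif("m", consensus)
            fwd = tr.scan_motif({"s": seq}, motif)
            rev = tr.scan_motif({"s": reverse_complement(seq)}, motif)
            assert len(fwd) == len(rev)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        letters = np.array(list("ACGT"))
        iupac = np.array(list(tr.IUPAC))
        for _ in range(1000):
            seq = "".join(rng.choice(letters, size=40))
            consensus = "".join(rng.choice(iupac, size=int(rng.integers(1, 7))))
            motif = tr.IupacMotif("m", consensus, strandedness="sense")
            got = sorted(h.offset for h in tr.scan_motif({"s": seq}, motif))
            assert got == brute_force_scan(seq, consensus)


class TestCountTps:
    def _ann(self):
        return GenomeAnnotation(
            [
                Feature("g1", "gene", 100, 400, "+"),
                Feature("g2", "gene", 600, 900, "-"),
            ]
        )

    def _tps(self, pos, strand):
        return SiteCall(pos, strand, 20, 0, 1e3, 50, 1e-10, "TPS")

    def test_counts_and_strand_rule(self):
        calls = [
            self._tps(150, "+"), self._tps(200, "+"), self._tps(399, "+"),
            self._tps(300, "-"),   # opposite strand of g1: not counted
            self._tps(700, "-"),
        ]
        counts = tr.count_tps_per_transcript(calls, self._ann())
        assert counts["g1"] == 3 and counts["g2"] == 1

    def test_no_overlap_gives_zero(self):
        counts = tr.count_tps_per_transcript([self._tps(50, "+")], self._ann())
        assert counts["g1"] == 0 and counts["g2"] == 0


class TestMergeWithCurated:
    def test_reciprocal_overlap_collapses_to_curated(self):
        curated = GenomeAnnotation([Feature("known_1", "sRNA", 100, 200, "+")])
        novel = [
            tr.TranscriptCandidate("new_1", 102, 198, "+", 102, 197, "sRNA"),
            tr.TranscriptCandidate("new_2", 500, 600, "+", 500, 599, "sRNA"),
        ]
        merged = tr.merge_with_curated(novel, curated)
        ids = {f.id for f in merged}
        assert ids == {"known_1", "new_2"}

    def test_no_duplicate_coordinates_emitted(self):
        curated = GenomeAnnotation([Feature("known_1", "sRNA", 100, 200, "+")])
        novel = [
            tr.TranscriptCandidate("a", 300, 400, "+", 300, 399, "sRNA"),
            tr.TranscriptCandidate("b", 300, 400, "+", 300, 399, "asRNA"),
        ]
        merged = tr.merge_with_curated(novel, curated)
        keys = [(f.start, f.end, f.strand) for f in merged]
        assert len(keys) == len(set(keys))
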