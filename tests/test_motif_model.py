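import numpy as np
import pytest

from regulonscout import (KNOWN_MOTIF_LIBRARY, build_motif, motif_from_consensus,
                          saturation_scan, scan_sequence, score_site)
from regulonscout._dna import BASES, expand_iupac_pattern, reverse_complement
from regulonscout.syndata import _random_dna, sample_site


def random_seq(n, rng, gc=0.5):
    return "".join(BASES[i] for i in _random_dna(n, gc, rng))


class TestBuildMotif:
    def test_pseudocounted_frequencies_and_weights(self):
        m = build_motif(["TGTTC"] * 4, pseudocount=1.0)
        t = BASES.index("T")
        assert m.frequencies[t, 0] == pytest.approx(0.85)
        assert m.weights[t, 0] == pytest.approx(2 + np.log2(0.85))
        assert m.consensus == "TGTTC"
        assert np.allclose(m.frequencies.sum(axis=0), 1.0, atol=1e-9)

    def test_uniform_column_gives_zero_weights(self):
        m = build_motif(["A", "C", "G", "T"], pseudocount=1.0)
        assert np.allclose(m.frequencies[:, 0], 0.25)
        assert np.allclose(m.weights[:, 0], 0.0)
        assert m.consensus == "N"

    def test_palindromy_detected_on_symmetric_site_set(self):
        sites = ["TGTTCAAAAGAACA", "TGTTCTTTTGAACA", "TGTTCGCGCGAACA", "TGTTCGCGCGAACA"]
        sites = sites + [reverse_complement(s) for s in sites]
        m = build_motif(sites)
        assert m.is_palindromic
        assert m.consensus.startswith("TGTTC") and m.consensus.endswith("GAACA")

    def test_unequal_lengths_and_bad_bases_rejected(self):
        with pytest.raises(ValueError):
            build_motif(["ACGT", "ACG"])
        with pytest.raises(ValueError):
            build_motif(["ACNT"])
        with pytest.raises(ValueError):
            build_motif([])


class TestScoreSite:
    def test_consensus_score_is_sum_of_column_weights(self):
        m = build_motif(["TGTTC"] * 4, pseudocount=1.0)
        assert score_site(m, "TGTTC") == pytest.approx(5 * (2 + np.log2(0.85)))
        assert score_site(m, "TGTTC") == pytest.approx(m.max_score)

    def test_uniform_motif_scores_zero_everywhere(self):
        m = build_motif(["ACGT", "CGTA", "GTAC", "TACG"], pseudocount=1.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert score_site(m, random_seq(4, rng)) == pytest.approx(0.0)

    def test_consensus_beats_every_single_substitution(self, verruco_motif):
        cons = "TGTTCAAAAGAACA"
        base_score = score_site(verruco_motif, cons)
        for l in range(len(cons)):
            for b in BASES:
                if b == cons[l]:
                    continue
                mutant = cons[:l] + b + cons[l + 1:]
                assert score_site(verruco_motif, mutant) <= base_score + 1e-12

    def test_length_mismatch_raises(self, verruco_motif):
        with pytest.raises(ValueError):
            score_site(verruco_motif, "TGTTC")

    def test_palindromic_motif_scores_site_and_reverse_complement_equally(self, verruco_motif):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = random_seq(14, rng)
            assert score_site(verruco_motif, s) == \
                pytest.approx(score_site(verruco_motif, reverse_complement(s)))

    def test_ambiguous_base_scores_column_average(self, verruco_motif):
        full = score_site(verruco_motif, "TGTTCAAAAGAACA")
        with_n = score_site(verruco_motif, "NGTTCAAAAGAACA")
        avg0 = verruco_motif.weights[:, 0].mean()
        own0 = verruco_motif.weights[BASES.index("T"), 0]
        assert with_n == pytest.approx(full - own0 + avg0)


class TestScanSequence:
    def test_single_embedded_consensus_found(self, verruco_motif):
        rng = np.random.default_rng(11)
        site = "TGTTCAGTCGAACA"
        seq = random_seq(37, rng) + site + random_seq(60, rng)
        hits = scan_sequence(verruco_motif, seq, threshold=0.9 * verruco_motif.max_score)
        assert [(h.position, h.score) for h in hits] == \
               [(37, pytest.approx(verruco_motif.max_score))]

    def test_threshold_above_max_yields_nothing(self, verruco_motif):
        assert scan_sequence(verruco_motif, "TGTTCAGTCGAACA" * 3,
                             threshold=verruco_motif.max_score + 1) == []

    def test_short_sequence_yields_nothing(self, verruco_motif):
        assert scan_sequence(verruco_motif, "ACGT") == []

    def test_palindromic_motif_reports_each_physical_site_once(self, verruco_motif):
        seq = "A" * 20 + "TGTTCAGTCGAACA" + "A" * 20
        hits = scan_sequence(verruco_motif, seq, threshold=0.9 * verruco_motif.max_score,
                             both_strands=True)
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_reverse_complement_scan_mirrors_positions(self, verruco_motif):
        rng = np.random.default_rng(4)
        seq = random_seq(30, rng) + "TGTTCAGTCGAACA" + random_seq(25, rng)
        fwd = scan_sequence(verruco_motif, seq, threshold=5.0)
        rev = scan_sequence(verruco_motif, reverse_complement(seq), threshold=5.0)
        W, L = verruco_motif.width, len(seq)
        assert sorted((L - h.position - W, round(h.score, 9)) for h in rev) == \
               sorted((h.position, round(h.score, 9)) for h in fwd)

    def test_matches_exhaustive_rescoring_oracle(self):
        """Scanning equals position-by-position rescoring on random inputs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            W = int(rng.integers(4, 12))
            sites = [random_seq(W, rng) for _ in range(int(rng.integers(2, 8)))]
            motif = build_motif(sites)
            seq = random_seq(int(rng.integers(W, 80)), rng)
            hits = scan_sequence(motif, seq, threshold=0.0, both_strands=True)
            expected = []
            for pos in range(len(seq) - W + 1):
                s = score_site(motif, seq[pos:pos + W])
                if s >= 0.0:
                    expected.append((pos, "+", round(s, 9)))
                if not motif.is_palindromic:
                    rc = reverse_complement(seq[pos:pos + W])
                    sr = score_site(motif, rc)
                    if sr >= 0.0:
                        expected.append((pos, "-", round(sr, 9)))
            got = [(h.position, h.strand, round(h.score, 9)) for h in hits]
            assert sorted(got) == sorted(expected)


class TestSaturationScan:
    def test_uniform_spacer_positions_are_tolerant_arms_essential(self, verruco_motif):
        sat = saturation_scan(verruco_motif, "TGTTCAAAAGAACA")
        assert sat.tolerant_positions() == [5, 6, 7, 8]
        assert sat.classification.count("essential") == 10

    def test_arm_substitution_delta_matches_weight_difference(self):
        m = build_motif(["TGTTC"] * 4, pseudocount=1.0)
        sat = saturation_scan(m, "TGTTC")
        t, a = BASES.index("T"), BASES.index("A")
        expected = (2 + np.log2(0.85)) - (2 + np.log2(0.05))
        assert sat.deltas[0, a] == pytest.approx(expected)
        assert expected == pytest.approx(4.09, abs=0.01)

    def test_own_base_delta_is_zero(self, verruco_motif):
        sat = saturation_scan(verruco_motif, "TGTTCAAAAGAACA")
        for l, b in enumerate("TGTTCAAAAGAACA"):
            assert sat.deltas[l, BASES.index(b)] == 0.0

    def test_site_length_mismatch_raises(self, verruco_motif):
        with pytest.raises(ValueError):
            saturation_scan(verruco_motif, "TGTTC")


def test_adding_consensus_site_never_lowers_consensus_score():
    rng = np.random.default_rng(9)
    for _ in range(20):
        W = int(rng.integers(4, 10))
        sites = [random_seq(W, rng) for _ in range(int(rng.integers(1, 6)))]
        m1 = build_motif(sites)
        cons = "".join(BASES[int(np.argmax(m1.frequencies[:, l]))] for l in range(W))
        m2 = build_motif(sites + [cons])
        assert score_site(m2, cons) >= score_site(m1, cons) - 1e-9


def test_known_motif_library_patterns_parse():
    geometries = {m.name: m.geometry for m in KNOWN_MOTIF_LIBRARY}
    assert geometries["Alphaproteobacteria"] == "direct"
    for m in KNOWN_MOTIF_LIBRARY:
        expanded = m.expanded
        assert set(expanded) <= set("ACGTN")
        assert expand_iupac_pattern(m.pattern) == expanded
        if m.geometry == "inverted":
            assert reverse_complement(expanded) == expanded


def test_sampled_sites_reproduce_motif_statistics(verruco_motif):
    rng = np.random.default_rng(0)
    sites = [sample_site(verruco_motif, rng) for _ in range(400)]
    m = build_motif(sites)
    # arm columns should be strongly conserved, spacer columns near-uniform
    ic = m.information_content
    assert ic[:5].min() > 1.0 and ic[9:].min() > 1.0
    assert ic[5:9].max() < 0.25
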