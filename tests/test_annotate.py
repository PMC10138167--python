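"""Alignment, template mapping, NPA scanning and physicochemistry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.SeqUtils.ProtParamData import kd as KD

from aqpkit import annotate
from aqpkit.records import ProteinRecord
from aqpkit.templates import build_template
from ._oracles import brute_force_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"
protein_strategy = st.text(alphabet=AA, min_size=1, max_size=30)


class TestAlignGlobal:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKTAYIAK"
        aln = annotate.align_global(seq, seq)
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        assert aln.score == sum(m[c, c] for c in seq)
        assert "-" not in aln.a_gapped + aln.b_gapped

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            annotate.align_global("A", "")

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            annotate.align_global("ABJZ", "ACDE")

    def test_wildcard_scores_zero(self):
        # X against anything contributes 0, so score('AXA','AAA') equals
        # two A:A matches.
        aln = annotate.align_global("AXA", "AAA")
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        assert aln.score == 2 * m["A", "A"]

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
        expected = brute_force_global_score(a, b)
        assert annotate.align_global(a, b).score == pytest.approx(expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(protein_strategy, protein_strategy)
    def test_score_symmetry(self, a, b):
        assert annotate.align_global(a, b).score == pytest.approx(
            annotate.align_global(b, a).score
        )


class TestTemplateMapping:
    def test_identity_mapping_recovers_every_column(self, templates):
        t = templates["PIP"]
        mapping = annotate.map_template_positions(
            ProteinRecord("ref", t.reference_sequence), t
        )
        for name, pos in t.columns.items():
            assert mapping[name] == (pos, t.reference_sequence[pos])

    def test_insertion_before_feature_shifts_index(self, templates):
        t = templates["PIP"]
        pos = t.columns["arR_H2"]
        query = (t.reference_sequence[:pos - 2] + "GGGGG"
                 + t.reference_sequence[pos - 2:])
        mapping = annotate.map_template_positions(ProteinRecord("q", query), t)
        assert mapping["arR_H2"][0] == pos + 5
        # features downstream of the insertion shift too
        assert mapping["froger_P1"][0] == t.columns["froger_P1"] + 5

    def test_deletion_spanning_feature_reports_missing(self, templates):
        t = templates["PIP"]
        pos = t.columns["froger_P2"]
        query = t.reference_sequence[:pos] + t.reference_sequence[pos + 1:]
        mapping = annotate.map_template_positions(ProteinRecord("q", query), t)
        assert mapping["froger_P2"] is None
        assert mapping["froger_P3"] is not None

    def test_low_identity_raises_with_value(self, templates):
        t = templates["PIP"]
        # length-matched junk over residues that are rare in the reference
        junk = "NP" * (len(t.reference_sequence) // 2)
        with pytest.raises(annotate.LowConfidenceAlignment) as err:
            annotate.map_template_positions(ProteinRecord("q", junk), t)
        assert 0.0 <= err.value.identity < 0.25


class TestFindNpaMotifs:
    def test_canonical_double_npa(self):
        seq = "GGGGGNPAGGGGGGGGGGNPAGGGGG"
        motifs = annotate.find_npa_motifs(seq)
        assert [(m.loop, m.start, m.triplet) for m in motifs] == [
            ("B", 5, "NPA"), ("E", 18, "NPA"),
        ]

    def test_degenerate_grammar_variants_match(self):
        seq = "GGNPSGGGGGGGGNPVGG"
        motifs = annotate.find_npa_motifs(seq)
        assert [m.triplet for m in motifs] == ["NPS", "NPV"]

    def test_xip_slv_spa_recovered_via_template_fallback(self, templates):
        # An XIP-like query with fully substituted triplets (SLV/SPA) has no
        # grammar hit; the template fallback recovers both at their columns.
        from aqpkit.templates import SUBFAMILY_SIGNATURES
        from aqpkit.simulate import generate_aqp_proteins
        sig = dict(SUBFAMILY_SIGNATURES["XIP"])
        sig.update(npa1="SLV", npa2="SPA")
        records, truth = generate_aqp_proteins(
            members=[("PruavXIP1;1", sig)], seed=5, indel_frac=0.0,
        )
        seq = records[0].sequence
        motifs = annotate.find_npa_motifs(seq, templates["XIP"])
        assert [m.triplet for m in motifs] == ["SLV", "SPA"]
        assert [m.start for m in motifs] == [
            truth["PruavXIP1;1"]["npa1_1"][0],
            truth["PruavXIP1;1"]["npa2_1"][0],
        ]

    def test_planted_pairs_recovered_exactly_at_random_offsets(self):
        rng = np.random.default_rng(11)
        filler = list("GASTLVIEQKRDHFWYCM")  # no N/P: no spurious hits
        for _ in range(100):
            g1 = int(rng.integers(5, 60))
            g2 = int(rng.integers(5, 60))
            tail = int(rng.integers(5, 30))
            third = "ASTLVI"
            m1 = "NP" + third[rng.integers(6)]
            m2 = "NP" + third[rng.integers(6)]
            seq = ("".join(rng.choice(filler, size=g1)) + m1
                   + "".join(rng.choice(filler, size=g2)) + m2
                   + "".join(rng.choice(filler, size=tail)))
            motifs = annotate.find_npa_motifs(seq)
            assert [(m.loop, m.start) for m in motifs] == [
                ("B", g1), ("E", g1 + 3 + g2)
            ]
            assert motifs[0].triplet == m1 and motifs[1].triplet == m2

    def test_never_overlapping_and_b_before_e(self):
        motifs = annotate.find_npa_motifs("GGNPNPAGG")  # overlapping candidates
        assert len(motifs) <= 2
        if len(motifs) == 2:
            assert motifs[0].start + 3 <= motifs[1].start


class TestPhyschem:
    def test_gravy_single_residue_is_scale_lookup(self):
        assert annotate.compute_gravy("GG") == pytest.approx(KD["G"])

    def test_gravy_is_length_weighted_mean(self):
        s1, s2 = "ACDE", "FGHIKLM"
        g = annotate.compute_gravy(s1 + s2)
        expected = (len(s1) * annotate.compute_gravy(s1)
                    + len(s2) * annotate.compute_gravy(s2)) / (len(s1) + len(s2))
        assert g == pytest.approx(expected)

    def test_gravy_20mer_hand_sum(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert annotate.compute_gravy(seq) == pytest.approx(
            sum(KD[c] for c in seq) / 20
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(protein_strategy)
    def test_gravy_bounded_by_scale_extremes(self, seq):
        assert -4.5 <= annotate.compute_gravy(seq) <= 4.5

    def test_wildcard_requires_skip_policy(self):
        with pytest.raises(ValueError, match="wildcard"):
            annotate.compute_gravy("ACXDE")
        assert annotate.compute_gravy("ACXDE", skip_wildcard=True) == (
            pytest.approx(annotate.compute_gravy("ACDE"))
        )

    def test_mw_gg_hand_computed(self):
        # two average glycine residue masses (57.05 Da) + one water (18.02 Da)
        assert annotate.compute_mw("GG") * 1000 == pytest.approx(
            2 * 57.05 + 18.02, abs=0.1
        )

    def test_mw_additivity(self):
        water_kda = 0.01802
        a, b = "MKT", "AYIAK"
        assert annotate.compute_mw(a + b) == pytest.approx(
            annotate.compute_mw(a) + annotate.compute_mw(b) - water_kda,
            abs=1e-4,
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(protein_strategy, st.sampled_from(AA))
    def test_mw_strictly_increasing_in_length(self, seq, extra):
        assert annotate.compute_mw(seq + extra) > annotate.compute_mw(seq)

    def test_pi_no_ionizable_side_chains_matches_grid_scan(self):
        seq = "GAGAGA"  # only the termini ionize
        pi = annotate.compute_pi(seq)
        grid = np.arange(1.0, 13.0, 0.001)
        charges = np.array([annotate.charge_at_pH(seq, p) for p in grid])
        root = grid[np.argmin(np.abs(charges))]
        assert pi == pytest.approx(root, abs=0.01)
        assert 2.0 < pi < 10.0  # bracketed by the termini pKa values


class TestTmSegments:
    def test_uniform_hydrophobic_spans_everything(self):
        seq = "I" * 40
        assert annotate.predict_tm_segments(seq) == [(0, 39)]

    def test_uniform_hydrophilic_finds_nothing(self):
        assert annotate.predict_tm_segments("D" * 40) == []

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            annotate.predict_tm_segments("I" * 40, window=18)

    def test_two_planted_blocks_detected_as_two_segments(self):
        from aqpkit.simulate import generate_tm_protein
        seq, spans = generate_tm_protein(n_blocks=2, block_len=23,
                                         gap_len=30, seed=1)
        segs = annotate.predict_tm_segments(seq)
        assert len(segs) == 2
        for (ps, pe), (ss, se) in zip(spans, segs):
            # each planted block is inside its reported segment, and the
            # segment never extends past one window beyond the block
            assert ss <= ps and pe <= se
            assert ps - ss < 19 and se - pe < 19
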