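import random

import pytest

from armfold.fold import (
    best_fold,
    enumerate_foldings,
    extract_candidates,
    find_anticodon_arms,
)
from armfold.grammar import TrnaClass, TrnaGrammar, validate_structure
from armfold.model import AnnotatedGenome, GeneAnnotation, Genome, revcomp
from armfold.simulate import build_trna_gene
from conftest import random_dna
from oracles import brute_force_anchor_scores, brute_force_anchors


class TestExtractCandidates:
    def _ag(self, spans, length=400):
        feats = [
            GeneAnnotation(start=s, end=e, gene=g, strand="+")
            for g, (s, e) in spans.items()
        ]
        return AnnotatedGenome(Genome("x", "ACGT" * (length // 4)), feats)

    def test_spacer_window_size(self):
        ag = self._ag({"cox1": (0, 100), "cox2": (130, 230)})
        windows = [w for w in extract_candidates(ag) if w.between == ("cox1", "cox2")]
        assert {w.strand for w in windows} == {"+", "-"}
        assert all(w.length == 30 + 100 for w in windows)

    def test_overlapping_features_pad_only(self):
        ag = self._ag({"cox1": (0, 150), "cox2": (100, 250)})
        windows = [w for w in extract_candidates(ag) if w.between == ("cox1", "cox2")]
        assert all(w.length == 100 for w in windows)

    def test_no_features_whole_genome(self):
        ag = self._ag({})
        with pytest.warns(UserWarning):
            windows = extract_candidates(ag)
        assert len(windows) == 2
        assert windows[0].length == ag.genome.length

    def test_short_windows_still_emitted(self):
        ag = self._ag({"cox1": (0, 100), "cox2": (101, 230)})
        windows = [w for w in extract_candidates(ag, pad=5) if w.between == ("cox1", "cox2")]
        assert all(w.length == 11 for w in windows)

    def test_origin_spanning_window_matches_rotation(self, small_clade):
        ag = small_clade.ancestor
        windows = {(w.between, w.strand): w.seq for w in extract_candidates(ag)}
        rot = ag.rotated(5000)
        windows_rot = {(w.between, w.strand): w.seq for w in extract_candidates(rot)}
        assert windows == windows_rot

    def test_minus_strand_is_revcomp(self):
        ag = self._ag({"cox1": (0, 100), "cox2": (130, 230)})
        plus, minus = [w for w in extract_candidates(ag) if w.between == ("cox1", "cox2")]
        assert minus.seq == revcomp(plus.seq)


class TestFindAnticodonArms:
    def test_planted_perfect_stem(self, rng):
        seq, structure = build_trna_gene("trnA", TrnaClass.ARMLESS, rng)
        anchors = find_anticodon_arms(seq, "trnA")
        planted_anchor = structure.ac_arm.stem5[0]
        assert planted_anchor in anchors

    def test_poly_a_empty(self):
        assert find_anticodon_arms("A" * 60) == []

    def test_unknown_identity_error(self):
        with pytest.raises(KeyError):
            find_anticodon_arms("ACGT" * 10, "trnZ")

    def test_gu_pair_tolerated(self):
        # stem 5' GCTCA / loop CTTGCAA / 3' TGAGT -> pair (G,T) at k=0 is GU
        seq = "TT" + "GCTCA" + "CTTGCAA" + "TGAGT" + "TT"
        anchors = find_anticodon_arms(seq, anticodons=("TGC",))
        assert 2 in anchors

    def test_agreement_with_bruteforce(self):
        rng = random.Random(5)
        for _ in range(60):
            seq = random_dna(rng, rng.randint(17, 60))
            assert find_anticodon_arms(seq) == brute_force_anchors(seq)

    def test_identity_filter(self):
        rng = random.Random(6)
        for _ in range(30):
            seq = random_dna(rng, 50)
            assert find_anticodon_arms(seq, "trnK") == brute_force_anchors(
                seq, anticodons=("CTT", "TTT")
            )


class TestEnumerateFoldings:
    def test_oracle_agreement_on_random_windows(self):
        rng = random.Random(9)
        checked = 0
        for _ in range(500):
            seq = random_dna(rng, rng.randint(31, 45), at=0.55)
            for anchor in find_anticodon_arms(seq):
                got = {
                    st.cls.value: sc.score
                    for st, sc in enumerate_foldings(seq, anchor)
                }
                want = brute_force_anchor_scores(seq, anchor)
                assert got == want, (seq, anchor)
                checked += 1
        assert checked > 10

    def test_oracle_agreement_on_armed_windows(self):
        # lengths 46-64 exercise the single-armed and cloverleaf classes
        rng = random.Random(10)
        checked = 0
        for _ in range(250):
            seq = random_dna(rng, rng.randint(46, 64), at=0.5)
            for anchor in find_anticodon_arms(seq):
                got = {
                    st.cls.value: sc.score
                    for st, sc in enumerate_foldings(seq, anchor)
                }
                assert got == brute_force_anchor_scores(seq, anchor)
                checked += 1
        assert checked > 10

    def test_armless_design_is_armless_only(self, rng):
        # 31-nt window: no room for any side arm
        seq, structure = build_trna_gene("trnY", TrnaClass.ARMLESS, rng)
        window = seq[: structure.length]
        anchor = structure.ac_arm.stem5[0]
        folds = enumerate_foldings(window, anchor)
        classes = {st.cls for st, _ in folds}
        assert TrnaClass.ARMLESS in classes
        assert TrnaClass.CLOVERLEAF not in classes

    def test_cloverleaf_scores_highest_when_planted(self, rng):
        seq, structure = build_trna_gene("trnV", TrnaClass.CLOVERLEAF, rng)
        anchor = structure.ac_arm.stem5[0]
        folds = enumerate_foldings(seq, anchor)
        by_class = {st.cls: sc.score for st, sc in folds}
        assert by_class[TrnaClass.CLOVERLEAF] == max(by_class.values())

    def test_mismatch_cap_blocks_fold(self):
        # acceptor arms share no complementarity: 5' AAAAAAA vs 3' AAAAAAA
        seq = "AAAAAAA" + "TT" + "GCTCA" + "CTTGCAA" + "TGAGC" + "TT" + "AAAAAAA"
        anchors = find_anticodon_arms(seq, anticodons=("TGC",))
        assert anchors
        for anchor in anchors:
            for st, sc in enumerate_foldings(seq, anchor):
                assert sc.mismatches <= 4

    def test_structures_validate_against_grammar(self):
        rng = random.Random(12)
        for _ in range(40):
            seq = random_dna(rng, rng.randint(31, 60), at=0.5)
            for anchor in find_anticodon_arms(seq):
                for st, _ in enumerate_foldings(seq, anchor):
                    assert validate_structure(st, seq) == []


class TestBestFold:
    def test_no_anchor_returns_none(self):
        assert best_fold("A" * 60, "trnA") is None

    def test_single_candidate(self, rng):
        seq, structure = build_trna_gene("trnW", TrnaClass.T_ARMLESS, rng)
        result = best_fold(seq, "trnW")
        assert result is not None
        st, _ = result
        assert st.cls is TrnaClass.T_ARMLESS
        assert st.identity == "trnW"

    def test_tie_broken_five_prime(self):
        # two identical perfect armless candidates in one window
        rng = random.Random(3)
        seq, structure = build_trna_gene("trnA", TrnaClass.ARMLESS, rng)
        window = seq + "TTTT" + seq
        result = best_fold(window, "trnA")
        assert result is not None
        st, _ = result
        assert st.span[0] < len(seq)  # 5'-most copy wins

    def test_planted_class_recovered_solo(self, rng):
        for cls in TrnaClass:
            seq, _ = build_trna_gene("trnQ", cls, rng)
            st, sc = best_fold(seq, "trnQ")
            assert st.cls is cls
            if cls is TrnaClass.ARMLESS:
                assert sc.mismatches == 0
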