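import math
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armfold.model import AnnotatedGenome, GeneAnnotation, Genome, revcomp
from armfold.stats import (
    aa_frequencies_and_rscu,
    at_content,
    overlaps_and_spacers,
    partitioned_composition,
    read_codon_table,
    skews,
    tally_start_stop,
)
from oracles import codon_position_bases

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestAtContent:
    def test_all_at(self):
        assert at_content("ATAT") == 1.0

    def test_all_gc(self):
        assert at_content("GCGC") == 0.0

    def test_n_excluded(self):
        assert at_content("ATNN") == 1.0

    def test_undefined(self):
        assert math.isnan(at_content("NNN"))

    @given(dna, dna)
    def test_concatenation_is_weighted_mean(self, s1, s2):
        c1, c2 = Counter(s1), Counter(s2)
        n1 = sum(c1[b] for b in "ACGT")
        n2 = sum(c2[b] for b in "ACGT")
        expect = (at_content(s1) * n1 + at_content(s2) * n2) / (n1 + n2)
        assert at_content(s1 + s2) == pytest.approx(expect)


class TestSkews:
    def test_balanced(self):
        assert skews("AATT").at_skew == 0.0

    def test_hand_value(self):
        assert skews("AAAT").at_skew == pytest.approx(0.5)

    def test_undefined_is_nan_not_zero(self):
        r = skews("GGCC")
        assert math.isnan(r.at_skew)
        assert r.gc_skew == 0.0

    @given(dna)
    def test_antisymmetric_under_revcomp(self, s):
        fwd, rev = skews(s), skews(revcomp(s))
        if fwd.at_defined:
            assert rev.at_skew == pytest.approx(-fwd.at_skew)
        if fwd.gc_defined:
            assert rev.gc_skew == pytest.approx(-fwd.gc_skew)

    @given(dna)
    def test_bounded(self, s):
        r = skews(s)
        if r.at_defined:
            assert -1.0 <= r.at_skew <= 1.0
        if r.gc_defined:
            assert -1.0 <= r.gc_skew <= 1.0


class TestTally:
    def test_single_entry(self):
        t = tally_start_stop([("ATG", "T")])
        assert t.start_counts == Counter({"ATG": 1})
        assert t.stop_counts == Counter({"T": 1})

    def test_counts_sum_to_entries(self):
        entries = [("ATA", "TAA"), ("ATG", "TA"), ("GTG", "TAG")]
        t = tally_start_stop(entries)
        assert sum(t.start_counts.values()) == len(entries)
        assert sum(t.stop_counts.values()) == len(entries)

    def test_rejects_bad_stop(self):
        with pytest.raises(ValueError):
            tally_start_stop([("ATG", "")])
        with pytest.raises(ValueError):
            tally_start_stop([("ATG", "TAAA")])

    def test_rejects_bad_start(self):
        with pytest.raises(ValueError):
            tally_start_stop([("AT", "TAA")])


class TestOverlaps:
    def _ag(self, spans, length=60):
        feats = [
            GeneAnnotation(start=s, end=e, gene=g, strand="+")
            for g, (s, e) in spans.items()
        ]
        return AnnotatedGenome(Genome("x", "A" * length), feats)

    def test_overlap_negative(self):
        omap = overlaps_and_spacers(self._ag({"cox1": (0, 10), "cox2": (7, 20)}))
        assert ("cox1", "cox2", -3) in omap.entries

    def test_abutting_zero(self):
        omap = overlaps_and_spacers(self._ag({"cox1": (0, 10), "cox2": (10, 20)}))
        assert ("cox1", "cox2", 0) in omap.entries

    def test_single_feature_empty(self):
        assert overlaps_and_spacers(self._ag({"cox1": (0, 10)})).entries == []

    def test_rotation_invariant_total(self, small_clade):
        ag = small_clade.ancestor
        base = sorted(g for _, _, g in overlaps_and_spacers(ag).entries)
        for offset in (1234, 7000, ag.genome.length - 3):
            rot = sorted(g for _, _, g in overlaps_and_spacers(ag.rotated(offset)).entries)
            assert rot == base

    def test_wrap_gap_matches_rotated(self, small_clade):
        ag = small_clade.ancestor
        last = ag.features[-1]
        omap = overlaps_and_spacers(ag)
        wrap_entry = [e for e in omap.entries if e[0] == last.gene][0]
        rot = ag.rotated(last.end + 5)
        omap_rot = overlaps_and_spacers(rot)
        wrap_rot = [e for e in omap_rot.entries if e[0] == last.gene][0]
        assert wrap_entry == wrap_rot


class TestPartitionedComposition:
    def test_codon_position_walk(self):
        assert codon_position_bases("ATGAAATTT", 3) == "GAT"

    def test_against_bruteforce(self, small_clade):
        ag = small_clade.species["sp1"]
        df = partitioned_composition(ag).set_index("partition")
        for f in ag.pcgs:
            seq = ag.feature_sequence(f)
            assert df.loc[f"gene:{f.gene}", "at_content"] == pytest.approx(at_content(seq))
        for strand in "+-":
            seqs = [
                ag.feature_sequence(f)[: len(ag.feature_sequence(f)) // 3 * 3]
                for f in ag.pcgs
                if f.strand == strand
            ]
            for pos in (1, 2, 3):
                pooled = "".join(codon_position_bases(s, pos) for s in seqs)
                assert df.loc[f"PCG:{strand}:pos{pos}", "at_content"] == pytest.approx(
                    at_content(pooled)
                )

    def test_minus_strand_uses_coding_strand(self):
        g = Genome("x", "CATCATCATTTT")
        f = GeneAnnotation(start=0, end=9, gene="nad5", strand="-")
        df = partitioned_composition(AnnotatedGenome(g, [f])).set_index("partition")
        assert df.loc["gene:nad5", "at_content"] == pytest.approx(
            at_content(revcomp("CATCATCAT"))
        )


class TestRscu:
    def test_two_synonyms_balanced(self):
        # lysine in table 5: AAA/AAG; use 5 of each
        seq = "ATG" + "AAA" * 5 + "AAG" * 5 + "TAA"
        ag = AnnotatedGenome(
            Genome("x", seq + "A" * 10),
            [GeneAnnotation(start=0, end=len(seq), gene="cox1", strand="+")],
        )
        _, rscu = aa_frequencies_and_rscu(ag)
        k = rscu[rscu.aa == "K"].set_index("codon")
        assert k.loc["AAA", "rscu"] == pytest.approx(1.0)
        assert k.loc["AAG", "rscu"] == pytest.approx(1.0)

    def test_exclusive_codon_of_four(self):
        # proline CCN family; only CCA used
        seq = "ATG" + "CCA" * 8 + "TAA"
        ag = AnnotatedGenome(
            Genome("x", seq + "A" * 10),
            [GeneAnnotation(start=0, end=len(seq), gene="cox1", strand="+")],
        )
        _, rscu = aa_frequencies_and_rscu(ag)
        p = rscu[rscu.aa == "P"].set_index("codon")
        assert p.loc["CCA", "rscu"] == pytest.approx(4.0)
        assert p.loc["CCT", "rscu"] == 0.0

    def test_family_mean_is_one(self, small_clade):
        _, rscu = aa_frequencies_and_rscu(small_clade.species["sp1"])
        for aa, grp in rscu.groupby("aa"):
            if grp["count"].sum() > 0:
                assert grp["rscu"].mean() == pytest.approx(1.0)

    def test_codon_counts_against_bruteforce(self, small_clade):
        ag = small_clade.species["sp1"]
        counts = Counter()
        for f in ag.pcgs:
            seq = ag.feature_sequence(f)
            for i in range(0, len(seq) - len(seq) % 3, 3):
                counts[seq[i : i + 3]] += 1
        _, rscu = aa_frequencies_and_rscu(ag)
        for _, row in rscu.iterrows():
            assert row["count"] == counts.get(row["codon"], 0)


def test_codon_table_reader():
    from importlib import resources

    path = resources.files("armfold.data").joinpath("dysderid_pcg_codons.tsv")
    entries = read_codon_table(path)
    assert len(entries) == 78  # 13 PCGs x 6 species
    t = tally_start_stop(entries)
    assert sum(t.start_counts.values()) == 78
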