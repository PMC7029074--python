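import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridzone.io import SequenceSet
from hybridzone.markers import (
    HGAI,
    Discordance,
    HaplotypeTable,
    ReferencePanel,
    RestrictionEnzyme,
    UndefinedDistance,
    build_haplotype_network,
    collapse_haplotypes,
    count_stop_codons,
    detect_discordance,
    diagnose_marker,
    group_mean_distances,
    k2p_distance,
    p_distance,
    predict_rflp,
    revcomp,
)

dna = st.text(alphabet="ACGT", min_size=10, max_size=60)


class TestDistances:
    def test_identical_zero(self):
        s = "ACGTACGTAC"
        assert p_distance(s, s) == 0.0
        assert k2p_distance(s, s) == 0.0

    def test_p_distance_by_definition(self):
        # 2 mismatches over 10 comparable sites
        assert p_distance("AAAAAAAAAA", "AAAAAAAACC") == pytest.approx(0.2)

    def test_pairwise_deletion(self):
        assert p_distance("AC-TN", "ACGTA") == 0.0  # only 3 comparable, all equal

    def test_no_comparable_sites_flagged(self):
        with pytest.warns(UndefinedDistance):
            assert math.isnan(p_distance("NNN", "ACG"))

    @settings(max_examples=50, derandomize=True)
    @given(dna, dna)
    def test_p_distance_equals_brute_count(self, s1, s2):
        n = min(len(s1), len(s2))
        s1, s2 = s1[:n], s2[:n]
        brute = sum(a != b for a, b in zip(s1, s2)) / n
        assert p_distance(s1, s2) == pytest.approx(brute)

    def test_k2p_one_transition_in_hundred(self):
        # P = 0.01, Q = 0: d = 1/2 ln(1/0.98)
        s1 = "A" * 100
        s2 = "G" + "A" * 99
        assert k2p_distance(s1, s2) == pytest.approx(0.5 * math.log(1 / 0.98))
        assert k2p_distance(s1, s2) == pytest.approx(0.01010, abs=5e-6)

    def test_k2p_transition_only_closed_form(self):
        # Q = 0 reduces to d = -1/2 ln(1 - 2P)
        s1 = "A" * 50
        for k in (1, 3, 7):
            s2 = "G" * k + "A" * (50 - k)
            P = k / 50
            assert k2p_distance(s1, s2) == pytest.approx(-0.5 * math.log(1 - 2 * P))

    def test_k2p_saturation_flagged(self):
        with pytest.warns(UndefinedDistance):
            assert math.isnan(k2p_distance("A" * 10, "G" * 10))

    def test_k2p_zero_iff_p_zero(self):
        s1, s2 = "ACGTACGTAA", "ACGTACGTAG"
        assert k2p_distance(s1, s2) > 0
        assert p_distance(s1, s2) > 0


class TestGroupDistances:
    def test_two_identical_groups_all_zero(self):
        ss = SequenceSet(["a", "b", "c", "d"], ["ACGT"] * 4, aligned=True)
        t = group_mean_distances(ss, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert t.loc["g1", "g2"] == 0.0
        assert t.loc["g1", "g1"] == 0.0

    @staticmethod
    def _related_seqs(rng, n, length=60, max_subs=6):
        anc = "".join(rng.choice(list("ACGT"), length))
        out = []
        for _ in range(n):
            s = list(anc)
            for pos in rng.choice(length, int(rng.integers(0, max_subs)), replace=False):
                s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
            out.append("".join(s))
        return out

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        seqs = self._related_seqs(rng, 9)
        ids = [f"s{i}" for i in range(9)]
        grouping = {ids[i]: f"g{i % 3}" for i in range(9)}
        ss = SequenceSet(ids, seqs, aligned=True)
        table = group_mean_distances(ss, grouping)
        by_id = dict(zip(ids, seqs))
        for g1, g2 in itertools.combinations_with_replacement(["g0", "g1", "g2"], 2):
            m1 = [i for i in ids if grouping[i] == g1]
            m2 = [i for i in ids if grouping[i] == g2]
            if g1 == g2:
                pairs = list(itertools.combinations(m1, 2))
            else:
                pairs = [(a, b) for a in m1 for b in m2]
            brute = np.mean([k2p_distance(by_id[a], by_id[b]) for a, b in pairs])
            assert table.loc[g1, g2] == pytest.approx(brute)

    def test_three_sequences_mean_of_pairs(self):
        ss = SequenceSet(
            ["a", "b", "c"], ["A" * 40, "G" + "A" * 39, "GG" + "A" * 38], aligned=True
        )
        t = group_mean_distances(ss, {"a": "x", "b": "x", "c": "x"})
        pairs = [
            k2p_distance("A" * 40, "G" + "A" * 39),
            k2p_distance("A" * 40, "GG" + "A" * 38),
            k2p_distance("G" + "A" * 39, "GG" + "A" * 38),
        ]
        assert t.loc["x", "x"] == pytest.approx(np.mean(pairs))

    def test_grouping_permutation_invariance(self):
        rng = np.random.default_rng(6)
        seqs = self._related_seqs(rng, 6, length=30, max_subs=4)
        ids = [f"s{i}" for i in range(6)]
        grouping = {ids[i]: "AB"[i % 2] for i in range(6)}
        a = group_mean_distances(SequenceSet(ids, seqs, aligned=True), grouping)
        perm = [3, 1, 5, 0, 2, 4]
        b = group_mean_distances(
            SequenceSet([ids[i] for i in perm], [seqs[i] for i in perm], aligned=True),
            grouping,
        )
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_singleton_group_flagged(self):
        ss = SequenceSet(["a", "b"], ["ACGT", "ACGT"], aligned=True)
        with pytest.warns(UndefinedDistance):
            t = group_mean_distances(ss, {"a": "g1", "b": "g2"})
        assert math.isnan(t.loc["g1", "g1"])


class TestHaplotypes:
    def test_copies_collapse_to_one(self):
        ss = SequenceSet([f"s{i}" for i in range(5)], ["ACGT"] * 5, aligned=True)
        table = collapse_haplotypes(ss)
        assert len(table) == 1 and table.counts == [5]

    def test_all_distinct_stay_distinct(self):
        ss = SequenceSet(["a", "b", "c"], ["AAAA", "AAAT", "AATT"], aligned=True)
        assert len(collapse_haplotypes(ss)) == 3

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(8)
        pool = ["AAAA", "AAAT", "AATT", "GATT"]
        seqs = [pool[i] for i in rng.integers(0, 4, size=20)]
        ids = [f"s{i}" for i in range(20)]
        table = collapse_haplotypes(SequenceSet(ids, seqs, aligned=True))
        brute = {}
        for i, s in zip(ids, seqs):
            brute.setdefault(s, []).append(i)
        assert sorted(map(tuple, table.members)) == sorted(
            tuple(v) for v in brute.values()
        )
        assert sum(table.counts) == 20

    def test_lenient_mode_merges_through_n(self):
        ss = SequenceSet(["a", "b"], ["ACGT", "ACGN"], aligned=True)
        assert len(collapse_haplotypes(ss, strict=False)) == 1
        assert len(collapse_haplotypes(ss, strict=True)) == 2


class TestNetwork:
    def _table(self, seqs):
        return HaplotypeTable(
            haplotypes=seqs,
            ids=[f"H{i + 1}" for i in range(len(seqs))],
            counts=[1] * len(seqs),
            members=[[f"s{i}"] for i in range(len(seqs))],
        )

    def test_two_haplotypes_one_step(self):
        edges = build_haplotype_network(self._table(["AAAA", "AAAT"]), 10)
        assert edges == [("H1", "H2", 1)]

    def test_line_not_triangle(self):
        edges = build_haplotype_network(self._table(["AAAA", "AAAT", "AATT"]), 10)
        assert sorted(edges) == [("H1", "H2", 1), ("H2", "H3", 1)]

    def test_ties_kept_as_parallel_edges(self):
        # H2 and H3 both 1 step from H1 and 2 steps from each other: both edges to H1 kept
        edges = build_haplotype_network(self._table(["AAAA", "AAAT", "AATA"]), 10)
        assert ("H1", "H2", 1) in edges and ("H1", "H3", 1) in edges

    def test_connection_limit_zero_no_edges(self):
        assert build_haplotype_network(self._table(["AAAA", "AAAT"]), 0) == []

    def test_connection_limit_disconnects(self):
        edges = build_haplotype_network(self._table(["AAAA", "TTTT"]), 3)
        assert edges == []


class TestDigest:
    def test_no_site_single_fragment(self):
        assert predict_rflp("A" * 100) == (100,)

    def test_hand_enumerated_cut(self):
        # GACGC at 10..14, cut 5 nt past the site end: fragments 20 + 80
        seq = "A" * 10 + "GACGC" + "A" * 85
        assert predict_rflp(seq) == (80, 20)

    def test_bottom_strand_site(self):
        # GCGTC at 30 on the top strand: top-strand cut 10 nt upstream (at 20)
        seq = "A" * 30 + "GCGTC" + "A" * 65
        assert predict_rflp(seq) == (80, 20)

    def test_out_of_range_cut_dropped_with_warning(self):
        seq = "A" * 93 + "GACGC" + "AA"  # cut would fall at 103 > 100
        with pytest.warns(UserWarning, match="dropped"):
            assert predict_rflp(seq) == (100,)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(60, 400))
    def test_fragments_sum_to_length(self, seed, length):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), length))
        assert sum(predict_rflp(seq)) == length

    def test_enzyme_on_reverse_complement_mirrors(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 300))
        assert sorted(predict_rflp(seq)) == sorted(predict_rflp(revcomp(seq)))


def _panel():
    p_ref = "A" * 30
    w_ref = "A" * 20 + "G" * 10
    return ReferencePanel(
        sequences={"COI": {"P": p_ref, "W": w_ref}, "Pho": {"P": p_ref, "W": w_ref}},
        rflp_patterns={"P": (152, 131, 97, 70, 33, 17), "W": (232, 153, 66, 33, 17)},
    )


class TestDiagnosis:
    def test_identical_to_reference(self):
        d = diagnose_marker(["A" * 30], "COI", _panel())
        assert d.verdict == "P"

    def test_heterozygote_both_species(self):
        d = diagnose_marker(["A" * 29 + "C", "A" * 20 + "G" * 9 + "C"], "Pho", _panel())
        assert d.verdict == "PW"

    def test_equidistant_is_ambiguous_not_guessed(self):
        mid = "A" * 25 + "G" * 5
        d = diagnose_marker([mid], "COI", _panel())
        assert d.verdict == "missing"
        assert d.evidence["reason"] == "ambiguous"

    def test_rflp_pure_patterns(self):
        assert diagnose_marker((152, 131, 97, 70, 33, 17), "ITS1", _panel()).verdict == "P"
        assert diagnose_marker((232, 153, 66, 33, 17), "ITS1", _panel()).verdict == "W"

    def test_rflp_within_tolerance(self):
        assert diagnose_marker((153, 130, 96, 71, 33, 17), "ITS1", _panel()).verdict == "P"

    def test_rflp_composite_is_pw(self):
        composite = (232, 153, 152, 131, 97, 70, 66, 33, 17)
        assert diagnose_marker(composite, "ITS1", _panel()).verdict == "PW"

    def test_rflp_garbage_is_missing(self):
        assert diagnose_marker((400, 100), "ITS1", _panel()).verdict == "missing"


class TestDiscordance:
    def test_criterion_a_nuclear_pw(self):
        d = detect_discordance({"COI": "P", "Pho": "P", "ITS1": "PW"})
        assert d.hybrid and ("a", ("ITS1",)) in d.criteria

    def test_criterion_b_mt_nuc(self):
        d = detect_discordance({"COI": "P", "Pho": "W", "ITS1": "W"})
        assert d.hybrid
        kinds = {det[-1] for c, det in d.criteria if c == "b"}
        assert "mt-nuc" in kinds

    def test_criterion_b_nuc_nuc(self):
        d = detect_discordance({"Pho": "P", "ITS1": "W"})
        assert d.hybrid
        assert d.criteria[0][1][-1] == "nuc-nuc"

    def test_concordant_not_hybrid(self):
        assert detect_discordance({"COI": "P", "Pho": "P", "ITS1": "P"}).hybrid is False

    def test_mt_pw_does_not_fire_criterion_a(self):
        # mtDNA is uniparental: a PW verdict there cannot fire (a)
        d = detect_discordance({"COI": "PW", "Pho": "P"})
        assert not any(c == "a" for c, _ in d.criteria)

    def test_too_few_markers_undetermined(self):
        assert detect_discordance({"COI": "P"}).hybrid is None
        assert detect_discordance({"COI": "missing", "Pho": "missing"}).hybrid is None

    @settings(max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["COI", "Pho", "ITS1", "usat"]),
            st.sampled_from(["P", "W", "PW", "missing"]),
            min_size=2,
        )
    )
    def test_species_label_symmetry(self, verdicts):
        swap = {"P": "W", "W": "P", "PW": "PW", "missing": "missing"}
        a = detect_discordance(verdicts)
        b = detect_discordance({m: swap[v] for m, v in verdicts.items()})
        assert a.hybrid == b.hybrid and len(a.criteria) == len(b.criteria)


def test_stop_codon_scan():
    assert count_stop_codons("ATGTAAACC") == 1
    assert count_stop_codons("ATGGCTGCA") == 0
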