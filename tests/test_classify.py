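"""Group assignment rules, isoform collapsing, HARF detection and the
family summary arithmetic."""

import random

import pytest

from familyscope import classify
from familyscope.domains import scan_protein

# Printed per-group gene counts of the two Vigna WRKY families.
ADZUKI_COUNTS = {"I": 15, "IIa": 5, "IIb": 14, "IIc": 20, "IId": 7, "IIe": 10, "III": 13}
MUNG_COUNTS = {"I": 16, "IIa": 1, "IIb": 19, "IIc": 20, "IId": 7, "IIe": 9, "III": 13}


def _record(seq, pid="p.1"):
    domains = scan_protein(pid, seq)
    return classify.FamilyRecord(pid, classify.gene_id_of(pid), seq, domains)


def _single_domain(n1=4, n2=23, term="H", variant="WRKYGQK"):
    return "MAA" + variant + "AAAAAAAR" + "AA" + "C" + "A" * n1 + "C" + "A" * n2 + "HA" + term + "AAAA"


class TestAssignGroup:
    def test_two_domains_is_group_i(self):
        seq = (
            "M"
            + "WRKYGQK" + "AAAAAAAA" + "C" + "AAAA" + "C" + "A" * 22 + "HAH"
            + "GGGG"
            + "WRKYGQK" + "AAAAAAAA" + "C" + "AAAA" + "C" + "A" * 23 + "HAH"
        )
        rec = classify.assign_group(_record(seq))
        assert rec.group == "I" and rec.evidence == "grammar"

    def test_single_c2hc_is_group_iii(self):
        rec = classify.assign_group(_record(_single_domain(n1=7, term="C")))
        assert rec.group == "III"

    def test_single_c2h2_n1_4_is_group_iic(self):
        rec = classify.assign_group(_record(_single_domain(n1=4)))
        assert rec.group == "IIc"

    def test_single_c2h2_long_spacer_unresolved_without_references(self):
        rec = classify.assign_group(_record(_single_domain(n1=5)))
        assert rec.group == "II-unresolved"

    def test_single_c2h2_long_spacer_resolved_by_nearest_reference(self):
        seq = _single_domain(n1=5)
        rec = _record(seq)
        d = rec.domains[0]
        dom_seq = seq[d.domain_start : d.domain_end + 1]
        far = "WRKYGQK" + "DDDDDDDD" + "C" + "DDDDD" + "C" + "D" * 23 + "HDH"
        refs = [("ref_d", "IId", dom_seq), ("ref_a", "IIa", far)]
        rec = classify.assign_group(rec, refs)
        assert rec.group == "IId"
        assert rec.evidence == "grammar+phylogeny"

    def test_finger_only_truncation_classified_by_finger(self):
        seq = "M" + "A" * 35 + "C" + "A" * 7 + "C" + "A" * 23 + "HAC" + "AAA"
        rec = classify.assign_group(_record(seq))
        assert rec.group == "III"

    def test_heptapeptide_only_truncation_unresolved_without_references(self):
        rec = classify.assign_group(_record("MAA" + "WRKYGQK" + "A" * 120))
        assert rec.group == "II-unresolved"

    def test_zero_domains_rejected(self):
        rec = classify.FamilyRecord("p.1", "p", "MAAA", [])
        with pytest.raises(ValueError, match="not a family member"):
            classify.assign_group(rec)

    def test_assignment_invariant_to_reference_order(self):
        seq = _single_domain(n1=5)
        rec = _record(seq)
        d = rec.domains[0]
        dom = seq[d.domain_start : d.domain_end + 1]
        refs = [
            ("r1", "IIa", dom[:-2] + "DD"),
            ("r2", "IIe", dom),
            ("r3", "IIb", "WRKYGQK" + "E" * 40),
        ]
        labels = set()
        for i in range(5):
            shuffled = refs[:]
            random.Random(i).shuffle(shuffled)
            labels.add(classify.assign_group(_record(seq), shuffled).group)
        assert labels == {"IIe"}


class TestHarf:
    @pytest.mark.parametrize(
        "seq, present",
        [
            ("AARTGHARFRRAPAA", True),
            ("AARTGHARFRRGPAA", True),
            ("AARTGHARFRRTPAA", False),
            ("RTGHARFRR", False),
        ],
    )
    def test_motif(self, seq, present):
        assert classify.detect_harf(seq)[0] is present


class TestCollapseIsoforms:
    def _recs(self, entries):
        out = []
        for pid, seq in entries:
            out.append(
                classify.FamilyRecord(pid, classify.gene_id_of(pid), seq, [], group="IIc")
            )
        return out

    def test_longest_isoform_represents_the_gene(self):
        recs = self._recs(
            [("g1.1", "MAAAA"), ("g1.2", "MAAAAAAA"), ("g1.3", "MA"), ("g1.4", "MAA")]
        )
        (rep,) = classify.collapse_isoforms(recs)
        assert rep.protein_id == "g1.2"
        assert rep.n_isoforms == 4

    def test_tie_goes_to_lowest_suffix(self):
        recs = self._recs([("g1.2", "MAAA"), ("g1.1", "MAAA")])
        (rep,) = classify.collapse_isoforms(recs)
        assert rep.protein_id == "g1.1"

    def test_single_isoform_unchanged(self):
        recs = self._recs([("g1.1", "MAAA")])
        (rep,) = classify.collapse_isoforms(recs)
        assert rep.protein_id == "g1.1" and rep.n_isoforms == 1

    def test_identical_proteins_at_distinct_loci_flagged_redundant(self):
        recs = self._recs([("g1.1", "MWAAA"), ("g2.1", "MWAAA"), ("g3.1", "MKV")])
        out = {r.protein_id: r for r in classify.collapse_isoforms(recs)}
        assert out["g1.1"].redundant_with == "g2.1"
        assert out["g2.1"].redundant_with == "g1.1"
        assert out["g3.1"].redundant_with is None

    def test_conflicting_isoform_labels_warn(self):
        recs = self._recs([("g1.1", "MAAAA"), ("g1.2", "MAA")])
        recs[1].group = "IIe"
        with pytest.warns(UserWarning, match="disagree"):
            (rep,) = classify.collapse_isoforms(recs)
        assert rep.group == "IIc"


class TestSummarize:
    def test_adzuki_count_vector_reproduces_printed_percentages(self):
        s = classify.summarize(ADZUKI_COUNTS)
        assert s.total == 84
        assert s.percentages["I"] == 17.9
        assert s.percentages["IIc"] == 23.8
        assert s.percentages["IId"] == 8.3
        assert s.percentages["IIe"] == 11.9
        assert s.percentages["III"] == 15.5
        assert s.combined_IIa_IIb == 23

    def test_mung_count_vector_reproduces_printed_percentages(self):
        s = classify.summarize(MUNG_COUNTS)
        assert s.total == 85
        assert s.percentages["I"] == 18.8
        assert s.percentages["IIc"] == 23.5
        assert s.percentages["IId"] == 8.2
        assert s.percentages["IIe"] == 10.6
        assert s.percentages["III"] == 15.3

    def test_group_ii_totals(self):
        for counts in (ADZUKI_COUNTS, MUNG_COUNTS):
            assert sum(counts[g] for g in ("IIa", "IIb", "IIc", "IId", "IIe")) == 56

    def test_single_group_is_100_percent(self):
        s = classify.summarize({"III": 7})
        assert s.percentages["III"] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify.summarize({})

    @pytest.mark.parametrize("seed", range(5))
    def test_percentages_sum_to_100_within_rounding(self, seed):
        rnd = random.Random(seed)
        counts = {g: rnd.randint(0, 40) for g in classify.GROUPS}
        counts["IIc"] += 1  # nonempty
        s = classify.summarize(counts)
        assert abs(sum(s.percentages.values()) - 100.0) <= 0.3

    def test_half_up_rounding(self):
        # 1/8 = 12.5% exactly: half-up gives 12.5 -> combined 13 if IIa+IIb.
        s = classify.summarize({"IIa": 1, "IIc": 7})
        assert s.percentages["IIa"] == 12.5
        assert s.combined_IIa_IIb == 13
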