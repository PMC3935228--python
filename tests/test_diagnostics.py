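import itertools

import pytest

from barcodegap import (
    AmplificationError,
    Primer,
    SequenceRecord,
    SequenceSet,
    call_species,
    find_diagnostic_sites,
    match_primer,
    reverse_complement,
    select_tag_windows,
    tag_difference_counts,
    virtual_pcr,
)
from barcodegap.diagnostics import TagWindow
from barcodegap.reference import (
    HERMYBIUS_REFERENCE,
    HERMYBIUS_VS_SOSYBIUS_POSITIONS,
    INTRICATA_HOLOTYPE,
    SOSYBIUS_NEOTYPE,
    STYR_ID1F,
    STYR_ID1R,
    STYR_ID2F,
    STYR_ID2R,
)

SOS = "Hermeuptychia sosybius"
HER = "Hermeuptychia hermybius"
INT = "Hermeuptychia intricata"


class TestDiagnosticSites:
    def test_all_published_positions_confirmed(self):
        """Every published 'k X (not Y)' entry holds on the two reference
        barcodes: hermybius shows X, the sosybius neotype shows Y."""
        seqs = SequenceSet([HERMYBIUS_REFERENCE, SOSYBIUS_NEOTYPE])
        labels = {HERMYBIUS_REFERENCE.id: HER, SOSYBIUS_NEOTYPE.id: SOS}
        sites = {s.position: s for s in find_diagnostic_sites(seqs, labels)}
        confirmed = 0
        for pos, x, y in HERMYBIUS_VS_SOSYBIUS_POSITIONS:
            assert pos in sites
            assert sites[pos].states[HER] == x
            assert sites[pos].states[SOS] == y
            confirmed += 1
        assert confirmed == 11

    def test_identical_groups_give_no_sites(self):
        seqs = SequenceSet(
            [SequenceRecord("a", "ACGT", species="A"), SequenceRecord("b", "ACGT", species="B")]
        )
        assert find_diagnostic_sites(seqs, {"a": "A", "b": "B"}) == []

    def test_matches_brute_force_column_scan(self, toy_alignment):
        labels = {r.id: r.species for r in toy_alignment}
        groups = ["A", "B", "C"]
        sites = find_diagnostic_sites(toy_alignment, labels, groups)
        # independent per-column re-scan
        members = {g: [r for r in toy_alignment if r.species == g] for g in groups}
        expected = []
        for col in range(toy_alignment.alignment_length):
            states = {}
            good = True
            for g in groups:
                obs = {m.residues[col] for m in members[g]}
                if len(obs) != 1 or not obs <= set("ACGT"):
                    good = False
                    break
                states[g] = obs.pop()
            if good and len(set(states.values())) > 1:
                expected.append((col + 1, states))
        assert [(s.position, dict(s.states)) for s in sites] == expected

    def test_single_ambiguity_disqualifies_column(self):
        seqs = SequenceSet(
            [
                SequenceRecord("a1", "ACGT", species="A"),
                SequenceRecord("a2", "NCGT", species="A"),
                SequenceRecord("b1", "TCGT", species="B"),
            ]
        )
        sites = find_diagnostic_sites(seqs, {r.id: r.species for r in seqs})
        assert sites == []

    def test_unknown_group_rejected(self, toy_alignment):
        labels = {r.id: r.species for r in toy_alignment}
        with pytest.raises(ValueError, match="nope"):
            find_diagnostic_sites(toy_alignment, labels, ["A", "nope"])


class TestTagWindows:
    def _reference_profile(self):
        seqs = SequenceSet([SOSYBIUS_NEOTYPE, HERMYBIUS_REFERENCE, INTRICATA_HOLOTYPE])
        labels = {r.id: r.species for r in seqs}
        return find_diagnostic_sites(seqs, labels), [SOS, HER, INT]

    def test_tag2_region_separates_all_pairs_by_two(self):
        sites, groups = self._reference_profile()
        amp = virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID2F, STYR_ID2R)
        s, e = amp.insert_interval
        inside = [x for x in sites if s <= x.position <= e]
        for ga, gb in itertools.combinations(groups, 2):
            assert sum(1 for x in inside if x.states[ga] != x.states[gb]) >= 2

    def test_empty_site_list_gives_empty_ranking(self):
        assert select_tag_windows([], ["A", "B"], 50, 658) == []

    def test_top_window_matches_exhaustive_enumeration(self, toy_alignment):
        labels = {r.id: r.species for r in toy_alignment}
        groups = ["A", "B", "C"]
        sites = find_diagnostic_sites(toy_alignment, labels, groups)
        L = toy_alignment.alignment_length
        win = 4
        best = select_tag_windows(sites, groups, win, L, top_k=1)[0]
        # brute force over every start
        def score(start):
            inside = [s for s in sites if start <= s.position <= start + win - 1]
            pm = min(
                sum(1 for s in inside if s.states[a] != s.states[b])
                for a, b in itertools.combinations(groups, 2)
            ) if inside else 0
            return (pm, len(inside))

        scores = {st: score(st) for st in range(1, L - win + 2)}
        top = max(scores.values())
        assert (best.pair_min, best.site_count) == top
        assert best.start == min(s for s, sc in scores.items() if sc == top)

    def test_ranking_stable_under_site_permutation(self, toy_alignment):
        labels = {r.id: r.species for r in toy_alignment}
        groups = ["A", "B", "C"]
        sites = find_diagnostic_sites(toy_alignment, labels, groups)
        fwd = select_tag_windows(sites, groups, 5, 10, top_k=3)
        rev = select_tag_windows(list(reversed(sites)), groups, 5, 10, top_k=3)
        assert fwd == rev

    def test_bad_window_length_rejected(self):
        with pytest.raises(ValueError):
            select_tag_windows([], ["A", "B"], 0, 658)


class TestPrimerMatching:
    def test_forward_primer_binds_neotype_once_through_degenerate_w(self):
        hits = match_primer(SOSYBIUS_NEOTYPE, STYR_ID1F)
        assert len(hits) == 1
        start, end = hits[0]
        window = SOSYBIUS_NEOTYPE.residues[start - 1 : end]
        # degenerate W matched against an A in the template
        w_at = STYR_ID1F.residues.index("W")
        assert window[w_at] in "AT"

    def test_no_match_is_empty(self):
        p = Primer("p", "AAAA", "forward")
        assert match_primer(SequenceRecord("t", "CCCC"), p) == []

    def test_degenerate_set_intersection(self):
        p = Primer("p", "AR", "forward")
        assert match_primer(SequenceRecord("t", "AG"), p) == [(1, 2)]
        assert match_primer(SequenceRecord("t", "AA"), p) == [(1, 2)]
        assert match_primer(SequenceRecord("t", "AC"), p) == []

    def test_reverse_primer_matched_by_reverse_complement(self):
        tmpl = SequenceRecord("t", "AAATTTGGGCCC")
        # reverse primer written 5'->3' on the minus strand of GGGCCC
        p = Primer("r", reverse_complement("GGGCCC"), "reverse")
        assert match_primer(tmpl, p) == [(7, 12)]


class TestVirtualPCR:
    def test_tag1_product_on_neotype(self):
        amp = virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID1F, STYR_ID1R)
        assert amp.insert_len == 75
        assert amp.product_len == 118

    def test_tag2_product_on_neotype(self):
        amp = virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID2F, STYR_ID2R)
        assert amp.insert_len == 56
        assert amp.product_len == 103

    def test_both_tags_amplify_all_three_references(self):
        for tmpl in (SOSYBIUS_NEOTYPE, HERMYBIUS_REFERENCE, INTRICATA_HOLOTYPE):
            for f, r in ((STYR_ID1F, STYR_ID1R), (STYR_ID2F, STYR_ID2R)):
                amp = virtual_pcr(tmpl, f, r)
                assert amp.product_len - amp.insert_len == len(f) + len(r)

    def test_swapped_primer_order_rejected(self):
        with pytest.raises(AmplificationError):
            virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID2F, STYR_ID1R)  # rev upstream of fwd

    def test_wrong_orientation_rejected(self):
        with pytest.raises(AmplificationError, match="orientation"):
            virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID1R, STYR_ID1F)


class TestSpeciesCalling:
    def _profile_and_insert(self, template):
        seqs = SequenceSet([SOSYBIUS_NEOTYPE, HERMYBIUS_REFERENCE, INTRICATA_HOLOTYPE])
        labels = {r.id: r.species for r in seqs}
        sites = find_diagnostic_sites(seqs, labels)
        amp = virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID2F, STYR_ID2R)
        s, e = amp.insert_interval
        profile = [x for x in sites if s <= x.position <= e]
        frag = SequenceRecord("frag", template.residues[s - 1 : e])
        return profile, frag, s

    def test_neotype_insert_called_sosybius(self):
        profile, frag, offset = self._profile_and_insert(SOSYBIUS_NEOTYPE)
        call = call_species(frag, profile, offset=offset)
        assert call.verdict == SOS
        # every scorable site is consistent with sosybius (other groups may
        # share a state at three-group sites)
        assert all(SOS in ev.matching_groups for ev in call.evidence)

    def test_intricata_insert_called_intricata(self):
        profile, frag, offset = self._profile_and_insert(INTRICATA_HOLOTYPE)
        assert call_species(frag, profile, offset=offset).verdict == INT

    def test_chimeric_fragment_flagged_contaminated(self):
        # intricata first half (sites private to intricata) + sosybius
        # second half (sites private to sosybius): irreconcilable evidence
        profile, frag_sos, offset = self._profile_and_insert(SOSYBIUS_NEOTYPE)
        _, frag_int, _ = self._profile_and_insert(INTRICATA_HOLOTYPE)
        half = len(frag_sos.residues) // 2
        chimera = SequenceRecord(
            "chimera", frag_int.residues[:half] + frag_sos.residues[half:]
        )
        assert call_species(chimera, profile, offset=offset).verdict == "contaminated"

    def test_fragment_without_sites_is_no_match(self):
        profile, _, _ = self._profile_and_insert(SOSYBIUS_NEOTYPE)
        frag = SequenceRecord("f", SOSYBIUS_NEOTYPE.residues[:10])
        assert call_species(frag, profile, offset=1).verdict == "no-match"

    def test_unmodified_member_recovers_its_group(self):
        seqs = SequenceSet([SOSYBIUS_NEOTYPE, HERMYBIUS_REFERENCE, INTRICATA_HOLOTYPE])
        labels = {r.id: r.species for r in seqs}
        profile = find_diagnostic_sites(seqs, labels)
        for rec in seqs:
            assert call_species(rec, profile, offset=1).verdict == rec.species

    def test_bad_offset_rejected(self):
        with pytest.raises(ValueError):
            call_species(SequenceRecord("f", "ACGT"), [], offset=0)


class TestTagDifferenceCounts:
    def test_published_tag2_differences(self, reference_set):
        amp = virtual_pcr(SOSYBIUS_NEOTYPE, STYR_ID2F, STYR_ID2R)
        counts = tag_difference_counts(reference_set, amp.insert_interval)
        assert counts[frozenset(("KJ025561", "KJ025595"))] == 4
        assert min(counts.values()) >= 2

    def test_self_difference_zero(self):
        seqs = SequenceSet([SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")])
        counts = tag_difference_counts(seqs, TagWindow(1, 4, 0, 0))
        assert counts[frozenset(("a", "b"))] == 0

    def test_out_of_range_window_rejected(self, reference_set):
        with pytest.raises(ValueError, match="range"):
            tag_difference_counts(reference_set, (600, 700))
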