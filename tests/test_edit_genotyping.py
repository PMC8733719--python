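import pytest

from paircut import (
    EditScenario,
    PrimerSet,
    call_edit,
    classify_plant,
    in_silico_pcr,
    nested_pcr,
    reverse_complement,
    simulate_edited_amplicons,
    transgene_status,
)
from paircut.edit_genotyping import (
    CHI,
    COMPLEX,
    ForeignSequenceError,
    HET,
    HOM,
    LARGE_DELETION,
    NON_EDITED,
    WILD_TYPE,
)

from conftest import random_sequence

REF = random_sequence(101, 3000)
CUTS = (900, 2100)

EXPECTED_CALL = {
    "wild-type": WILD_TYPE,
    "deletion": LARGE_DELETION,
    "deletion+insertion": LARGE_DELETION,
    "indel-g1": "indel-g1",
    "indel-g2": "indel-g2",
}

ALL_SCENARIOS = [
    EditScenario("wild-type"),
    EditScenario("deletion"),
    EditScenario("deletion+insertion", insertion_len=5),
    EditScenario("deletion+insertion", insertion_len=23),
    EditScenario("indel-g1", indel_len=-7),
    EditScenario("indel-g1", indel_len=2),
    EditScenario("indel-g2", indel_len=-1),
    EditScenario("indel-g2", indel_len=12),
]


def left_aligned_gap(reference: str, start: int, length: int) -> int:
    """Independent mini-oracle: leftmost equivalent placement of the gap
    [start, start+length)."""
    while start > 0 and reference[start - 1] == reference[start + length - 1]:
        start -= 1
    return start


class TestInSilicoPcr:
    FWD = REF[100:120]
    REV = reverse_complement(REF[580:600])

    def test_planted_amplicon(self):
        products = in_silico_pcr(REF, self.FWD, self.REV)
        assert [length for _, length in products] == [500]
        assert products[0][0] == REF[100:600]

    def test_missing_reverse_site_empty(self):
        assert in_silico_pcr(REF[:400], self.FWD, self.REV) == []

    def test_deleted_template_product_shorter_by_delta(self):
        fwd = REF[700:720]
        rev = reverse_complement(REF[2500:2520])
        start, end = 1000, 2408  # Δ = 1408
        deleted = REF[:start] + REF[end:]
        (_, wt_len), = in_silico_pcr(REF, fwd, rev)
        (_, mut_len), = in_silico_pcr(deleted, fwd, rev)
        assert wt_len - mut_len == 1408

    def test_five_prime_mismatch_tolerated_but_seed_exact(self):
        fuzzy_fwd = ("A" if self.FWD[0] != "A" else "C") + self.FWD[1:]
        assert in_silico_pcr(REF, fuzzy_fwd, self.REV)
        bad_seed = self.FWD[:-1] + ("A" if self.FWD[-1] != "A" else "C")
        assert in_silico_pcr(REF, bad_seed, self.REV) == []

    def test_nested_pcr_products_nested(self):
        primers = PrimerSet(
            label="t",
            outer_forward=REF[100:120],
            outer_reverse=reverse_complement(REF[580:600]),
            inner_forward=REF[150:170],
            inner_reverse=reverse_complement(REF[520:540]),
        )
        products = nested_pcr(REF, primers)
        assert [length for _, length in products] == [390]

    def test_primer_length_floor(self):
        with pytest.raises(ValueError):
            PrimerSet("t", "ACGTACGTACGT", REF[580:600], REF[150:170], REF[520:540])


class TestCallEdit:
    def test_reference_is_wild_type(self):
        call = call_edit(REF, REF, CUTS)
        assert call.call_type == WILD_TYPE
        assert call.deletion_size == 0
        assert call.junction_insertion == ""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_recovery_over_all_scenarios(self, seed):
        """call_edit recovers call type, Δ (exact) and left-aligned
        breakpoints for every simulated scenario."""
        clones, truths = simulate_edited_amplicons(
            REF, CUTS, ALL_SCENARIOS, clones_per_scenario=2, seed=seed
        )
        for (clone_id, seq), truth in zip(clones, truths):
            call = call_edit(REF, seq, CUTS, clone_id=clone_id)
            assert call.call_type == EXPECTED_CALL[truth.kind], truth.kind
            assert call.deletion_size == truth.delta
            if truth.kind == "wild-type":
                continue
            expected_left = left_aligned_gap(
                REF, truth.breakpoint_left,
                truth.breakpoint_right - truth.breakpoint_left,
            ) if not truth.insertion else truth.breakpoint_left
            assert call.breakpoint_left == expected_left
            assert (
                call.breakpoint_right - call.breakpoint_left
                == truth.breakpoint_right - truth.breakpoint_left
            )
            if truth.insertion and truth.kind == "deletion+insertion":
                assert call.junction_insertion == truth.insertion

    def test_junction_insertion_length_reported(self):
        clones, truths = simulate_edited_amplicons(
            REF, CUTS, [EditScenario("deletion+insertion", insertion_len=5)], seed=4
        )
        call = call_edit(REF, clones[0][1], CUTS)
        assert call.call_type == LARGE_DELETION
        assert len(call.junction_insertion) == 5

    def test_microhomology_deletion_left_aligned(self):
        # a CTGA repeat straddles both breakpoints: the deleted segment can
        # slide by 4 bases; the left-aligned placement must be reported
        ref = random_sequence(7, 400) + "CTGA" + random_sequence(8, 300) \
            + "CTGA" + random_sequence(9, 400)
        cut_l, cut_r = 404, 708  # inside/at the two repeat copies
        amplicon = ref[:404] + ref[708:]
        call = call_edit(ref, amplicon, (cut_l, cut_r))
        assert call.call_type == LARGE_DELETION
        assert call.deletion_size == 304
        assert call.breakpoint_left == left_aligned_gap(ref, 404, 304)
        assert call.microhomology_span >= 4

    def test_reverse_complement_amplicon_normalized(self):
        clones, _ = simulate_edited_amplicons(
            REF, CUTS, [EditScenario("deletion")], seed=5
        )
        call = call_edit(REF, reverse_complement(clones[0][1]), CUTS)
        assert call.call_type == LARGE_DELETION
        assert call.deletion_size == CUTS[1] - CUTS[0]

    def test_foreign_sequence_rejected(self):
        with pytest.raises(ForeignSequenceError):
            call_edit(REF, random_sequence(55, 800), CUTS)

    def test_two_site_indels_called_complex(self):
        amplicon = (
            REF[: CUTS[0] - 3] + REF[CUTS[0] :][: CUTS[1] - CUTS[0] - 4] + REF[CUTS[1] :]
        )
        call = call_edit(REF, amplicon, CUTS)
        assert call.call_type == COMPLEX


class TestClassifyPlant:
    def _deletion_call(self, delta=1427, left=900):
        return call_edit(
            REF, REF[:left] + REF[left + delta :], (left, left + delta)
        )

    def test_het_five_deletion_four_wildtype(self):
        calls = [self._deletion_call() for _ in range(5)] + [
            call_edit(REF, REF, CUTS) for _ in range(4)
        ]
        got = classify_plant(calls, edited_band=True, wt_band=True)
        assert got.genotype == HET

    def test_all_wildtype_wt_band_only_non_edited(self):
        calls = [call_edit(REF, REF, CUTS) for _ in range(6)]
        got = classify_plant(calls, edited_band=False, wt_band=True)
        assert got.genotype == NON_EDITED

    def test_three_distinct_junctions_chimeric(self):
        calls = [
            self._deletion_call(1200, 900),
            self._deletion_call(1205, 898),
            self._deletion_call(1190, 905),
        ]
        got = classify_plant(calls, edited_band=True, wt_band=True)
        assert got.genotype == CHI

    def test_edited_band_only_single_allele_homozygous(self):
        calls = [self._deletion_call() for _ in range(6)]
        got = classify_plant(calls, edited_band=True, wt_band=False)
        assert got.genotype == HOM

    def test_order_invariant(self):
        calls = [self._deletion_call() for _ in range(5)] + [
            call_edit(REF, REF, CUTS) for _ in range(4)
        ]
        fwd = classify_plant(calls, edited_band=True, wt_band=True)
        rev = classify_plant(list(reversed(calls)), edited_band=True, wt_band=True)
        assert fwd.genotype == rev.genotype

    def test_extreme_edited_fraction_called_chimeric(self):
        calls = [self._deletion_call()] + [call_edit(REF, REF, CUTS) for _ in range(9)]
        got = classify_plant(calls, edited_band=True, wt_band=True)
        assert got.genotype == CHI

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_plant([], edited_band=False, wt_band=True)


class TestTransgeneStatus:
    CAS9 = random_sequence(201, 600)
    REP = random_sequence(202, 500)
    MARKERS = {
        "Cas9": (CAS9[50:70], reverse_complement(CAS9[450:470]), 420),
        "Rep/RepA": (REP[30:50], reverse_complement(REP[380:400]), 370),
    }

    def test_cas9_cassette_detected(self):
        template = REF + self.CAS9
        assert transgene_status(template, {"Cas9": self.MARKERS["Cas9"]}) == {
            "Cas9": True
        }

    def test_clean_template_all_negative(self):
        got = transgene_status(REF, self.MARKERS)
        assert got == {"Cas9": False, "Rep/RepA": False}

    def test_rep_only_plant(self):
        template = REF + self.REP
        got = transgene_status(template, self.MARKERS)
        assert got == {"Cas9": False, "Rep/RepA": True}

    def test_wrong_product_length_not_detected(self):
        fwd, rev, _ = self.MARKERS["Cas9"]
        got = transgene_status(REF + self.CAS9, {"Cas9": (fwd, rev, 900)})
        assert got == {"Cas9": False}
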