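import pytest

from paircut import (
    OffTargetPolicy,
    build_profile,
    evaluate_policy,
    search_bulge,
    search_mismatch,
)
from paircut.offtarget_search import OffTargetProfile, OffTargetHit

from conftest import make_genome, random_sequence
from oracles import naive_bulge_search, naive_mismatch_search, rc

SPACER = "TGTCTGACTTGACTCCGTG"


def plant(background: str, pos: int, site: str, pam: str = "TGG") -> str:
    text = site + pam
    return background[:pos] + text + background[pos + len(text):]


class TestSearchMismatch:
    def test_unique_planted_site_self_match(self):
        g = make_genome(c=plant(random_sequence(0, 400), 100, SPACER))
        hits = search_mismatch(g, SPACER, max_mm=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.seq_id, h.strand, h.start, h.mismatch_count) == ("c", "+", 100, 0)

    def test_mismatch_positions_reported(self):
        mutated = list(SPACER)
        mutated[4] = "A" if SPACER[4] != "A" else "C"   # position 5
        mutated[10] = "A" if SPACER[10] != "A" else "C"  # position 11
        seq = plant(random_sequence(1, 600), 50, SPACER)
        seq = plant(seq, 300, "".join(mutated))
        hits = search_mismatch(make_genome(c=seq), SPACER, max_mm=2)
        by_start = {h.start: h for h in hits}
        assert by_start[300].mismatch_positions == (5, 11)
        assert by_start[300].mismatch_count == 2
        assert by_start[50].mismatch_count == 0

    def test_minus_strand_site_found(self):
        site_rc = rc(SPACER + "AGG")
        seq = random_sequence(2, 300)[:120] + site_rc + random_sequence(3, 120)
        hits = search_mismatch(make_genome(c=seq), SPACER, max_mm=0)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].site == SPACER
        assert hits[0].pam == "AGG"

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("max_mm", [0, 2, 4])
    def test_equals_brute_force(self, seed, max_mm):
        seq = random_sequence(seed + 100, 3000)
        seq = plant(seq, 500, SPACER)
        mutated = list(SPACER)
        mutated[2] = {"A": "C", "C": "A", "G": "A", "T": "G"}[mutated[2]]
        seq = plant(seq, 1500, "".join(mutated))
        g = make_genome(c=seq)
        got = {
            (h.seq_id, h.strand, h.start, h.end, h.mismatch_positions)
            for h in search_mismatch(g, SPACER, max_mm=max_mm)
        }
        assert got == naive_mismatch_search(g.records, SPACER, max_mm)

    def test_monotone_in_mismatch_level(self):
        g = make_genome(c=plant(random_sequence(42, 5000), 700, SPACER))
        previous = set()
        for k in range(5):
            current = {
                (h.seq_id, h.strand, h.start)
                for h in search_mismatch(g, SPACER, max_mm=k)
            }
            assert previous <= current
            previous = current

    def test_strand_symmetry(self):
        seq = plant(random_sequence(8, 2000), 400, SPACER)
        fwd = search_mismatch(make_genome(c=seq), SPACER, max_mm=3)
        rev = search_mismatch(make_genome(c=rc(seq)), SPACER, max_mm=3)
        n = len(seq)
        fwd_set = {(h.strand, h.start, h.end, h.mismatch_positions) for h in fwd}
        mirrored = {
            ("+" if h.strand == "-" else "-", n - h.end, n - h.start,
             h.mismatch_positions)
            for h in rev
        }
        assert fwd_set == mirrored

    def test_window_with_many_ns_never_matches(self):
        seq = plant(random_sequence(3, 200), 50, SPACER)
        noisy = seq[:55] + "NNNNN" + seq[60:]
        assert search_mismatch(make_genome(c=noisy), SPACER, max_mm=4) == []

    def test_spacer_with_n_rejected(self):
        g = make_genome(c=random_sequence(0, 100))
        with pytest.raises(ValueError):
            search_mismatch(g, "ACGTNACGTACGTACGTAC", max_mm=2)

    def test_max_mm_above_validated_regime_rejected(self):
        g = make_genome(c=random_sequence(0, 100))
        with pytest.raises(ValueError):
            search_mismatch(g, SPACER, max_mm=5)


class TestSearchBulge:
    def test_planted_dna_bulge(self):
        bulged = SPACER[:9] + "T" + SPACER[9:]
        g = make_genome(c=plant(random_sequence(5, 500), 200, bulged))
        hits = search_bulge(g, SPACER, max_mm=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.bulge_type, h.bulge_size, h.mismatch_count) == ("dna", 1, 0)
        assert h.start == 200 and h.end == 220

    def test_planted_rna_bulge(self):
        shrunk = SPACER[:9] + SPACER[10:]
        g = make_genome(c=plant(random_sequence(6, 500), 200, shrunk))
        hits = search_bulge(g, SPACER, max_mm=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.bulge_type, h.bulge_size, h.mismatch_count) == ("rna", 1, 0)
        assert h.end - h.start == len(SPACER) - 1

    def test_perfect_site_not_duplicated_as_bulge(self):
        g = make_genome(c=plant(random_sequence(7, 500), 200, SPACER))
        assert search_mismatch(g, SPACER, max_mm=0)
        for h in search_bulge(g, SPACER, max_mm=3):
            assert h.start != 200

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_brute_force_oracle(self, seed):
        seq = random_sequence(seed + 50, 2500)
        bulged = SPACER[:7] + "A" + SPACER[7:]
        seq = plant(seq, 800, bulged)
        g = make_genome(c=seq)
        got = {
            (h.seq_id, h.strand, h.start, h.end, h.bulge_type, h.mismatch_count)
            for h in search_bulge(g, SPACER, max_mm=3)
        }
        assert got == naive_bulge_search(g.records, SPACER, max_mm=3)

    def test_bulge_size_zero_empty(self):
        g = make_genome(c=random_sequence(1, 300))
        assert search_bulge(g, SPACER, bulge_size=0) == []

    def test_invalid_bulge_size(self):
        g = make_genome(c=random_sequence(1, 100))
        with pytest.raises(ValueError):
            search_bulge(g, SPACER, bulge_size=2)


class TestProfileAndPolicy:
    def test_on_target_excluded_from_counts_but_flagged(self):
        g = make_genome(c=plant(random_sequence(0, 400), 100, SPACER))
        hits = search_mismatch(g, SPACER, max_mm=4)
        profile = build_profile(SPACER, hits, on_target_site=("c", "+", 100))
        assert profile.counts_by_mismatch[0] == 0
        flagged = [h for h in profile.hits if h.is_on_target]
        assert len(flagged) == 1 and flagged[0].start == 100

    @staticmethod
    def _profile_with_counts(counts):
        hits = []
        for mm, n in counts.items():
            for i in range(n):
                positions = tuple(range(1, mm + 1))
                hits.append(
                    OffTargetHit(
                        seq_id="c", strand="+", start=1000 * mm + i * 30,
                        end=1000 * mm + i * 30 + 19, site="A" * 19, pam="AGG",
                        mismatch_count=mm, mismatch_positions=positions,
                    )
                )
        return OffTargetProfile(spacer=SPACER, hits=hits)

    def test_pass_at_inclusive_boundary(self):
        profile = self._profile_with_counts({3: 3, 4: 30})
        assert evaluate_policy(profile).passed

    def test_fail_at_two_mismatches(self):
        result = evaluate_policy(self._profile_with_counts({2: 1}))
        assert not result.passed
        assert "2 mismatch" in result.first_violation

    def test_fail_above_level3_cap_names_counts(self):
        result = evaluate_policy(self._profile_with_counts({3: 4}))
        assert not result.passed
        assert "4 > 3" in result.first_violation

    def test_caps_must_be_non_negative(self):
        with pytest.raises(ValueError):
            OffTargetPolicy(max_hits_at_mismatch={0: -1})
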