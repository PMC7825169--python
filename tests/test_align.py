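import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_align_score
from ampdiv.align import (AberrantOperonError, anchored_msa, global_align,
                          match_degenerate_primer, overlap_align,
                          pairwise_identity, partition_regions,
                          reverse_complement, sequence_identity)
from ampdiv.io import load_bundled_references

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestGlobalAlign:
    def test_identical_sequences(self):
        res = global_align("ACGT", "ACGT")
        assert (res.matches, res.mismatches, res.score) == (4, 0, 8)

    def test_single_substitution(self):
        res = global_align("ACGT", "ACGA")
        assert (res.matches, res.mismatches) == (3, 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_align("", "ACGT")

    def test_gap_strip_recovers_inputs(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 30)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 30)))
            res = global_align(a, b)
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b
            gaps = sum(1 for x, y in zip(res.aligned_a, res.aligned_b)
                       if x == "-" or y == "-")
            assert res.matches + res.mismatches + gaps == res.length

    @given(dna, dna)
    def test_score_matches_brute_force_enumeration(self, a, b):
        assert global_align(a, b).score == brute_force_align_score(a, b)

    def test_score_matches_oracle_on_battery(self, rng):
        """Dynamic program equals exhaustive enumeration on >= 500 pairs."""
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 9)))
            assert global_align(a, b).score == brute_force_align_score(a, b)


class TestIdentity:
    def test_identical_is_one(self):
        assert pairwise_identity(global_align("ACGTACGT", "ACGTACGT")) == 1.0

    def test_three_quarters(self):
        assert pairwise_identity(global_align("ACGT", "ACGA")) == 0.75

    def test_hundred_mer_with_three_substitutions(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for p in (10, 50, 90):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        assert sequence_identity(a, "".join(b)) == pytest.approx(0.97)

    @given(dna, dna)
    def test_symmetric(self, a, b):
        assert sequence_identity(a, b, cache=False) == \
            sequence_identity(b, a, cache=False)

    @given(dna)
    def test_self_identity_is_one(self, a):
        assert sequence_identity(a, a, cache=False) == 1.0

    @given(st.text(alphabet="ACGT", min_size=2, max_size=30),
           st.integers(0, 10 ** 6))
    def test_single_substitution_strictly_below_one(self, a, k):
        pos = k % len(a)
        b = a[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[a[pos]] \
            + a[pos + 1:]
        ident = sequence_identity(a, b, cache=False)
        assert ident <= (len(a) - 1) / len(a) < 1.0

    def test_terminal_gaps_excluded_from_denominator(self):
        # a flush substring (and, more generally, a perfect overlap such as
        # ACAC vs CACA) scores 1.0: terminal overhangs are not penalised
        assert sequence_identity("ACGTACGT", "GTAC") == 1.0
        assert sequence_identity("ACAC", "CACA") == 1.0


class TestPrimerMatching:
    def test_degenerate_hit_positions(self):
        # R={A,G}: "AG" at 0 matches exactly; "CG" at 2 needs one mismatch
        assert match_degenerate_primer("AGCG", "RG", 0) == [(0, 0)]
        assert match_degenerate_primer("AGCG", "RG", 1) == \
            [(0, 0), (1, 1), (2, 1)]

    def test_exact_substring_single_hit(self):
        assert match_degenerate_primer("TTACGTT", "ACGT", 0) == [(2, 0)]

    def test_primer_longer_than_sequence(self):
        assert match_degenerate_primer("ACG", "ACGTACGT", 0) == []

    def test_23s_primer_matches_synthetic_23s_start(self):
        seq = "AA" + "GGTTCCCCCATTCGG" + "AA"
        hits = match_degenerate_primer(seq, "RGTTBYCYCATTCRG", 1)
        assert hits and hits[0][0] == 2 and hits[0][1] <= 1

    def test_reverse_complement_orientation(self):
        # revcomp of ACGT-primer "AARG" is "CYTT"
        seq = "GGCCTTGG"
        assert match_degenerate_primer(seq, "CCAARG"[2:], 0,
                                       orientation="reverse-complement") == \
            match_degenerate_primer(seq, reverse_complement("AARG"), 0)


class TestAnchoredMsa:
    def test_reference_only(self):
        msa = anchored_msa("ACGT", [])
        assert msa.rows == {} and msa.insertions == {}

    def test_single_variant_column(self):
        msa = anchored_msa("ACGT", ["ACTT"], member_ids=["m"])
        diffs = [p for p in range(4) if msa.rows["m"][p] != msa.reference[p]]
        assert diffs == [2]  # reference position 3, 1-based

    def test_deletion_appears_as_gap_column(self):
        ref = "ACGTACGTACGTACGTACGT"
        member = ref[:9] + ref[10:]  # 1-bp deletion
        msa = anchored_msa(ref, [member], member_ids=["m"])
        assert msa.rows["m"].count("-") == 1

    def test_insertion_recorded_not_columned(self):
        ref = "ACGTACGTACGTACGTACGT"
        member = ref[:10] + "T" + ref[10:]
        msa = anchored_msa(ref, [member], member_ids=["m"])
        assert len(msa.rows["m"]) == len(ref)
        assert any(s == "T" for ins in msa.insertions.values()
                   for s in ins.values())

    def test_round_trip_member_reconstruction(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 60))
        member = ref[:20] + "A" + ref[20:40] + ref[41:]  # one ins, one del
        msa = anchored_msa(ref, [member], member_ids=["m"])
        rebuilt = []
        for p in range(len(ref)):
            if p in msa.insertions and "m" in msa.insertions[p]:
                rebuilt.append(msa.insertions[p]["m"])
            c = msa.rows["m"][p]
            if c != "-":
                rebuilt.append(c)
        if len(ref) in msa.insertions and "m" in msa.insertions[len(ref)]:
            rebuilt.append(msa.insertions[len(ref)]["m"])
        assert "".join(rebuilt) == member


@pytest.fixture(scope="module")
def refs():
    return load_bundled_references()


class TestPartitionRegions:
    def test_constructed_amplicon_recovered_exactly(self, refs, rng):
        ssu, lsu = refs
        spacer = "".join(rng.choice(list("ACGT"), 300))
        amp = ssu + spacer + lsu
        part = partition_regions(amp, ssu, lsu, "t")
        assert part.ssu == (0, len(ssu))
        assert part.its == (len(ssu), len(ssu) + 300)
        assert part.lsu == (len(ssu) + 300, len(amp))

    def test_internal_substitutions_do_not_move_span(self, refs, rng):
        ssu, lsu = refs
        mutated = list(ssu)
        mutated[700] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[700]]
        mutated[900] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[900]]
        amp = "".join(mutated) + "".join(rng.choice(list("ACGT"), 280)) + lsu
        part = partition_regions(amp, ssu, lsu, "t")
        assert part.ssu == (0, len(ssu))
        assert part.its == (len(ssu), len(ssu) + 280)

    def test_truncated_amplicon_rejected(self, refs):
        ssu, lsu = refs
        with pytest.raises(AberrantOperonError, match="shorter"):
            partition_regions(ssu[: int(len(ssu) * 0.7)], ssu, lsu, "t")

    def test_missing_its_flagged_aberrant(self, refs):
        ssu, lsu = refs
        with pytest.raises(AberrantOperonError, match="ITS"):
            partition_regions(ssu + lsu, ssu, lsu, "t", min_its=1)

    def test_idempotent(self, refs, rng):
        ssu, lsu = refs
        amp = ssu + "".join(rng.choice(list("ACGT"), 260)) + lsu
        p1 = partition_regions(amp, ssu, lsu, "t")
        p2 = partition_regions(amp, ssu, lsu, "t")
        assert (p1.ssu, p1.its, p1.lsu) == (p2.ssu, p2.its, p2.lsu)
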