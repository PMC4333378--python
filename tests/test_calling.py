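"""Unit and property tests for alignment, normalization, calling, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polfid import (
    EventGroup,
    InputError,
    MutantRead,
    MutationEvent,
    PairwiseAlignment,
    ReferenceTarget,
    Region,
    ScoringParams,
    align_to_reference,
    apply_events,
    call_events,
    call_read,
    group_events,
    multiplicity_of,
    normalize_indels,
)

from conftest import mutate_sequence, random_sequence, read_of
from oracle_align import all_optimal_alignments, optimal_score

dna = st.text(alphabet="ACGT", min_size=1, max_size=24)


# ---------------------------------------------------------------------------
# domain-type invariants
# ---------------------------------------------------------------------------


class TestTypes:
    def test_reference_uppercases(self):
        ref = ReferenceTarget("r", "acgt")
        assert ref.sequence == "ACGT"

    def test_reference_rejects_bad_alphabet(self):
        with pytest.raises(InputError):
            ReferenceTarget("r", "ACGU")

    def test_reference_rejects_out_of_bounds_region(self):
        with pytest.raises(InputError):
            ReferenceTarget("r", "ACGT", regions=(Region("x", 1, 5),))

    def test_reference_rejects_duplicate_region_labels(self):
        with pytest.raises(InputError):
            ReferenceTarget(
                "r", "ACGTACGT",
                regions=(Region("x", 1, 2), Region("x", 3, 4)),
            )

    def test_detectable_scalar_and_set(self):
        assert ReferenceTarget("r", "ACGT", detectable_sites=147).detectable_count == 147
        assert (
            ReferenceTarget("r", "ACGT", detectable_sites=frozenset({1, 3})).detectable_count
            == 2
        )

    def test_read_rejects_bad_alphabet(self):
        with pytest.raises(InputError):
            MutantRead("m", "ACGX")

    def test_alignment_rejects_double_gap_column(self):
        with pytest.raises(InputError):
            PairwiseAlignment("A-", "A-", 0.0)

    def test_event_invariants(self):
        with pytest.raises(InputError):
            MutationEvent("substitution", 1, "A", "A")
        with pytest.raises(InputError):
            MutationEvent("insertion", 1, "A", "C")
        with pytest.raises(InputError):
            MutationEvent("deletion", 1, "", "")
        e = MutationEvent("insertion", 0, "", "TT")
        assert e.length == 2 and e.net_length_change == 2


# ---------------------------------------------------------------------------
# align_to_reference
# ---------------------------------------------------------------------------


class TestAlign:
    def test_identity(self):
        aln = align_to_reference(ReferenceTarget("r", "ACGTACGT"), read_of("ACGTACGT"))
        assert aln.ref_row == aln.read_row == "ACGTACGT"

    def test_single_substitution_unique_optimum(self):
        aln = align_to_reference(ReferenceTarget("r", "ACGT"), read_of("AGGT"))
        assert aln.ref_row == "ACGT" and aln.read_row == "AGGT"

    def test_single_gap_score_matches_oracle(self):
        # one deletion from an 8-mer; the score must equal the exhaustive
        # DP optimum computed by an independent oracle
        ref, read = "AATTTTAA", "AATTTAA"
        aln = align_to_reference(ReferenceTarget("r", ref), read_of(read))
        assert aln.ref_row.count("-") + aln.read_row.count("-") == 1
        assert aln.score == pytest.approx(optimal_score(ref, read))

    @given(ref=dna, read=dna)
    @settings(max_examples=60, deadline=None)
    def test_score_matches_oracle_property(self, ref, read):
        aln = align_to_reference(ReferenceTarget("r", ref), read_of(read))
        assert aln.score == pytest.approx(optimal_score(ref, read))
        assert aln.reference == ref and aln.read == read

    def test_rejects_bad_scoring(self):
        with pytest.raises(InputError):
            ScoringParams(match=1, mismatch=1)
        with pytest.raises(InputError):
            ScoringParams(gap_open=1)


# ---------------------------------------------------------------------------
# normalize_indels
# ---------------------------------------------------------------------------


class TestNormalize:
    def test_no_gap_identity(self):
        aln = PairwiseAlignment("ACGT", "AGGT", -1.0)
        assert normalize_indels(aln) == aln

    def test_deletion_left_of_homopolymer(self):
        # every score-equivalent placement of the T deletion normalizes to the
        # first T of the run
        ref, read = "CATTTTAC", "CATTTAC"
        placements = all_optimal_alignments(ref, read)
        assert len(placements) > 1  # run makes the optimum degenerate
        canonical = set()
        for ref_row, read_row in placements:
            norm = normalize_indels(PairwiseAlignment(ref_row, read_row, 0.0))
            canonical.add((norm.ref_row, norm.read_row))
            events = call_events(norm)
            assert events == [MutationEvent("deletion", 3, "T", "")]
        assert len(canonical) == 1

    def test_insertion_anchored_left_of_run(self):
        ref, read = "GCAAAC", "GCAAAAC"
        for ref_row, read_row in all_optimal_alignments(ref, read):
            norm = normalize_indels(PairwiseAlignment(ref_row, read_row, 0.0))
            events = call_events(norm)
            assert events == [MutationEvent("insertion", 2, "", "A")]

    def test_insertion_before_position_one(self):
        ref, read = "AAAC", "AAAAC"
        for ref_row, read_row in all_optimal_alignments(ref, read):
            events = call_events(
                normalize_indels(PairwiseAlignment(ref_row, read_row, 0.0))
            )
            assert events == [MutationEvent("insertion", 0, "", "A")]

    @given(ref=dna, read=dna)
    @settings(max_examples=60, deadline=None)
    def test_idempotent(self, ref, read):
        aln = align_to_reference(ReferenceTarget("r", ref), read_of(read))
        once = normalize_indels(aln)
        assert normalize_indels(once) == once

    @given(ref=dna, read=dna)
    @settings(max_examples=60, deadline=None)
    def test_preserves_sequences(self, ref, read):
        aln = align_to_reference(ReferenceTarget("r", ref), read_of(read))
        norm = normalize_indels(aln)
        assert norm.reference == ref and norm.read == read


# ---------------------------------------------------------------------------
# call_events
# ---------------------------------------------------------------------------


class TestCallEvents:
    def test_identity_alignment_empty(self):
        assert call_events(PairwiseAlignment("ACGT", "ACGT", 4.0)) == []

    def test_single_substitution(self):
        events = call_events(PairwiseAlignment("ACGT", "AGGT", -1.0))
        assert events == [MutationEvent("substitution", 2, "C", "G")]

    def test_adjacent_mismatches_stay_separate(self):
        events = call_events(PairwiseAlignment("ACGT", "AGCT", -1.0))
        assert [e.kind for e in events] == ["substitution", "substitution"]
        assert [e.position for e in events] == [2, 3]
        assert all(e.length == 1 for e in events)

    def test_deletion_round_trip(self):
        ref = ReferenceTarget("r", "ACGTACGT")
        events = call_read(ref, read_of("ACGACGT"))
        assert apply_events(ref.sequence, events) == "ACGACGT"

    def test_n_columns_masked(self):
        events = call_events(PairwiseAlignment("ACGT", "ANGT", 0.0))
        assert events == []
        events = call_events(PairwiseAlignment("AC-GT", "ACNGT", 0.0))
        assert events == []

    def test_mixed_insertion_keeps_non_n(self):
        events = call_events(PairwiseAlignment("AC--GT", "ACNAGT", 0.0))
        assert events == [MutationEvent("insertion", 2, "", "A")]

    @given(
        seed=st.integers(0, 10_000),
        n_sub=st.integers(0, 3),
        n_ins=st.integers(0, 2),
        n_del=st.integers(0, 2),
    )
    @settings(max_examples=80, deadline=None)
    def test_round_trip_property(self, seed, n_sub, n_ins, n_del):
        rng = np.random.default_rng(seed)
        ref_seq = random_sequence(rng, 40)
        read_seq = mutate_sequence(rng, ref_seq, n_sub, n_ins, n_del)
        ref = ReferenceTarget("r", ref_seq)
        events = call_read(ref, read_of(read_seq))
        assert apply_events(ref_seq, events) == read_seq

    def test_determinism(self, reference64, rng):
        read_seq = mutate_sequence(rng, reference64.sequence, 2, 1, 1)
        a = call_read(reference64, read_of(read_seq))
        b = call_read(reference64, read_of(read_seq))
        assert a == b


# ---------------------------------------------------------------------------
# canonicalization vs exhaustive oracle
# ---------------------------------------------------------------------------


class TestCanonicalInvariance:
    """The event list must not depend on which co-optimal alignment was emitted."""

    @pytest.mark.parametrize("length", [4, 5, 6])
    def test_exhaustive_small_ac_alphabet(self, length):
        # exhaustive over {A,C}^length (repeat-rich) and every single-base indel
        import itertools

        for ref in map("".join, itertools.product("AC", repeat=length)):
            self._check_all_single_indels(ref)

    def test_random_longer_references(self, rng):
        for _ in range(40):
            ref = random_sequence(rng, int(rng.integers(7, 13)))
            self._check_all_single_indels(ref)

    def _check_all_single_indels(self, ref):
        reads = set()
        for i in range(len(ref)):  # single deletions
            read = ref[:i] + ref[i + 1 :]
            if read:
                reads.add(read)
        for i in range(len(ref) + 1):  # single insertions
            for b in "ACGT":
                reads.add(ref[:i] + b + ref[i:])
        for read in reads:
            expected = None
            for ref_row, read_row in all_optimal_alignments(ref, read):
                events = tuple(
                    call_events(
                        normalize_indels(PairwiseAlignment(ref_row, read_row, 0.0))
                    )
                )
                if expected is None:
                    expected = events
                else:
                    assert events == expected, (ref, read)
            # and the package's own aligner lands on the same canonical form
            got = tuple(
                call_read(ReferenceTarget("r", ref), read_of(read))
            )
            assert got == expected, (ref, read)


# ---------------------------------------------------------------------------
# group_events
# ---------------------------------------------------------------------------


def _sub(pos: int) -> MutationEvent:
    return MutationEvent("substitution", pos, "A", "C")


class TestGrouping:
    def test_five_apart_one_group(self):
        groups = group_events([_sub(10), _sub(15)])
        assert len(groups) == 1
        assert groups[0].is_complex
        assert groups[0].span == (10, 15)

    def test_fifteen_apart_two_groups(self):
        groups = group_events([_sub(10), _sub(25)])
        assert len(groups) == 2
        assert not any(g.is_complex for g in groups)

    def test_exactly_ten_apart_joins(self):
        # ">10 nucleotides apart" means 10 is NOT apart
        assert len(group_events([_sub(10), _sub(20)])) == 1
        assert len(group_events([_sub(10), _sub(21)])) == 2

    def test_empty(self):
        assert group_events([]) == []

    def test_single_linkage_chain(self):
        groups = group_events([_sub(1), _sub(9), _sub(17)])
        assert len(groups) == 1 and len(groups[0].events) == 3

    @given(
        positions=st.lists(st.integers(1, 200), min_size=0, max_size=12, unique=True),
        distance=st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_grouping_is_partition(self, positions, distance):
        events = [_sub(p) for p in sorted(positions)]
        groups = group_events(events, distance)
        flat = [e for g in groups for e in g.events]
        assert sorted(e.position for e in flat) == sorted(positions)
        # merging adjacent groups would violate the rule; splitting any group too
        for g1, g2 in zip(groups, groups[1:]):
            assert g2.events[0].start - g1.events[-1].end > distance
        for g in groups:
            for e1, e2 in zip(g.events, g.events[1:]):
                assert e2.start - e1.end <= distance

    def test_multiplicity_capped_at_three(self):
        groups = [
            group_events([_sub(1), _sub(30), _sub(60), _sub(90), _sub(120)]),
            group_events([_sub(1)]),
        ]
        assert len(groups[0]) == 5
        assert multiplicity_of(groups) == {3: 1, 1: 1}
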