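"""Sequence extraction, edit distance (with independent oracles), chunk and
pause observables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterochunk.metrics import (
    SymbolSequence,
    asymmetry_index,
    boundary_positions,
    chunk_partition,
    chunking_rate,
    extract_sequence,
    levenshtein_indel,
    normalized_distance,
    pause_durations,
    project_phase_portrait,
)


from conftest import _indel_brute_force, _indel_dp_recurrence


def _piecewise_trajectory(symbols, dwells, n_modes, dt=0.1, level=1.0):
    """Write a piecewise-constant trajectory realizing a symbol sequence."""
    t, rows = [], []
    now = 0.0
    for s, d in zip(symbols, dwells):
        n = int(round(d / dt))
        for _ in range(n):
            row = np.zeros(n_modes)
            row[s] = level
            rows.append(row)
            t.append(now)
            now += dt
    return np.array(t), np.array(rows)


class TestLevenshteinIndel:
    def test_examples(self):
        assert levenshtein_indel("abc", "abc") == 0
        assert levenshtein_indel("abcd", "abd") == 1
        assert levenshtein_indel("abc", "xyz") == 6

    def test_exhaustive_small_alphabet(self):
        """All pairs of length <= 4 over a 3-symbol alphabet against both
        independent oracles."""
        seqs = [s for r in range(5) for s in itertools.product("abc", repeat=r)]
        for a in seqs:
            for b in seqs:
                d = levenshtein_indel(a, b)
                assert d == _indel_dp_recurrence(a, b)
                assert d == _indel_brute_force(a, b)

    @given(st.lists(st.integers(0, 3), max_size=6),
           st.lists(st.integers(0, 3), max_size=6))
    @settings(max_examples=150, deadline=None)
    def test_matches_oracles_on_random_pairs(self, a, b):
        d = levenshtein_indel(a, b)
        assert d == _indel_dp_recurrence(a, b)
        assert d == _indel_brute_force(a, b)

    @given(st.lists(st.integers(0, 3), max_size=5),
           st.lists(st.integers(0, 3), max_size=5),
           st.lists(st.integers(0, 3), max_size=5))
    @settings(max_examples=120, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein_indel(a, a) == 0
        assert levenshtein_indel(a, b) == levenshtein_indel(b, a)
        assert (levenshtein_indel(a, c)
                <= levenshtein_indel(a, b) + levenshtein_indel(b, c))


class TestNormalizedDistance:
    def test_identical_sequences(self):
        assert normalized_distance(list(range(24)), list(range(24))) == 0.0

    def test_one_deletion_from_24(self):
        a = list(range(24))
        assert normalized_distance(a, a[:-1]) == pytest.approx(1 / 24)

    def test_disjoint_alphabets_exceed_one_and_clip(self):
        a, b = [0, 1, 2], [3, 4, 5]
        assert normalized_distance(a, b) == 2.0
        assert normalized_distance(a, b, clip=True) == 1.0

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError):
            normalized_distance([], [])


class TestExtractSequence:
    def test_constant_winner(self):
        t = np.arange(50) * 0.1
        x = np.zeros((50, 3))
        x[:, 1] = 1.0
        seq = extract_sequence(t, x, 0.5, 3)
        assert list(seq.symbols) == [1]

    def test_three_mode_cycle_with_dwells(self):
        t, x = _piecewise_trajectory([0, 1, 2, 0], [2.0, 3.0, 1.0, 2.0], 4)
        seq = extract_sequence(t, x, 0.5, 3)
        assert list(seq.symbols) == [0, 1, 2, 0]
        assert np.allclose(seq.dwells, [1.9, 2.9, 0.9, 1.9], atol=0.11)

    def test_roundtrip_identity_on_synthetic_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            syms = []
            last = -1
            for _ in range(rng.integers(2, 8)):
                s = int(rng.integers(0, 5))
                if s == last:
                    continue
                syms.append(s)
                last = s
            dwell = rng.uniform(1.0, 3.0, len(syms))
            t, x = _piecewise_trajectory(syms, dwell, 5)
            seq = extract_sequence(t, x, 0.5, 3)
            assert list(seq.symbols) == syms

    def test_debounce_drops_glitches(self):
        t, x = _piecewise_trajectory([0, 2, 1], [2.0, 0.1, 2.0], 3)
        seq = extract_sequence(t, x, 0.5, min_dwell=3)
        assert list(seq.symbols) == [0, 1]

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            extract_sequence(np.array([]), np.zeros((0, 2)))


class TestChunkingRate:
    def test_one_transition_per_pattern(self):
        seq = SymbolSequence(np.arange(25) % 2 + np.arange(25) * 0,
                             np.arange(25.0), np.arange(25.0) + 0.9)
        # 25 activations -> 24 transitions over 24 patterns
        assert chunking_rate(seq, 24) == 1.0

    def test_three_transitions_over_24(self):
        seq = SymbolSequence([0, 1, 2, 3], [0.0, 5, 10, 15], [4.9, 9.9, 14.9, 19.9])
        assert chunking_rate(seq, 24) == pytest.approx(3 / 24)

    def test_constant_chunk_mode(self):
        seq = SymbolSequence([2], [0.0], [10.0])
        assert chunking_rate(seq, 24) == 0.0

    def test_empty_phase_is_an_error(self):
        with pytest.raises(ValueError):
            chunking_rate(SymbolSequence([0], [0.0], [1.0]), 0)

    def test_invariant_to_sampling_stride(self):
        t, y = _piecewise_trajectory([0, 1, 0], [4.0, 4.0, 4.0], 2)
        for stride in (1, 2, 3):
            seq = extract_sequence(t[::stride], y[::stride], 0.5, 1)
            assert chunking_rate(seq, 12) == pytest.approx(2 / 12)


class TestChunkPartition:
    def test_block_structured_Q(self):
        Q = np.zeros((6, 2))
        Q[:3, 0] = 0.4
        Q[3:, 1] = 0.4
        part = chunk_partition(Q=Q)
        assert list(part["weights"]) == [0, 0, 0, 1, 1, 1]
        assert part["chunk_sizes"] == {0: 3, 1: 3}

    def test_weak_rows_unassigned(self):
        Q = np.zeros((3, 2))
        Q[0, 1] = 0.4
        part = chunk_partition(Q=Q)
        assert part["weights"][0] == 1
        assert list(part["weights"][1:]) == [-1, -1]

    def test_activity_partition_follows_cm_trajectory(self):
        em = SymbolSequence([0, 1, 2, 3], [0.0, 2, 4, 6], [1.9, 3.9, 5.9, 7.9])
        t, y = _piecewise_trajectory([0, 1], [4.0, 4.0], 2)
        part = chunk_partition(em, (t, y))
        assert list(part["activity"]) == [0, 0, 1, 1]
        assert part["chunk_sizes"] == {0: 2, 1: 2}


class TestPauses:
    def test_uniform_dwells_give_zero_pauses(self):
        em = SymbolSequence(np.arange(6), np.arange(6.0) * 2,
                            np.arange(6.0) * 2 + 2)
        out = pause_durations(em, [2, 5])
        assert np.allclose(out["pauses"], 0.0)

    def test_inflated_boundaries_recovered_exactly(self):
        onsets = np.array([0.0, 2, 4, 9, 11, 13])
        offsets = np.array([2.0, 4, 9, 11, 13, 15])  # activation 2 dwells 5
        em = SymbolSequence(np.arange(6), onsets, offsets)
        out = pause_durations(em, [2])
        assert out["within_median"] == pytest.approx(2.0)
        assert out["pauses"][0] == pytest.approx(3.0)

    def test_boundary_positions_from_cm_onsets(self):
        em = SymbolSequence([5, 6, 7], [0.0, 2, 4], [1.9, 3.9, 5.9])
        cm = SymbolSequence([0, 1], [0.0, 2.5], [2.4, 5.9])
        assert boundary_positions(em, cm) == [1]


class TestAsymmetryIndex:
    def test_symmetric_matrix_is_zero(self):
        rng = np.random.default_rng(0)
        A = rng.random((5, 5))
        S = (A + A.T) / 2
        assert asymmetry_index(S) == 0.0

    def test_single_flipped_pair_closed_form(self):
        V = np.full((3, 3), 1.0)
        V[0, 1], V[1, 0] = 0.3, 1.5
        # antisymmetric part has two entries +/-(1.5-0.3)/2
        off = V - np.diag(np.diag(V))
        expected = np.sqrt(2 * 0.6**2) / np.linalg.norm(off)
        assert asymmetry_index(V) == pytest.approx(expected)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(np.zeros((2, 3)))


class TestPhasePortrait:
    def test_direct_substitution(self):
        t = np.array([0.0])
        x = np.zeros((1, 6))
        y = np.zeros((1, 2))
        y[0, 1] = 1.0
        partition = np.array([0, 0, 0, 1, 1, 1])
        out = project_phase_portrait(t, x, y, partition)
        assert out["J"][0, 1] == pytest.approx(0.5)
        assert out["J"][0, 0] == 0.0
        assert bool(out["active"][0]) is True

    def test_all_zero_state(self):
        out = project_phase_portrait(np.array([0.0]), np.zeros((1, 4)),
                                     np.zeros((1, 2)), np.array([0, 0, 1, 1]))
        assert np.all(out["J"] == 0)
        assert not out["active"][0]
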