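"""Phase oracles: marking behavior, kickback, ancilla hygiene, duplicates."""

import itertools

import numpy as np
import pytest

from helpers import enumerate_flipped_addresses, equality_flipped_pairs
from qkmer.circuit import Circuit, Register, h, mcx, simulate_statevector, x
from qkmer.classical import match_naive
from qkmer.encoding import encode_kmer
from qkmer.oracles import (
    OracleError,
    build_enumerate_oracle,
    build_equality_oracle,
    prepare_match_minus,
)


def _bits_to_int(bits):
    v = 0
    for b in bits:
        v = (v << 1) | b
    return v


class TestMatchMinus:
    def test_minus_state(self):
        c = Circuit([Register("m", 1, "match")])
        c.extend(prepare_match_minus(0))
        state = simulate_statevector(c)
        assert np.allclose(state, [1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_fragment_then_inverse_restores_zero(self):
        c = Circuit([Register("m", 1, "match")])
        frag = prepare_match_minus(0)
        c.extend(frag)
        c.extend(reversed(frag))
        assert np.allclose(simulate_statevector(c), [1, 0])

    def test_phase_kickback(self):
        """MCX into |-> flips the sign of the satisfying control branch."""
        c = Circuit([Register("ctrl", 1), Register("m", 1, "match")])
        c.append(h(0))
        c.extend(prepare_match_minus(1))
        c.append(mcx([0], 1))
        state = simulate_statevector(c)
        # |0>|-> branch keeps +, |1>|-> branch flips
        assert state[c.basis_index({"ctrl": 0, "m": 0})].real > 0
        assert state[c.basis_index({"ctrl": 1, "m": 0})].real < 0


class TestEnumerateOracle:
    def _oracle_state(self, patterns, data_kmer):
        L = len(patterns[0])
        c = Circuit([Register("data", 2 * L, "data"), Register("m", 1, "match")])
        data = list(c.qubits("data"))
        mq = c.qubit("m", 0)
        c.extend(prepare_match_minus(mq))
        c.extend(build_enumerate_oracle(patterns, data, mq))
        init = {"data": _bits_to_int(encode_kmer(data_kmer))}
        return simulate_statevector(c, init), c, init

    def test_matching_state_phase_flipped(self):
        state, c, init = self._oracle_state(["GT"], "GT")
        amp = state[c.basis_index({**init, "m": 0})]
        assert amp.real == pytest.approx(-1 / np.sqrt(2))

    def test_non_matching_state_unchanged(self):
        state, c, init = self._oracle_state(["GT"], "AC")
        amp = state[c.basis_index({**init, "m": 0})]
        assert amp.real == pytest.approx(+1 / np.sqrt(2))

    def test_duplicates_rejected(self):
        with pytest.raises(OracleError, match="duplicate"):
            build_enumerate_oracle(["AC", "AC"], list(range(4)), 4)

    def test_all_a_pattern_needs_validity_when_padded(self):
        with pytest.raises(OracleError, match="validity"):
            build_enumerate_oracle(["AA"], list(range(4)), 4, padded=True)
        # unpadded address space: fine without a validity qubit
        assert build_enumerate_oracle(["AA"], list(range(4)), 4, padded=False)


class TestEqualityOracle:
    def _state(self, L, data_kmer, pattern_kmer):
        c = Circuit(
            [
                Register("data", 2 * L, "data"),
                Register("pdata", 2 * L, "pattern_data"),
                Register("eq", 2 * L, "equality_ancilla"),
                Register("m", 1, "match"),
            ]
        )
        mq = c.qubit("m", 0)
        c.extend(prepare_match_minus(mq))
        c.extend(
            build_equality_oracle(
                L, list(c.qubits("data")), list(c.qubits("pdata")), list(c.qubits("eq")), mq
            )
        )
        init = {
            "data": _bits_to_int(encode_kmer(data_kmer)),
            "pdata": _bits_to_int(encode_kmer(pattern_kmer)),
        }
        return simulate_statevector(c, init), c, init

    def test_equal_flips_and_restores_ancillas(self):
        state, c, init = self._state(3, "GTA", "GTA")
        amp = state[c.basis_index({**init, "eq": 0, "m": 0})]
        assert amp.real == pytest.approx(-1 / np.sqrt(2))
        # all population must sit at eq = 0
        probs = np.abs(state) ** 2
        on_clean = probs[c.basis_index({**init, "eq": 0, "m": 0})] + probs[
            c.basis_index({**init, "eq": 0, "m": 1})
        ]
        assert on_clean == pytest.approx(1.0, abs=1e-9)

    def test_unequal_no_flip(self):
        state, c, init = self._state(3, "GTA", "TAC")
        amp = state[c.basis_index({**init, "eq": 0, "m": 0})]
        assert amp.real == pytest.approx(+1 / np.sqrt(2))

    def test_smallest_case_all_equal_bits(self):
        state, c, init = self._state(1, "A", "A")  # data [0,0] vs pattern [0,0]
        amp = state[c.basis_index({**init, "m": 0})]
        assert amp.real == pytest.approx(-1 / np.sqrt(2))

    def test_wrong_ancilla_width_rejected(self):
        with pytest.raises(OracleError, match="exactly"):
            build_equality_oracle(2, list(range(4)), list(range(4, 8)), list(range(8, 11)), 11)


class TestOracleClassicalEquivalence:
    """The central check: phase-flipped addresses == classical match positions."""

    @pytest.mark.parametrize(
        "text,patterns,addressing",
        [
            ("ACGT", ("AC", "CG", "GT"), "linear"),
            ("ACGTACGT", ("GTA", "TAC"), "cyclic"),
            ("ACGTACGT", ("GTA", "TAC"), "linear"),
            ("AAAA", ("GT",), "linear"),
            ("AACA", ("AA",), "linear"),  # all-A pattern with padded addresses
            ("GATTACA", ("TA", "AT"), "linear"),
        ],
    )
    def test_enumerate_oracle_marks_match_set(self, text, patterns, addressing):
        flipped, pad_flips = enumerate_flipped_addresses(text, list(patterns), addressing)
        truth = set(match_naive(text, patterns, addressing).positions)
        assert flipped == truth
        assert pad_flips == set()

    @pytest.mark.parametrize(
        "text,patterns,addressing",
        [
            ("ACGTACGT", ("GTA", "TAC"), "cyclic"),
            ("ACGT", ("AC", "GT"), "linear"),
            ("AACAA", ("AA",), "cyclic"),  # all-A pattern + padded pattern IDs
            ("GATTACA", ("TAC",), "linear"),
        ],
    )
    def test_equality_oracle_marks_match_pairs(self, text, patterns, addressing):
        flipped, pad_flips = equality_flipped_pairs(text, list(patterns), addressing)
        truth = match_naive(text, patterns, addressing)
        expected = {
            (i, j)
            for j, p in enumerate(patterns)
            for i in truth.per_pattern[p]
        }
        assert flipped == expected
        assert pad_flips == set()

    def test_exhaustive_two_letter_alphabet(self):
        """Exhaustive soundness on the 2-letter sub-alphabet {A,C}:
        every text up to length 5, every pattern set with m <= 2, L <= 2."""
        alphabet = "AC"
        for n in range(1, 6):
            for text_t in itertools.product(alphabet, repeat=n):
                text = "".join(text_t)
                for L in (1, 2):
                    if L > n:
                        continue
                    kmers = ["".join(t) for t in itertools.product(alphabet, repeat=L)]
                    sets = [(k,) for k in kmers] + list(itertools.combinations(kmers, 2))
                    for patterns in sets:
                        flipped, pad = enumerate_flipped_addresses(text, list(patterns))
                        truth = set(match_naive(text, patterns, "linear").positions)
                        assert flipped == truth, (text, patterns)
                        assert pad == set(), (text, patterns)
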