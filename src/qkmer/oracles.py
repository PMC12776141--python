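"""Phase-marking oracles for the two matchers.

Both oracles kick a -1 phase onto matching branches through a match qubit
prepared in |-> = (|0> - |1>)/sqrt(2): any X conditioned into |-> flips the
sign of the controlling branch and leaves the match qubit itself unchanged.

* Enumerate-m oracle: the m patterns are hardcoded into the circuit.  For
  each pattern in turn, X gates conjugate the data qubits whose encoded
  pattern bit is 0, an MCX with all 2L data qubits as controls targets the
  match qubit, and the X layer is undone.  Net effect: phase -1 exactly on
  data basis states equal to an encoded pattern; the data register is
  restored.

* Equality oracle (Nested Grover): compares the data register against the
  pattern-data register bit by bit.  For each bit position, CNOTs from the
  data and pattern qubits into a dedicated ancilla compute XOR, and an X
  turns it into XNOR (ancilla = 1 iff the bits agree).  An MCX over all 2L
  XNOR ancillas targets the match qubit, then the XNOR layer is uncomputed
  so the ancillas end clean at |0...0>.

Duplicate patterns are rejected at construction: the same basis state would
be phase-flipped twice and (-1)^2 = +1 silently unmarks a true match.
"""

from __future__ import annotations

from typing import Sequence

from .circuit import Gate, cnot, h, mcx, x
from .encoding import encode_kmer, validate_dna


class OracleError(ValueError):
    """Inconsistent oracle specification."""


def prepare_match_minus(match_qubit: int) -> list[Gate]:
    """X then H: |0> -> |1> -> (|0> - |1>)/sqrt(2), enabling phase kickback."""
    return [x(match_qubit), h(match_qubit)]


def _checked_patterns(patterns: Sequence[str]) -> list[str]:
    pats = [validate_dna(p, what="pattern") for p in patterns]
    if not pats:
        raise OracleError("need at least one pattern")
    L = len(pats[0])
    if L == 0:
        raise OracleError("patterns must be non-empty")
    if any(len(p) != L for p in pats):
        raise OracleError("patterns must all have the same length")
    if len(set(pats)) != len(pats):
        dup = sorted({p for p in pats if pats.count(p) > 1})
        raise OracleError(
            f"duplicate pattern(s) {dup}: a repeated pattern flips the phase twice "
            "and cancels the mark"
        )
    return pats


def build_enumerate_oracle(
    patterns: Sequence[str],
    data_qubits: Sequence[int],
    match_qubit: int,
    valid_qubit: int | None = None,
    *,
    padded: bool = False,
) -> list[Gate]:
    """Sequential hardcoded-pattern oracle over the data register.

    *valid_qubit*, when given, is added as an extra control on the MCX of
    any all-A pattern: that pattern encodes to all-zeros, which is also what
    padded (invalid) addresses leave in the data register, so without the
    control a padded address would be falsely marked.  Set ``padded=True``
    when the address space has padding states; an all-A pattern then makes
    the validity qubit mandatory.
    """
    pats = _checked_patterns(patterns)
    L = len(pats[0])
    if len(data_qubits) != 2 * L:
        raise OracleError(f"data register must have {2 * L} qubits, got {len(data_qubits)}")
    gates: list[Gate] = []
    for pat in pats:
        ebits = encode_kmer(pat)
        conj = [data_qubits[b] for b, bit in enumerate(ebits) if bit == 0]
        controls = list(data_qubits)
        if all(b == 0 for b in ebits):
            if padded and valid_qubit is None:
                raise OracleError(
                    f"pattern {pat!r} encodes to all-zeros; a validity qubit is required "
                    "when the address space is padded (see qkmer.qram)"
                )
            if valid_qubit is not None:
                controls.append(valid_qubit)
        gates.extend(x(q) for q in conj)
        gates.append(mcx(controls, match_qubit))
        gates.extend(x(q) for q in conj)
    return gates


def build_equality_oracle(
    L: int,
    data_qubits: Sequence[int],
    pattern_qubits: Sequence[int],
    ancilla_qubits: Sequence[int],
    match_qubit: int,
    extra_controls: Sequence[int] = (),
) -> list[Gate]:
    """XNOR-ancilla equality comparison: phase -1 iff data bits == pattern bits.

    *extra_controls* (validity qubits) are appended to the MCX control list;
    they block spurious equality between padded all-zero loads and genuine
    all-zero encodings."""
    if L < 1:
        raise OracleError("L must be >= 1")
    if len(data_qubits) != 2 * L or len(pattern_qubits) != 2 * L:
        raise OracleError(f"data and pattern registers must each have {2 * L} qubits")
    if len(ancilla_qubits) != 2 * L:
        raise OracleError(
            f"equality ancilla register must have exactly {2 * L} qubits, "
            f"got {len(ancilla_qubits)}"
        )
    xnor: list[Gate] = []
    for k in range(2 * L):
        xnor.append(cnot(data_qubits[k], ancilla_qubits[k]))
        xnor.append(cnot(pattern_qubits[k], ancilla_qubits[k]))
        xnor.append(x(ancilla_qubits[k]))
    gates = list(xnor)
    gates.append(mcx(list(ancilla_qubits) + list(extra_controls), match_qubit))
    gates.extend(reversed(xnor))  # uncompute: ancillas end at |0...0>
    return gates
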