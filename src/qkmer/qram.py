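"""Ideal-QRAM load/unload circuits realized as explicit address multiplexers.

A QRAM query maps sum_i a_i |i>|0...0>  ->  sum_i a_i |i>|d_i>, where d_i is
the 2L-bit encoding of the length-L window of the text starting at position
i.  Here that unitary is built literally, one address-conditioned block per
valid address: X-conjugate the address qubits that are 0 in the address's
bit pattern, then MCX from all address qubits onto every data qubit whose
encoded window bit is 1, then undo the conjugation.  The per-query gate cost
is therefore O(S*L) MCX gates — the explicit-circuit price of the ideal-QRAM
abstraction, which is exactly what the resource accounting in
:mod:`qkmer.resources` counts.  Unloading is the gate-reversed load, so
load -> (phase-only oracle) -> unload leaves the data register clean.

Addressing is either *linear* (S = n-L+1 windows, no wraparound) or *cyclic*
(S = n windows, the text treated as circular so every position starts a
window).  The address register has ceil(log2 S) qubits (minimum 1); basis
states >= S are padding and deliberately load nothing, leaving the data
register all-zero.  Because all-zero is also the valid encoding of "AA...A",
the oracles add a validity control in the rare configurations where that
could produce a false match; the load can mark a validity qubit per valid
address for that purpose (``valid_qubit``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .circuit import Gate, mcx, x
from .encoding import encode_kmer, validate_dna

ADDRESSING_MODES = ("linear", "cyclic")


class QramError(ValueError):
    """Inconsistent text/window/addressing specification."""


def _address_width(S: int) -> int:
    return max(1, math.ceil(math.log2(S))) if S > 1 else 1


@dataclass(frozen=True)
class QramSpec:
    """Text memory layout: which window each address holds."""

    text: str
    L: int
    addressing: str = "linear"
    _norm_text: str = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_norm_text", validate_dna(self.text, what="text"))
        if self.addressing not in ADDRESSING_MODES:
            raise QramError(f"addressing must be one of {ADDRESSING_MODES}")
        if self.L < 1:
            raise QramError("window length L must be >= 1")
        if self.L > len(self.text):
            raise QramError(f"window length L={self.L} exceeds text length {len(self.text)}")

    @property
    def n(self) -> int:
        return len(self._norm_text)

    @property
    def S(self) -> int:
        """Number of valid addresses: n-L+1 (linear) or n (cyclic)."""
        return self.n - self.L + 1 if self.addressing == "linear" else self.n

    @property
    def address_width(self) -> int:
        return _address_width(self.S)

    @property
    def padded(self) -> bool:
        """True when the address register has basis states beyond S."""
        return (1 << self.address_width) > self.S


def substring_at(spec: QramSpec, i: int) -> str:
    """The length-L window stored at address *i*."""
    if not 0 <= i < spec.S:
        raise QramError(f"address {i} out of range [0, {spec.S})")
    t = spec._norm_text
    if spec.addressing == "linear":
        return t[i : i + spec.L]
    return "".join(t[(i + j) % spec.n] for j in range(spec.L))


def _address_block(
    address_bits: Sequence[int],
    address_qubits: Sequence[int],
    set_targets: Sequence[int],
) -> list[Gate]:
    """Gates that, conditioned on the address register holding exactly
    *address_bits*, flip every qubit in *set_targets*."""
    gates: list[Gate] = []
    conj = [address_qubits[k] for k, b in enumerate(address_bits) if b == 0]
    gates.extend(x(q) for q in conj)
    gates.extend(mcx(list(address_qubits), t) for t in set_targets)
    gates.extend(x(q) for q in conj)
    return gates


def _int_bits(v: int, width: int) -> list[int]:
    return [(v >> (width - 1 - k)) & 1 for k in range(width)]


def build_load(
    spec: QramSpec,
    address_qubits: Sequence[int],
    data_qubits: Sequence[int],
    valid_qubit: int | None = None,
) -> list[Gate]:
    """The QRAM load fragment: |i>|0..0> -> |i>|encode(window_i)> for i < S.

    Padding addresses (i >= S) are untouched and keep all-zero data.  When
    *valid_qubit* is given, each valid address additionally flips it, so the
    oracles can distinguish genuine windows from padding.
    """
    aw = spec.address_width
    if len(address_qubits) != aw:
        raise QramError(f"address register must have {aw} qubits, got {len(address_qubits)}")
    if len(data_qubits) != 2 * spec.L:
        raise QramError(f"data register must have {2 * spec.L} qubits, got {len(data_qubits)}")
    gates: list[Gate] = []
    for i in range(spec.S):
        ebits = encode_kmer(substring_at(spec, i))
        targets = [data_qubits[b] for b, bit in enumerate(ebits) if bit == 1]
        if valid_qubit is not None:
            targets.append(valid_qubit)
        gates.extend(_address_block(_int_bits(i, aw), address_qubits, targets))
    return gates


def build_unload(
    spec: QramSpec,
    address_qubits: Sequence[int],
    data_qubits: Sequence[int],
    valid_qubit: int | None = None,
) -> list[Gate]:
    """Exact gate-reversed :func:`build_load`; load then unload is identity."""
    return list(reversed(build_load(spec, address_qubits, data_qubits, valid_qubit)))


def build_pattern_load(
    patterns: Sequence[str],
    id_qubits: Sequence[int],
    data_qubits: Sequence[int],
    valid_qubit: int | None = None,
) -> list[Gate]:
    """Pattern-dictionary QRAM: |j>|0..0> -> |j>|encode(pattern_j)> for j < m.

    Pattern IDs >= m (padding of the ceil(log2 m) register) load all-zeros,
    mirroring the text QRAM's padding behavior."""
    pats = [validate_dna(p, what="pattern") for p in patterns]
    if not pats:
        raise QramError("need at least one pattern")
    L = len(pats[0])
    if L == 0:
        raise QramError("patterns must be non-empty")
    if any(len(p) != L for p in pats):
        raise QramError("patterns must all have the same length")
    m = len(pats)
    pw = _address_width(m)
    if len(id_qubits) != pw:
        raise QramError(f"pattern-ID register must have {pw} qubits, got {len(id_qubits)}")
    if len(data_qubits) != 2 * L:
        raise QramError(f"pattern-data register must have {2 * L} qubits, got {len(data_qubits)}")
    gates: list[Gate] = []
    for j, pat in enumerate(pats):
        ebits = encode_kmer(pat)
        targets = [data_qubits[b] for b, bit in enumerate(ebits) if bit == 1]
        if valid_qubit is not None:
            targets.append(valid_qubit)
        gates.extend(_address_block(_int_bits(j, pw), id_qubits, targets))
    return gates


def build_pattern_unload(
    patterns: Sequence[str],
    id_qubits: Sequence[int],
    data_qubits: Sequence[int],
    valid_qubit: int | None = None,
) -> list[Gate]:
    return list(reversed(build_pattern_load(patterns, id_qubits, data_qubits, valid_qubit)))


def pattern_id_width(m: int) -> int:
    """Width of the pattern-ID register for m patterns (minimum 1)."""
    if m < 1:
        raise QramError("need at least one pattern")
    return _address_width(m)
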