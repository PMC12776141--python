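"""Two-bit binary encoding of DNA for loading into qubit registers.

Each nucleotide occupies two bits, high bit first: A=(0,0), C=(0,1),
G=(1,0), T=(1,1).  A k-mer of length L therefore occupies exactly 2L bits
(and, downstream, 2L qubits): bit 2j is the high bit of base j and bit 2j+1
its low bit, bases concatenated left-to-right in sequence order.  The same
most-significant-bit-first convention is used everywhere a register is read
back as an integer, so one endianness rule covers the whole package.

Only the four canonical bases are encodable; ambiguity codes (N, IUPAC
degenerate symbols) and gaps are rejected because the two-bit code has no
free slot for them.  Input is case-insensitive.
"""

from __future__ import annotations

BASE_TO_BITS: dict[str, tuple[int, int]] = {
    "A": (0, 0),
    "C": (0, 1),
    "G": (1, 0),
    "T": (1, 1),
}

BITS_TO_BASE: dict[tuple[int, int], str] = {v: k for k, v in BASE_TO_BITS.items()}

ALPHABET = "ACGT"


class EncodingError(ValueError):
    """A symbol outside {A, C, G, T} or a malformed bit vector."""


def encode_base(base: str, position: int | None = None) -> tuple[int, int]:
    """Return the two-bit code of a single nucleotide.

    Parameters
    ----------
    base
        One character; lower case accepted.
    position
        Optional 1-based position used in the error message when the symbol
        is not encodable (callers validating whole sequences pass it).
    """
    if not isinstance(base, str) or len(base) != 1:
        raise EncodingError(f"expected a single character, got {base!r}")
    up = base.upper()
    try:
        return BASE_TO_BITS[up]
    except KeyError:
        where = f" at position {position}" if position is not None else ""
        raise EncodingError(
            f"symbol {base!r}{where} is not in the DNA alphabet A/C/G/T "
            "(ambiguity codes and gaps cannot be two-bit encoded)"
        ) from None


def encode_kmer(seq: str) -> tuple[int, ...]:
    """Encode a DNA string into its 2L-bit vector (high bit of each base first)."""
    if not seq:
        raise EncodingError("cannot encode an empty sequence")
    bits: list[int] = []
    for pos, base in enumerate(seq, start=1):
        bits.extend(encode_base(base, position=pos))
    return tuple(bits)


def decode_bits(bits) -> str:
    """Inverse of :func:`encode_kmer`; requires an even-length 0/1 vector."""
    bits = tuple(int(b) for b in bits)
    if len(bits) % 2 != 0:
        raise EncodingError(f"bit vector length {len(bits)} is odd; bases use two bits each")
    if any(b not in (0, 1) for b in bits):
        raise EncodingError("bit vector entries must be 0 or 1")
    return "".join(BITS_TO_BASE[(bits[i], bits[i + 1])] for i in range(0, len(bits), 2))


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase *seq* and raise :class:`EncodingError` naming the first bad position."""
    up = seq.upper()
    for pos, base in enumerate(up, start=1):
        if base not in BASE_TO_BITS:
            raise EncodingError(
                f"{what} contains non-ACGT symbol {seq[pos - 1]!r} at position {pos}"
            )
    return up
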