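"""File formats and fixture generation: the workbench's user surface.

Texts arrive as FASTA (parsed with Biopython) or raw one-line strings;
pattern dictionaries as plain text (one k-mer per line) or FASTA.  All
sequence input is case-folded and validated against the strict A/C/G/T
alphabet with 1-based position diagnostics.  The fixture generator plants
pattern occurrences into a random background so that planted positions are
true matches by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .classical import match_naive
from .encoding import EncodingError, validate_dna


class IOFormatError(ValueError):
    pass


def _validate_record(seq: str, label: str) -> str:
    try:
        return validate_dna(seq, what=label)
    except EncodingError as e:
        raise IOFormatError(str(e)) from None


def read_fasta(path: str | Path) -> list[str]:
    """All record sequences from a FASTA file, uppercased and validated."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IOFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise IOFormatError(f"{path}: record {rec.id!r} is empty")
        out.append(_validate_record(seq, f"record {rec.id!r}"))
    return out


def read_text(path: str | Path) -> str:
    """A single DNA text: FASTA (records concatenated) or a raw string file."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    head = path.read_text()
    if head.lstrip().startswith(">"):
        return "".join(read_fasta(path))
    raw = "".join(head.split())
    if not raw:
        raise IOFormatError(f"{path}: empty text")
    return _validate_record(raw, "text")


def read_patterns(path: str | Path) -> list[str]:
    """Equal-length, duplicate-free pattern list from plain text or FASTA."""
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    content = path.read_text()
    if content.lstrip().startswith(">"):
        pats = read_fasta(path)
    else:
        pats = [
            _validate_record(line.strip(), f"pattern on line {i}")
            for i, line in enumerate(content.splitlines(), start=1)
            if line.strip()
        ]
    if not pats:
        raise IOFormatError(f"{path}: no patterns found")
    L = len(pats[0])
    for p in pats:
        if len(p) != L:
            raise IOFormatError(
                f"{path}: mixed pattern lengths ({L} and {len(p)}); "
                "the registers require a single fixed L"
            )
    seen = set()
    for p in pats:
        if p in seen:
            raise IOFormatError(f"{path}: duplicate pattern {p!r} (double phase marks cancel)")
        seen.add(p)
    return pats


def write_fasta(path: str | Path, seq: str, name: str = "seq") -> None:
    Path(path).write_text(f">{name}\n{seq}\n")


def write_patterns(path: str | Path, patterns: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in patterns))


@dataclass(frozen=True)
class Fixture:
    """A random text with recorded planted pattern occurrences.

    Planted positions are true matches by construction; the random
    background may contain additional chance matches, which the fixture
    does not record."""

    text: str
    patterns: tuple[str, ...]
    planted: tuple[tuple[int, str], ...]  # (position, pattern)
    seed: int


_BASES = np.array(list("ACGT"))


def generate_fixture(n: int, m: int, L: int, planted: int, seed: int) -> Fixture:
    """Random length-n text with *planted* non-overlapping occurrences of m
    random distinct length-L patterns (cycled over), reproducible by seed."""
    if L < 1 or n < L:
        raise IOFormatError("need 1 <= L <= n")
    if m < 1 or m > 4**L:
        raise IOFormatError(f"cannot draw {m} distinct patterns of length {L}")
    if planted * L > n:
        raise IOFormatError(f"cannot pack {planted} non-overlapping length-{L} plants into n={n}")
    rng = np.random.default_rng(seed)
    pats: list[str] = []
    while len(pats) < m:
        p = "".join(rng.choice(_BASES, size=L))
        if p not in pats:
            pats.append(p)
    text = rng.choice(_BASES, size=n)
    placements: list[tuple[int, str]] = []
    occupied: set[int] = set()
    attempts = 0
    while len(placements) < planted:
        attempts += 1
        if attempts > 1000 * max(1, planted):
            raise IOFormatError("could not place all plants without overlap; lower `planted`")
        pos = int(rng.integers(0, n - L + 1))
        span = set(range(pos, pos + L))
        if span & occupied:
            continue
        pat = pats[len(placements) % m]
        text[pos : pos + L] = list(pat)
        occupied |= span
        placements.append((pos, pat))
    fixture = Fixture(
        text="".join(text),
        patterns=tuple(pats),
        planted=tuple(sorted(placements)),
        seed=seed,
    )
    # self-check: every planted position must be a classical match
    truth = match_naive(fixture.text, fixture.patterns, "linear")
    assert all(pos in truth.per_pattern[pat] for pos, pat in fixture.planted)
    return fixture
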