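"""Grover diffusion operator and iteration-count schedules.

The diffuser is the inversion-about-average operator on one register,
realized with the standard circuit H^w, X^w, (H on the last qubit, MCX from
the other w-1 qubits, H), X^w, H^w, which implements I - 2|s><s| — the
textbook 2|s><s| - I up to a global phase, with |s> the uniform state of
the register.  The multi-controlled Z is the H.MCX.H sandwich, staying
inside the package's H/X/CNOT/MCX gate set.  Width 1 degenerates: on a
single qubit 2|s><s| - I is exactly the X gate, which is what we emit.

Iteration schedules
-------------------
outer_iterations(S) = max(1, floor((pi/4) * sqrt(S))) over the S valid text
positions.  This is the standard Grover count for an unknown (assumed small)
number of marked positions; with unknown k the optimal (pi/4)sqrt(N/k) is
unavailable.  It is a declared convention — overridable per run — and gives
R = 1 for the bundled 4-base demonstration.

inner_iterations(m) = ceil(pi * sqrt(m) / 4) over the m patterns, i.e. the
near-optimal count for the single matching pattern among m.  Both schedules
are floors/ceilings of smooth functions and are clamped to >= 1.  See
docs/methods.md for why small-m demonstrations may pin these explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .circuit import Gate, h, mcx, x


@dataclass(frozen=True)
class IterationSchedule:
    """Outer (text-position) and inner (pattern-space) Grover repetition counts."""

    outer_R: int
    inner_r: int = 1

    def __post_init__(self) -> None:
        if self.outer_R < 1 or self.inner_r < 1:
            raise ValueError("iteration counts must be >= 1")


def build_diffuser(qubits: Sequence[int]) -> list[Gate]:
    """Inversion about the uniform state of the given qubits (global phase aside)."""
    qs = list(qubits)
    w = len(qs)
    if w < 1:
        raise ValueError("diffuser needs at least one qubit")
    if w == 1:
        return [x(qs[0])]  # 2|s><s| - I on one qubit is exactly X
    gates: list[Gate] = []
    gates.extend(h(q) for q in qs)
    gates.extend(x(q) for q in qs)
    gates.append(h(qs[-1]))
    gates.append(mcx(qs[:-1], qs[-1]))
    gates.append(h(qs[-1]))
    gates.extend(x(q) for q in qs)
    gates.extend(h(q) for q in qs)
    return gates


def outer_iterations(S: int) -> int:
    """Outer Grover repetitions for S valid text positions."""
    if S < 1:
        raise ValueError("S must be >= 1")
    return max(1, math.floor((math.pi / 4.0) * math.sqrt(S)))


def inner_iterations(m: int) -> int:
    """Inner Grover repetitions for m patterns: ceil(pi*sqrt(m)/4)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return max(1, math.ceil(math.pi * math.sqrt(m) / 4.0))
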