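"""Closed-form qubit and gate accounting, plus the quantum/classical crossover.

The accounting follows the explicit-multiplexer QRAM realization: loading S
windows of L bases costs S*L multi-controlled-X blocks counted per
(position, base) — each base spans 2 data qubits, so the finer per-qubit
count 2*S*L is reported alongside.  Qubit totals are register sums plus a
fixed overhead of 3 ancillas (phase inversion, match indication,
intermediate computation); MCX decomposition ancillas depend on the
compilation strategy and are out of scope here, as is depth modeling.

Gate-complexity crossover: Enumerate-m costs O(sqrt(n) * L * m) total,
Nested Grover O(sqrt(n) * L * sqrt(m)); against the classical linear bound
O(n) a theoretical advantage requires sqrt(n) * L * sqrt(m) < n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

VARIANTS = ("enumerate_m", "nested_grover")

#: Fixed ancilla overhead in the qubit totals: phase inversion + match
#: indication + intermediate computation.
OVERHEAD_ANCILLAS = 3


class EstimateError(ValueError):
    pass


def _index_width(S: int) -> int:
    return max(1, math.ceil(math.log2(S))) if S > 1 else 1


@dataclass(frozen=True)
class ResourceEstimate:
    variant: str
    n: int
    m: int
    L: int
    S: int
    index_qubits: int
    data_qubits: int
    pattern_id_qubits: int
    pattern_data_qubits: int
    equality_ancillas: int
    overhead_ancillas: int
    total_qubits: int
    mcx_load: int
    mcx_load_per_qubit: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def table(self) -> str:
        rows = [
            ("variant", self.variant),
            ("text length n", self.n),
            ("patterns m", self.m),
            ("pattern length L", self.L),
            ("positions S", self.S),
            ("index qubits", self.index_qubits),
            ("data qubits (2L)", self.data_qubits),
        ]
        if self.variant == "nested_grover":
            rows += [
                ("pattern-ID qubits", self.pattern_id_qubits),
                ("pattern-data qubits (2L)", self.pattern_data_qubits),
                ("equality ancillas (2L)", self.equality_ancillas),
            ]
        rows += [
            ("overhead ancillas", self.overhead_ancillas),
            ("total qubits", self.total_qubits),
            ("load MCX blocks (S*L)", self.mcx_load),
            ("load MCX per data qubit (2*S*L)", self.mcx_load_per_qubit),
        ]
        width = max(len(str(k)) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def estimate(
    n: int, m: int, L: int, variant: str = "enumerate_m", addressing: str = "linear"
) -> ResourceEstimate:
    """Qubit/gate accounting for a search instance of the given shape."""
    if variant not in VARIANTS:
        raise EstimateError(f"variant must be one of {VARIANTS}")
    if L < 1:
        raise EstimateError("L must be >= 1")
    if L > n:
        raise EstimateError(f"pattern length L={L} exceeds text length n={n}")
    if m < 1:
        raise EstimateError("m must be >= 1")
    S = n - L + 1 if addressing == "linear" else n
    index = _index_width(S)
    data = 2 * L
    if variant == "enumerate_m":
        pid = pdata = eq = 0
    else:
        pid = _index_width(m)
        pdata = 2 * L
        eq = 2 * L
    total = index + data + pid + pdata + eq + OVERHEAD_ANCILLAS
    return ResourceEstimate(
        variant=variant,
        n=n,
        m=m,
        L=L,
        S=S,
        index_qubits=index,
        data_qubits=data,
        pattern_id_qubits=pid,
        pattern_data_qubits=pdata,
        equality_ancillas=eq,
        overhead_ancillas=OVERHEAD_ANCILLAS,
        total_qubits=total,
        mcx_load=S * L,
        mcx_load_per_qubit=2 * S * L,
    )


@dataclass(frozen=True)
class CrossoverReport:
    n: int
    m: int
    L: int
    enumerate_cost: float  # sqrt(n) * L * m
    nested_cost: float  # sqrt(n) * L * sqrt(m)
    classical_cost: float  # n
    advantage: bool  # nested_cost < classical_cost
    enumerate_complexity: str = "O(sqrt(n) * L * m)"
    nested_complexity: str = "O(sqrt(n) * L * sqrt(m))"
    classical_complexity: str = "O(n + m)"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def crossover(n: int, m: int, L: int) -> CrossoverReport:
    """Evaluate the advantage condition sqrt(n) * L * sqrt(m) < n."""
    if n < 1 or m < 1 or L < 1:
        raise EstimateError("n, m and L must all be positive")
    sqrt_n = math.sqrt(n)
    nested = sqrt_n * L * math.sqrt(m)
    enum = sqrt_n * L * m
    return CrossoverReport(
        n=n,
        m=m,
        L=L,
        enumerate_cost=enum,
        nested_cost=nested,
        classical_cost=float(n),
        advantage=nested < n,
    )
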