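"""Minimal gate-level circuit representation and exact statevector execution.

The gate set is the one the algorithms need and nothing more: H, X, CNOT and
MCX (multi-controlled X).  All four are self-inverse, so reversing an op list
inverts any fragment emitted by the builder modules — the property that makes
compute–oracle–uncompute QRAM discipline trivial to implement and to test.

Conventions
-----------
* Qubits are numbered globally, register after register in declaration order.
* Qubit 0 is the most significant bit of the overall basis-state index, and
  within each register the first qubit is the most significant bit of that
  register's integer value.  This matches the most-significant-first bit
  order of :mod:`qkmer.encoding`, so one endianness rule covers encoded
  k-mers, addresses and measured bitstrings alike.
* MCX is executed natively as a single unitary; decomposition into Toffoli
  ladders is a resource-accounting concern (:mod:`qkmer.resources`), not a
  simulation concern.
* Simulation is exact statevector evolution (no noise model).  A qubit cap
  (default 24) keeps runs desk-sized; exceeding it raises
  :class:`ResourceLimitError` rather than thrashing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

GATE_KINDS = ("H", "X", "CNOT", "MCX")

REGISTER_ROLES = (
    "address",
    "data",
    "pattern_id",
    "pattern_data",
    "equality_ancilla",
    "match",
    "work_ancilla",
)

DEFAULT_QUBIT_CAP = 24

_INV_SQRT2 = 1.0 / np.sqrt(2.0)


class CircuitError(ValueError):
    """Malformed register, gate or basis-state specification."""


class ResourceLimitError(RuntimeError):
    """Requested simulation exceeds the configured qubit cap."""


@dataclass(frozen=True)
class Register:
    """A named block of qubits with a semantic role."""

    name: str
    width: int
    role: str = "work_ancilla"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise CircuitError(f"register {self.name!r} must have width >= 1")
        if self.role not in REGISTER_ROLES:
            raise CircuitError(f"unknown register role {self.role!r}")


@dataclass(frozen=True)
class Gate:
    """One gate application: kind, control qubits (ordered) and one target."""

    kind: str
    controls: tuple[int, ...]
    targets: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise CircuitError(f"unknown gate kind {self.kind!r}")
        if len(self.targets) != 1:
            raise CircuitError("gates in this set have exactly one target")
        if self.kind == "H" or self.kind == "X":
            if self.controls:
                raise CircuitError(f"{self.kind} takes no controls")
        elif self.kind == "CNOT":
            if len(self.controls) != 1:
                raise CircuitError("CNOT takes exactly one control")
        elif self.kind == "MCX":
            if len(self.controls) < 1:
                raise CircuitError("MCX needs at least one control")
        if len(set(self.controls)) != len(self.controls):
            raise CircuitError("duplicate control qubits")
        if set(self.controls) & set(self.targets):
            raise CircuitError("control and target qubits must be disjoint")


def h(q: int) -> Gate:
    return Gate("H", (), (q,))


def x(q: int) -> Gate:
    return Gate("X", (), (q,))


def cnot(control: int, target: int) -> Gate:
    return Gate("CNOT", (control,), (target,))


def mcx(controls: Sequence[int], target: int) -> Gate:
    return Gate("MCX", tuple(controls), (target,))


def inverse_fragment(gates: Sequence[Gate]) -> list[Gate]:
    """Exact inverse of a fragment: every gate in the set is self-inverse."""
    return list(reversed(gates))


@dataclass
class Circuit:
    """An ordered gate list over named registers, plus an optional final
    measured register (measurement is realized by sampling the statevector,
    so it is metadata here, always at the end of the circuit)."""

    registers: tuple[Register, ...]
    ops: list[Gate] = field(default_factory=list)
    measured_register: str | None = None

    def __init__(self, registers: Iterable[Register]):
        regs = tuple(registers)
        names = [r.name for r in regs]
        if len(set(names)) != len(names):
            raise CircuitError("register names must be unique")
        self.registers = regs
        self.ops = []
        self.measured_register = None
        self._offsets: dict[str, int] = {}
        off = 0
        for r in regs:
            self._offsets[r.name] = off
            off += r.width
        self._width = off

    @property
    def width(self) -> int:
        return self._width

    def register(self, name: str) -> Register:
        for r in self.registers:
            if r.name == name:
                return r
        raise CircuitError(f"no register named {name!r}")

    def qubits(self, name: str) -> range:
        r = self.register(name)
        off = self._offsets[name]
        return range(off, off + r.width)

    def qubit(self, name: str, i: int) -> int:
        r = self.register(name)
        if not 0 <= i < r.width:
            raise CircuitError(f"qubit index {i} out of range for register {name!r}")
        return self._offsets[name] + i

    def append(self, gate: Gate) -> "Circuit":
        if self.measured_register is not None:
            raise CircuitError("cannot append gates after measurement")
        for q in gate.controls + gate.targets:
            if not 0 <= q < self._width:
                raise CircuitError(f"qubit index {q} outside circuit of width {self._width}")
        self.ops.append(gate)
        return self

    def extend(self, gates: Iterable[Gate]) -> "Circuit":
        for g in gates:
            self.append(g)
        return self

    def measure(self, register_name: str) -> "Circuit":
        self.register(register_name)  # existence check
        self.measured_register = register_name
        return self

    def census(self) -> dict[str, int | dict[int, int]]:
        """Gate counts by kind; MCX additionally bucketed by control count."""
        counts: dict[str, int] = {}
        buckets: dict[int, int] = {}
        for g in self.ops:
            counts[g.kind] = counts.get(g.kind, 0) + 1
            if g.kind == "MCX":
                nc = len(g.controls)
                buckets[nc] = buckets.get(nc, 0) + 1
        out: dict[str, int | dict[int, int]] = dict(counts)
        if buckets:
            out["MCX_by_controls"] = buckets
        return out

    def basis_index(self, values: Mapping[str, int] | None = None) -> int:
        """Index of the basis state with each register at the given integer
        value (unspecified registers at 0)."""
        values = dict(values or {})
        idx = 0
        for r in self.registers:
            v = int(values.pop(r.name, 0))
            if not 0 <= v < 2**r.width:
                raise CircuitError(f"value {v} out of range for register {r.name!r}")
            idx = (idx << r.width) | v
        if values:
            raise CircuitError(f"unknown registers in basis spec: {sorted(values)}")
        return idx


def census_of(gates: Sequence[Gate]) -> dict[str, int | dict[int, int]]:
    """Gate census of a bare fragment (no register context needed)."""
    tmp = Circuit([Register("q", max((max(g.controls + g.targets) for g in gates), default=0) + 1)])
    for g in gates:
        tmp.append(g)
    return tmp.census()


def _apply_gate(psi_t: np.ndarray, gate: Gate) -> None:
    """Apply *gate* in place to a statevector reshaped to (2,)*N (axis g =
    qubit g; axis index 0/1 = qubit value)."""
    if gate.kind == "H":
        a = np.moveaxis(psi_t, gate.targets[0], 0)
        a0 = a[0].copy()
        a1 = a[1].copy()
        a[0] = (a0 + a1) * _INV_SQRT2
        a[1] = (a0 - a1) * _INV_SQRT2
        return
    if gate.kind == "X":
        a = np.moveaxis(psi_t, gate.targets[0], 0)
        tmp = a[0].copy()
        a[0] = a[1]
        a[1] = tmp
        return
    # CNOT / MCX: flip the target axis on the all-controls-1 slice.
    idx: list = [slice(None)] * psi_t.ndim
    for c in gate.controls:
        idx[c] = 1
    sub = psi_t[tuple(idx)]
    t_axis = gate.targets[0] - sum(1 for c in gate.controls if c < gate.targets[0])
    a = np.moveaxis(sub, t_axis, 0)
    tmp = a[0].copy()
    a[0] = a[1]
    a[1] = tmp


def simulate_statevector(
    circ: Circuit,
    initial: int | Mapping[str, int] | np.ndarray | None = None,
    *,
    qubit_cap: int = DEFAULT_QUBIT_CAP,
) -> np.ndarray:
    """Exact unitary evolution of *circ* from *initial*.

    *initial* may be a basis-state index, a ``{register: value}`` mapping, a
    full amplitude vector, or None (all-zeros).  Returns a unit-norm complex
    vector of length ``2**circ.width``.
    """
    n = circ.width
    if n > qubit_cap:
        raise ResourceLimitError(
            f"circuit needs {n} qubits but the simulator cap is {qubit_cap}; "
            "raise qubit_cap explicitly if you really want this"
        )
    dim = 1 << n
    if initial is None:
        psi = np.zeros(dim, dtype=np.complex128)
        psi[0] = 1.0
    elif isinstance(initial, (int, np.integer)):
        if not 0 <= int(initial) < dim:
            raise CircuitError(f"basis index {initial} out of range")
        psi = np.zeros(dim, dtype=np.complex128)
        psi[int(initial)] = 1.0
    elif isinstance(initial, Mapping):
        psi = np.zeros(dim, dtype=np.complex128)
        psi[circ.basis_index(initial)] = 1.0
    else:
        psi = np.asarray(initial, dtype=np.complex128).copy()
        if psi.shape != (dim,):
            raise CircuitError(f"initial vector must have length {dim}")
        nrm = np.linalg.norm(psi)
        if abs(nrm - 1.0) > 1e-9:
            raise CircuitError(f"initial vector is not normalized (|psi| = {nrm})")
    psi_t = psi.reshape((2,) * n)
    for g in circ.ops:
        _apply_gate(psi_t, g)
    return psi


def marginal_probabilities(state: np.ndarray, circ: Circuit, register_name: str) -> np.ndarray:
    """Measurement distribution of one register, other registers traced out.

    Entry k is the probability of reading integer k from the register (first
    register qubit = most significant bit)."""
    n = circ.width
    p = np.abs(state.reshape((2,) * n)) ** 2
    keep = set(circ.qubits(register_name))
    other = tuple(ax for ax in range(n) if ax not in keep)
    m = p.sum(axis=other) if other else p
    return m.reshape(-1)


@dataclass
class MeasurementHistogram:
    """Sampled measurement outcomes of one register: integer value -> count."""

    counts: dict[int, int]
    shots: int
    register: str = ""

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.shots:
            raise CircuitError(f"counts sum to {total}, expected {self.shots} shots")

    def top(self, k: int) -> list[int]:
        """The k most frequent outcomes (ties broken by smaller value)."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [v for v, _ in ranked[:k]]

    def to_json_dict(self) -> dict:
        return {
            "shots": self.shots,
            "register": self.register,
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MeasurementHistogram":
        return cls(
            counts={int(k): int(v) for k, v in d["counts"].items()},
            shots=int(d["shots"]),
            register=d.get("register", ""),
        )


def sample_counts(
    state: np.ndarray,
    circ: Circuit,
    register_name: str,
    shots: int,
    seed: int,
) -> MeasurementHistogram:
    """Sample *shots* measurements of one register from the exact marginal.

    Deterministic for a fixed (state, seed) pair."""
    if shots < 1:
        raise CircuitError("shots must be >= 1")
    p = marginal_probabilities(state, circ, register_name)
    p = p / p.sum()  # guard rounding drift at the 1e-16 level
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, p)
    counts = {int(k): int(c) for k, c in enumerate(draws) if c > 0}
    return MeasurementHistogram(counts=counts, shots=shots, register=register_name)
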