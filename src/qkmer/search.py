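"""End-to-end assembly of the two quantum matchers.

Enumerate-m circuit
    H on the address register; match qubit to |->;
    R x [QRAM load; hardcoded multi-pattern oracle; QRAM unload;
         diffuser over the address register];
    measure the address register.

Nested Grover circuit
    H on address and pattern-ID registers; match qubit to |->;
    R x [text QRAM load;
         r x [pattern QRAM load; equality oracle; pattern QRAM unload;
              diffuser over the pattern-ID register];
         text QRAM unload; diffuser over the address register];
    measure the address register.

Addressing defaults to linear windows for Enumerate-m and cyclic windows
for Nested Grover (both overridable), matching the bundled demonstrations.
The iteration schedule defaults to the counts in :mod:`qkmer.grover` and can
be pinned per instance; the bundled 8-base Nested Grover demonstration pins
one outer and one inner iteration — see :func:`toy2_nested_instance` and
docs/methods.md for the derivation.

Validity qubits: padded basis states of the address (and pattern-ID)
register load all-zero data, which collides with the valid encoding of an
all-A word.  The builders allocate a validity work qubit, marked by the
QRAM load, exactly in the configurations where that collision could create
a false phase mark; otherwise no extra qubit is spent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .circuit import (
    Circuit,
    MeasurementHistogram,
    Register,
    h,
    marginal_probabilities,
    sample_counts,
    simulate_statevector,
    DEFAULT_QUBIT_CAP,
)
from .classical import match_naive
from .encoding import validate_dna
from .grover import IterationSchedule, build_diffuser, inner_iterations, outer_iterations
from .oracles import build_enumerate_oracle, build_equality_oracle, prepare_match_minus
from .qram import QramSpec, build_load, build_pattern_load, pattern_id_width, substring_at

VARIANTS = ("enumerate_m", "nested_grover")

#: The two in-study demonstration instances.
TOY1_TEXT, TOY1_PATTERNS = "ACGT", ("AC", "CG", "GT")
TOY2_TEXT, TOY2_PATTERNS = "ACGTACGT", ("GTA", "TAC")

DEFAULT_SHOTS = 1024
#: An address is "detected" when its frequency exceeds this multiple of the
#: uniform baseline shots / 2**address_width.
DEFAULT_DETECTION_FACTOR = 1.5


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchInstance:
    """A fully specified run: text, pattern dictionary and execution knobs."""

    text: str
    patterns: tuple[str, ...]
    variant: str = "enumerate_m"
    addressing: str | None = None  # None -> linear (enumerate) / cyclic (nested)
    shots: int = DEFAULT_SHOTS
    seed: int = 0
    schedule: IterationSchedule | None = None
    qubit_cap: int = DEFAULT_QUBIT_CAP

    def __post_init__(self) -> None:
        object.__setattr__(self, "text", validate_dna(self.text, what="text"))
        object.__setattr__(
            self, "patterns", tuple(validate_dna(p, what="pattern") for p in self.patterns)
        )
        if self.variant not in VARIANTS:
            raise SearchError(f"variant must be one of {VARIANTS}")
        if not self.patterns:
            raise SearchError("need at least one pattern")
        L = len(self.patterns[0])
        if L == 0 or any(len(p) != L for p in self.patterns):
            raise SearchError("patterns must be non-empty and all the same length")
        if L > len(self.text):
            raise SearchError("pattern length exceeds text length")
        if self.shots < 1:
            raise SearchError("shots must be >= 1")

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def L(self) -> int:
        return len(self.patterns[0])

    @property
    def m(self) -> int:
        return len(self.patterns)

    @property
    def resolved_addressing(self) -> str:
        if self.addressing is not None:
            return self.addressing
        return "linear" if self.variant == "enumerate_m" else "cyclic"

    @property
    def qram_spec(self) -> QramSpec:
        return QramSpec(self.text, self.L, self.resolved_addressing)

    @property
    def S(self) -> int:
        return self.qram_spec.S

    def resolved_schedule(self) -> IterationSchedule:
        if self.schedule is not None:
            return self.schedule
        return IterationSchedule(
            outer_R=outer_iterations(self.S),
            inner_r=inner_iterations(self.m) if self.variant == "nested_grover" else 1,
        )


def _needs_text_valid(inst: SearchInstance) -> bool:
    """Padded addresses leave all-zero data; that is confusable with a real
    match only against an all-A pattern or against a padded pattern ID."""
    spec = inst.qram_spec
    if not spec.padded:
        return False
    any_all_a = any(set(p) == {"A"} for p in inst.patterns)
    if inst.variant == "enumerate_m":
        return any_all_a
    pid_padded = (1 << pattern_id_width(inst.m)) > inst.m
    return any_all_a or pid_padded


def _needs_pattern_valid(inst: SearchInstance) -> bool:
    """Padded pattern IDs load all-zero pattern data; confusable only with a
    genuinely all-A text window (padded addresses are already blocked by the
    text validity control when both paddings exist)."""
    if inst.variant != "nested_grover":
        return False
    if (1 << pattern_id_width(inst.m)) <= inst.m:
        return False
    spec = inst.qram_spec
    return any(set(substring_at(spec, i)) == {"A"} for i in range(spec.S))


def build_enumerate_m(inst: SearchInstance) -> Circuit:
    """Assemble the Enumerate-m circuit for *inst* (measurement included)."""
    if inst.variant != "enumerate_m":
        raise SearchError("instance variant is not enumerate_m")
    spec = inst.qram_spec
    need_valid = _needs_text_valid(inst)
    regs = [
        Register("address", spec.address_width, "address"),
        Register("data", 2 * inst.L, "data"),
        Register("match", 1, "match"),
    ]
    if need_valid:
        regs.append(Register("valid", 1, "work_ancilla"))
    circ = Circuit(regs)
    addr = list(circ.qubits("address"))
    data = list(circ.qubits("data"))
    match_q = circ.qubit("match", 0)
    valid_q = circ.qubit("valid", 0) if need_valid else None

    circ.extend(h(q) for q in addr)
    circ.extend(prepare_match_minus(match_q))
    R = inst.resolved_schedule().outer_R
    load = build_load(spec, addr, data, valid_q)
    oracle = build_enumerate_oracle(inst.patterns, data, match_q, valid_q, padded=spec.padded)
    diffuser = build_diffuser(addr)
    for _ in range(R):
        circ.extend(load)
        circ.extend(oracle)
        circ.extend(reversed(load))
        circ.extend(diffuser)
    circ.measure("address")
    return circ


def build_nested_grover(inst: SearchInstance) -> Circuit:
    """Assemble the Nested Grover circuit for *inst* (measurement included)."""
    if inst.variant != "nested_grover":
        raise SearchError("instance variant is not nested_grover")
    spec = inst.qram_spec
    pw = pattern_id_width(inst.m)
    need_tvalid = _needs_text_valid(inst)
    need_pvalid = _needs_pattern_valid(inst)
    regs = [
        Register("address", spec.address_width, "address"),
        Register("pattern_id", pw, "pattern_id"),
        Register("data", 2 * inst.L, "data"),
        Register("pattern_data", 2 * inst.L, "pattern_data"),
        Register("equality", 2 * inst.L, "equality_ancilla"),
        Register("match", 1, "match"),
    ]
    if need_tvalid:
        regs.append(Register("text_valid", 1, "work_ancilla"))
    if need_pvalid:
        regs.append(Register("pattern_valid", 1, "work_ancilla"))
    circ = Circuit(regs)
    addr = list(circ.qubits("address"))
    pid = list(circ.qubits("pattern_id"))
    data = list(circ.qubits("data"))
    pdata = list(circ.qubits("pattern_data"))
    eq = list(circ.qubits("equality"))
    match_q = circ.qubit("match", 0)
    tvalid = circ.qubit("text_valid", 0) if need_tvalid else None
    pvalid = circ.qubit("pattern_valid", 0) if need_pvalid else None

    circ.extend(h(q) for q in addr)
    circ.extend(h(q) for q in pid)
    circ.extend(prepare_match_minus(match_q))

    sched = inst.resolved_schedule()
    text_load = build_load(spec, addr, data, tvalid)
    pat_load = build_pattern_load(inst.patterns, pid, pdata, pvalid)
    extra = [q for q in (tvalid, pvalid) if q is not None]
    equality = build_equality_oracle(inst.L, data, pdata, eq, match_q, extra_controls=extra)
    inner_diff = build_diffuser(pid)
    outer_diff = build_diffuser(addr)

    for _ in range(sched.outer_R):
        circ.extend(text_load)
        for _ in range(sched.inner_r):
            circ.extend(pat_load)
            circ.extend(equality)
            circ.extend(reversed(pat_load))
            circ.extend(inner_diff)
        circ.extend(reversed(text_load))
        circ.extend(outer_diff)
    circ.measure("address")
    return circ


def build(inst: SearchInstance) -> Circuit:
    if inst.variant == "enumerate_m":
        return build_enumerate_m(inst)
    return build_nested_grover(inst)


@dataclass(frozen=True)
class MatchReport:
    """Quantum run outcome plus classical ground truth and their agreement."""

    instance: SearchInstance
    schedule: IterationSchedule
    histogram: MeasurementHistogram
    probabilities: tuple[float, ...]  # exact address marginal, index = address
    predicted_positions: tuple[int, ...]  # thresholded, ranked by frequency
    classical_positions: tuple[int, ...]
    agreement: Mapping[int, bool]  # classical position -> was it predicted?
    detection_factor: float

    @property
    def no_amplified_position(self) -> bool:
        return len(self.predicted_positions) == 0

    @property
    def all_detected(self) -> bool:
        return all(self.agreement.values())

    @property
    def spurious_positions(self) -> tuple[int, ...]:
        truth = set(self.classical_positions)
        return tuple(p for p in self.predicted_positions if p not in truth)

    def to_json_dict(self) -> dict:
        return {
            "schema": "qkmer.match_report/1",
            "text": self.instance.text,
            "patterns": list(self.instance.patterns),
            "variant": self.instance.variant,
            "addressing": self.instance.resolved_addressing,
            "n": self.instance.n,
            "L": self.instance.L,
            "m": self.instance.m,
            "S": self.instance.S,
            "seed": self.instance.seed,
            "schedule": {"outer_R": self.schedule.outer_R, "inner_r": self.schedule.inner_r},
            "histogram": self.histogram.to_json_dict(),
            "probabilities": [round(p, 12) for p in self.probabilities],
            "predicted_positions": list(self.predicted_positions),
            "classical_positions": list(self.classical_positions),
            "agreement": {str(k): v for k, v in self.agreement.items()},
            "detection_factor": self.detection_factor,
            "no_amplified_position": self.no_amplified_position,
        }


def run(inst: SearchInstance, detection_factor: float = DEFAULT_DETECTION_FACTOR) -> MatchReport:
    """Build, simulate and sample *inst*; attach classical ground truth.

    An address is *predicted* when its sampled frequency is at least
    ``detection_factor * shots / 2**address_width`` (the uniform baseline);
    predicted addresses are ranked by frequency.  Deterministic for a fixed
    (instance, seed)."""
    circ = build(inst)
    state = simulate_statevector(circ, qubit_cap=inst.qubit_cap)
    hist = sample_counts(state, circ, "address", inst.shots, inst.seed)
    probs = marginal_probabilities(state, circ, "address")
    n_states = len(probs)
    threshold = detection_factor * inst.shots / n_states
    predicted = [
        a for a, c in sorted(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if c >= threshold
    ]
    truth = match_naive(inst.text, inst.patterns, inst.resolved_addressing).positions
    agreement = {pos: pos in predicted for pos in truth}
    return MatchReport(
        instance=inst,
        schedule=inst.resolved_schedule(),
        histogram=hist,
        probabilities=tuple(float(p) for p in probs),
        predicted_positions=tuple(predicted),
        classical_positions=truth,
        agreement=agreement,
        detection_factor=detection_factor,
    )


def toy1_instance(variant: str = "enumerate_m", shots: int = DEFAULT_SHOTS, seed: int = 0) -> SearchInstance:
    """The 4-base demonstration: text ACGT, patterns {AC, CG, GT} (S=3, R=1)."""
    return SearchInstance(TOY1_TEXT, TOY1_PATTERNS, variant=variant, shots=shots, seed=seed)


def toy2_enumerate_instance(shots: int = DEFAULT_SHOTS, seed: int = 0) -> SearchInstance:
    """The 8-base demonstration under Enumerate-m, linear windows (S=6)."""
    return SearchInstance(TOY2_TEXT, TOY2_PATTERNS, variant="enumerate_m", shots=shots, seed=seed)


def toy2_nested_instance(shots: int = DEFAULT_SHOTS, seed: int = 0) -> SearchInstance:
    """The 8-base demonstration under Nested Grover, cyclic windows (S=8).

    The schedule is pinned to one outer and one inner iteration: with the
    four cyclic match positions being exactly half of the 8-state address
    space, amplitude amplification stalls for every schedule in which the
    inner loop acts as a clean phase oracle, and (R=1, r=1) is the unique
    configuration whose exact output concentrates all probability on the
    match addresses {2, 3, 6, 7} (0.25 each) — the published behavior of
    this demonstration.  See docs/methods.md for the full derivation.
    """
    return SearchInstance(
        TOY2_TEXT,
        TOY2_PATTERNS,
        variant="nested_grover",
        shots=shots,
        seed=seed,
        schedule=IterationSchedule(outer_R=1, inner_r=1),
    )
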