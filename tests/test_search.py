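"""End-to-end matchers: register inventories, exact behavior, soundness."""

import numpy as np
import pytest

from qkmer.circuit import ResourceLimitError
from qkmer.classical import match_naive
from qkmer.grover import IterationSchedule
from qkmer.search import (
    SearchInstance,
    build,
    build_enumerate_m,
    build_nested_grover,
    run,
    toy1_instance,
    toy2_nested_instance,
)


class TestAssembly:
    def test_toy1_registers(self):
        inst = toy1_instance()
        assert (inst.S, inst.resolved_schedule().outer_R) == (3, 1)
        circ = build_enumerate_m(inst)
        widths = {r.name: r.width for r in circ.registers}
        assert widths == {"address": 2, "data": 4, "match": 1}

    def test_toy2_nested_registers(self):
        circ = build_nested_grover(toy2_nested_instance())
        widths = {r.name: r.width for r in circ.registers}
        assert widths == {
            "address": 3,
            "pattern_id": 1,
            "data": 6,
            "pattern_data": 6,
            "equality": 6,
            "match": 1,
        }
        assert circ.width == 23

    def test_wrong_variant_rejected(self):
        with pytest.raises(Exception):
            build_nested_grover(toy1_instance())

    def test_qubit_cap_refusal(self):
        inst = SearchInstance("ACGT" * 16, ("ACGTACGTAC",), qubit_cap=24)
        with pytest.raises(ResourceLimitError):
            run(inst)

    def test_single_pattern_degenerate_inner(self):
        inst = SearchInstance("ACGT", ("AC",), variant="nested_grover", addressing="linear")
        sched = inst.resolved_schedule()
        assert sched.inner_r == 1
        circ = build_nested_grover(inst)
        assert {r.name: r.width for r in circ.registers}["pattern_id"] == 1


class TestEnumerateBehavior:
    def test_single_pattern_amplified_to_certainty(self):
        """{AC} on ACGT: one marked address of four -> probability 1 at 0."""
        report = run(SearchInstance("ACGT", ("AC",), seed=2))
        assert report.probabilities[0] == pytest.approx(1.0, abs=1e-9)
        assert report.predicted_positions == (0,)
        assert report.all_detected

    def test_no_match_keeps_uniform_distribution(self):
        report = run(SearchInstance("AAAA", ("GT",), seed=3))
        probs = np.array(report.probabilities)
        assert np.allclose(probs, 1 / len(probs), atol=1e-9)
        assert report.no_amplified_position
        assert report.classical_positions == ()

    def test_seed_determinism(self):
        r1 = run(SearchInstance("ACGTACGT", ("GTA", "TAC"), seed=9))
        r2 = run(SearchInstance("ACGTACGT", ("GTA", "TAC"), seed=9))
        assert r1.histogram.counts == r2.histogram.counts
        assert r1.predicted_positions == r2.predicted_positions

    def test_schedule_override(self):
        inst = SearchInstance(
            "ACGTACGT", ("GTA", "TAC"), schedule=IterationSchedule(outer_R=2)
        )
        assert inst.resolved_schedule().outer_R == 2


class TestSoundness:
    """In the sparse-match single-round regime (k marked of N <= N/4 with one
    amplification round) Grover provably separates matches from non-matches:
    every match address exceeds 1.5x the uniform baseline and every non-match
    stays below it.  Outside that regime amplitude amplification can invert
    (marked-majority) or stall (k = N/2), so this is the regime where the
    amplified-implies-match property is a theorem rather than a tendency."""

    def _random_instances(self, rng, variant, count):
        bases = np.array(list("ACGT"))
        made = 0
        while made < count:
            n = int(rng.integers(4, 9))
            # nested instances carry three 2L-wide registers; keep them desk-sized
            L = int(rng.integers(1, 4 if variant == "enumerate_m" else 3))
            if L > n:
                continue
            m = 2 if variant == "nested_grover" else int(rng.integers(1, 4))
            m = min(m, 4**L)
            text = "".join(rng.choice(bases, size=n))
            pats = set()
            while len(pats) < m:
                pats.add("".join(rng.choice(bases, size=L)))
            yield text, tuple(sorted(pats))
            made += 1

    def test_enumerate_sparse_matches_amplified(self):
        rng = np.random.default_rng(77)
        checked = 0
        for text, patterns in self._random_instances(rng, "enumerate_m", 40):
            inst = SearchInstance(
                text, patterns, seed=5, schedule=IterationSchedule(outer_R=1)
            )
            truth = set(match_naive(text, patterns, "linear").positions)
            n_states = 2 ** inst.qram_spec.address_width
            if not truth or len(truth) > n_states // 4:
                continue
            report = run(inst)
            baseline = 1.0 / n_states
            amplified = {
                a for a, p in enumerate(report.probabilities) if p > 1.5 * baseline
            }
            assert amplified == truth, (text, patterns)
            checked += 1
        assert checked >= 8

    def test_nested_two_pattern_clean_phase_regime(self):
        """With m = 2 (no pattern-ID padding) and r = 2 inner iterations the
        inner loop acts as an exact phase oracle, so the whole nested circuit
        reduces to Grover over addresses; sparse matches must then be exactly
        the amplified set."""
        rng = np.random.default_rng(78)
        checked = 0
        for text, patterns in self._random_instances(rng, "nested_grover", 25):
            inst = SearchInstance(
                text,
                patterns,
                variant="nested_grover",
                seed=5,
                schedule=IterationSchedule(outer_R=1, inner_r=2),
            )
            truth = set(match_naive(text, patterns, inst.resolved_addressing).positions)
            n_states = 2 ** inst.qram_spec.address_width
            if not truth or len(truth) > n_states // 4:
                continue
            report = run(inst)
            baseline = 1.0 / n_states
            amplified = {
                a for a, p in enumerate(report.probabilities) if p > 1.5 * baseline
            }
            assert amplified == truth, (text, patterns)
            checked += 1
        assert checked >= 4

    def test_report_agreement_fields(self):
        report = run(SearchInstance("ACGTACGT", ("GTA", "TAC"), seed=1))
        assert set(report.agreement) == {2, 3}
        assert report.spurious_positions == ()

    def test_report_json_schema_roundtrip(self):
        import json

        report = run(toy1_instance(seed=4))
        payload = json.loads(json.dumps(report.to_json_dict()))
        assert payload["schema"] == "qkmer.match_report/1"
        assert payload["S"] == 3
        assert sum(payload["histogram"]["counts"].values()) == payload["histogram"]["shots"]
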