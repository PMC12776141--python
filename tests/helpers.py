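"""Shared test utilities: phase-flip extraction from oracle fragments.

The central correctness notion is that the set of basis addresses whose
amplitude sign is flipped by load -> oracle -> unload equals the classical
match set.  These helpers build the minimal circuit for that check and read
the signs off the exact statevector.
"""

from __future__ import annotations

import numpy as np

from qkmer.circuit import Circuit, Register, h, simulate_statevector
from qkmer.oracles import build_enumerate_oracle, build_equality_oracle, prepare_match_minus
from qkmer.qram import QramSpec, build_load, build_pattern_load, pattern_id_width


def enumerate_flipped_addresses(text, patterns, addressing="linear"):
    """Addresses whose phase is flipped by load -> enumerate oracle -> unload,
    starting from a uniform address superposition with the match qubit in |->."""
    spec = QramSpec(text, len(patterns[0]), addressing)
    need_valid = spec.padded and any(set(p) == {"A"} for p in patterns)
    regs = [
        Register("address", spec.address_width, "address"),
        Register("data", 2 * spec.L, "data"),
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
    load = build_load(spec, addr, data, valid_q)
    circ.extend(load)
    circ.extend(build_enumerate_oracle(patterns, data, match_q, valid_q, padded=spec.padded))
    circ.extend(reversed(load))
    state = simulate_statevector(circ)
    n_states = 1 << spec.address_width
    baseline = 1.0 / np.sqrt(n_states) / np.sqrt(2.0)  # match qubit |-> component
    flipped = set()
    for i in range(n_states):
        amp = state[circ.basis_index({"address": i})]
        assert abs(abs(amp) - baseline) < 1e-9, "data/ancilla registers not restored"
        assert abs(amp.imag) < 1e-12
        if amp.real < 0:
            flipped.add(i)
    # sign flips must never land on padding addresses
    return {i for i in flipped if i < spec.S}, {i for i in flipped if i >= spec.S}


def equality_flipped_pairs(text, patterns, addressing="cyclic"):
    """(address, pattern_id) pairs phase-flipped by
    text load -> pattern load -> equality oracle -> unload both."""
    L = len(patterns[0])
    spec = QramSpec(text, L, addressing)
    m = len(patterns)
    pw = pattern_id_width(m)
    addr_padded = spec.padded
    pid_padded = (1 << pw) > m
    any_all_a_pat = any(set(p) == {"A"} for p in patterns)
    from qkmer.qram import substring_at

    any_all_a_win = any(set(substring_at(spec, i)) == {"A"} for i in range(spec.S))
    need_tvalid = addr_padded and (any_all_a_pat or pid_padded)
    need_pvalid = pid_padded and any_all_a_win
    regs = [
        Register("address", spec.address_width, "address"),
        Register("pattern_id", pw, "pattern_id"),
        Register("data", 2 * L, "data"),
        Register("pattern_data", 2 * L, "pattern_data"),
        Register("equality", 2 * L, "equality_ancilla"),
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
    tload = build_load(spec, addr, data, tvalid)
    pload = build_pattern_load(patterns, pid, pdata, pvalid)
    circ.extend(tload)
    circ.extend(pload)
    extra = [q for q in (tvalid, pvalid) if q is not None]
    circ.extend(build_equality_oracle(L, data, pdata, eq, match_q, extra_controls=extra))
    circ.extend(reversed(pload))
    circ.extend(reversed(tload))
    state = simulate_statevector(circ)
    na = 1 << spec.address_width
    np_ = 1 << pw
    baseline = 1.0 / np.sqrt(na * np_) / np.sqrt(2.0)
    flipped = set()
    for i in range(na):
        for j in range(np_):
            amp = state[circ.basis_index({"address": i, "pattern_id": j})]
            assert abs(abs(amp) - baseline) < 1e-9, "registers not restored"
            if amp.real < 0:
                flipped.add((i, j))
    valid_flips = {(i, j) for i, j in flipped if i < spec.S and j < m}
    pad_flips = flipped - valid_flips
    return valid_flips, pad_flips
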