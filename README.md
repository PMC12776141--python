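# qkmer — quantum multi-pattern k-mer matching, simulated exactly

Locating every occurrence of a dictionary of k-mers in a DNA text is a
workhorse of variant calling, pathogen typing and metagenomic
classification; classically it is solved in linear time by Aho–Corasick.
`qkmer` builds, gate by gate, two Grover-style quantum alternatives and runs
them on an exact statevector simulator, so their real behavior — successes,
stalls and all — can be measured rather than asserted:

* **Enumerate-m** — the m patterns are hardcoded into a phase oracle. Each
  amplification round loads the length-L window at every superposed start
  position through a QRAM query, tests it against each pattern with
  X-conjugated multi-controlled-X gates into a |−⟩ match qubit (phase
  kickback), uncomputes the load, and applies the diffuser over the address
  register. Oracle work per round: O(m·L); total gates O(√S·m·L) over
  S = n−L+1 window positions.

* **Nested Grover** — patterns live in a second QRAM indexed by a
  pattern-ID register. An inner Grover loop over pattern space (equality
  oracle built from CNOT/X XNOR ancillas, diffuser over the pattern IDs)
  sits inside each outer round over text positions, for O(L·√m) oracle work
  per outer round and O(√S·L·√m) total — the variant whose gate count drops
  below the classical O(n) bound when √n·L·√m < n.

The ideal QRAM ∑ᵢαᵢ|i⟩|0⟩ → ∑ᵢαᵢ|i⟩|dᵢ⟩ is realized as an explicit
address-conditioned multiplexer (one MCX block per valid address, S·L
blocks per query), every load exactly uncomputed to keep the oracles
phase-only. A classical reference (naive scan + Aho–Corasick, validated
against each other) supplies ground truth for every quantum run, and a
closed-form resource estimator reports qubit totals, load-MCX counts and
the quantum/classical crossover for arbitrary (n, m, L).

Everything runs on plain numpy; circuits up to 24 qubits by default
(overridable). See `docs/methods.md` for the model, conventions, schedule
analysis and known limitations.

## Worked example

The bundled 8-base demonstration: text `ACGTACGT`, motifs `GTA` and `TAC`,
Nested Grover with cyclic addressing (every one of the 8 positions starts a
wrap-around window; GTA occurs at 2 and 6, TAC at 3 and 7):

```sh
qkmer run --text fixtures/toy2.fa --patterns fixtures/toy2_patterns.txt \
      --variant nested_grover --outer-iters 1 --inner-iters 1 \
      --shots 1024 --seed 1
```

prints (abridged):

```
"S": 8,
"schedule": {"outer_R": 1, "inner_r": 1},
"histogram": {"counts": {"2": 252, "3": 238, "6": 268, "7": 266}},
"predicted_positions": [6, 7, 2, 3],
"classical_positions": [2, 3, 6, 7]
```

All 1024 shots land on the four true motif start positions — the exact
amplitude calculation puts probability 0.25 on each of {2, 3, 6, 7} and 0
elsewhere. The one-outer/one-inner schedule is pinned here because the four
matches are exactly half of the 8-state address space, a regime where
longer schedules provably stall at uniform (`docs/methods.md`).

Resource accounting for a kilobase-scale search:

```sh
qkmer estimate --n 1000 --m 10 --l 20
```

```
positions S                      981
index qubits                     10
data qubits (2L)                 40
overhead ancillas                3
total qubits                     53
load MCX blocks (S*L)            19620
...
nested cost     sqrt(n)*L*sqrt(m) = 2000
classical cost  n                 = 1000
quantum advantage (nested < classical): False
```

A 1000-base text with ten 20-mers needs 53 qubits and 19,620 load-MCX
blocks per query — and still no theoretical advantage; the crossover
√n·L·√m < n needs genome-scale n (≈10⁸) and k-mer dictionaries of ≈10⁴
patterns (`qkmer estimate --n 100000000 --m 10000 --l 20 --json`).

Other subcommands: `qkmer verify` diffs a run report against both classical
matchers; `qkmer fixture` generates random texts with planted motifs.

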