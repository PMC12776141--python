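# Methods

## Problem and model

Given a DNA text `t` of length `n` over {A,C,G,T} and a dictionary of `m`
distinct patterns, all of the same length `L`, find every start position
whose length-`L` window equals a dictionary pattern. Window positions are
0-based; *linear* addressing uses the S = n−L+1 in-bounds windows, *cyclic*
addressing treats the text as circular so all S = n positions start a valid
window (position i covers characters (i+j) mod n). Enumerate-m defaults to
linear and Nested Grover to cyclic addressing, matching the bundled
demonstrations; both are overridable.

Both quantum matchers follow Grover amplitude amplification over the
address space: prepare a uniform superposition of addresses, repeatedly
apply a phase oracle that flips the sign of match addresses followed by the
inversion-about-average diffuser, then measure. The oracle is built from a
QRAM load of the window at every superposed address, a marking step into a
match qubit prepared in |−⟩ (phase kickback), and an exact uncomputation of
the load so that the oracle is phase-only on the address register.

All simulation is exact, noiseless statevector evolution. Hardware
concerns — noise channels, transpilation, connectivity, error
correction — are explicitly out of scope; the point of the package is to
measure what the *ideal* circuits do.

## Encoding and endianness

Each base maps to two bits, high bit first: A=(0,0), C=(0,1), G=(1,0),
T=(1,1); a k-mer of length L occupies exactly 2L bits/qubits, bases
concatenated left-to-right. One endianness convention covers the package:
within any register the first qubit is the most significant bit of the
register's integer value, and registers are laid out in declaration order.
Measured address bitstrings therefore decode to integers with no extra
bookkeeping. The base-level bit order is a declared convention; any
consistent choice yields identical measurement statistics.

Ambiguity codes (N, IUPAC degenerates) and gaps are rejected with a
position diagnostic: the 2-bit code has no slot for them, and silently
coercing them would corrupt matches.

## Circuit substrate and simulator

The gate set is H, X, CNOT and MCX — sufficient for every construction
here and all self-inverse, so any fragment is inverted by reversing its op
list; that is what makes compute–oracle–uncompute discipline cheap to
implement and to verify. MCX executes natively as one unitary; its
decomposition cost into elementary gates is a resource-accounting topic,
not a simulation topic. The simulator applies gates in place on the state
tensor (no gate matrices are ever materialized), checks nothing weaker than
exact unitarity in its tests (norm drift < 1e-9), and refuses circuits
beyond a configurable qubit cap (default 24; 2^24 amplitudes ≈ 268 MB) with
the resource estimate attached to the refusal. Sampling draws a multinomial
from the exact marginal of the measured register under a caller-supplied
seed, so runs are reproducible shot-for-shot.

## QRAM as an explicit multiplexer

The ideal-QRAM query ∑αᵢ|i⟩|0⟩ → ∑αᵢ|i⟩|dᵢ⟩ is met by brute-force
circuitization: for each valid address i, X gates conjugate the address
qubits that are 0 in i's bit pattern, one MCX per set bit of the encoded
window writes the data register, and the conjugation is undone. Unloading
is the reversed gate list. Per query this costs S·L per-(position, base)
MCX blocks — the figure the resource estimator reports — while the
idealized O(log S) query abstraction of a physical (e.g. bucket-brigade)
QRAM is *reported* by the complexity strings, never implemented. This
matches how the algorithms were analyzed: simulate under the ideal-QRAM
assumption, count the explicit load gates.

**Padding.** A ⌈log₂S⌉-qubit address register has 2^⌈log₂S⌉ − S extra basis
states when S is not a power of two. These padding addresses load nothing,
leaving all-zero data. All-zero, however, is the legitimate encoding of
"AA…A", so a padded address could be falsely marked when an all-A word is
being compared. The builders close this hole with a validity work qubit,
set by the load for valid addresses only, added as an MCX control exactly
in the configurations that need it: an all-A pattern with a padded address
space (Enumerate-m); for Nested Grover additionally a padded pattern-ID
space colliding with a padded address space or with an all-A text window.
No extra qubit is spent otherwise. Oracle tests assert that phase flips
never land on padding states.

## Oracles

*Enumerate-m*: per pattern, X-conjugate the data qubits whose encoded
pattern bit is 0, MCX from all 2L data qubits (plus validity control when
required) onto the match qubit, unconjugate. Duplicate patterns are
rejected at construction — two flips of the same basis state cancel and
would silently unmark a true match. Distinct equal-length patterns cannot
double-mark one address, so ordering is immaterial.

*Equality oracle*: per bit position, CNOTs from the data and pattern qubits
into a dedicated ancilla compute XOR; an X converts it to XNOR; an MCX over
all 2L XNOR ancillas (plus validity controls) targets the match qubit; the
XNOR layer is then uncomputed so the ancillas exit at |0…0⟩. Ancilla
hygiene is asserted to 1e-9 in the tests.

## Iteration schedules and what the demonstrations force

The outer schedule defaults to R = max(1, ⌊(π/4)·√S⌋) over the S valid
positions — the standard Grover count when the number of matches k is
unknown and assumed small. The inner schedule defaults to
r = ⌈π·√m/4⌉, the near-optimal count for the single matching pattern among
m. Both are per-run overridable (`--outer-iters`, `--inner-iters`), and the
schedule choice is the single most consequential knob in the package, so
its edge cases are documented here rather than discovered in anger:

* **Sparse-match regime (the useful one).** With one amplification round
  and 1 ≤ k ≤ N/4 marked states among N = 2^⌈log₂S⌉, the exact final
  probability of each match is (3 − 4k/N)²/N ≥ 4/N and of each non-match at
  most (N/(N−k))·cos²(·)/N < 1.5/N: matches and non-matches are provably
  separated by the 1.5×-uniform detection threshold the run report uses.
  The soundness tests assert exactly this regime.

* **Majority inversion.** When more than half the (padded) address space is
  marked, inversion-about-average amplifies the *complement*. The 4-base
  demonstration (text ACGT, patterns AC/CG/GT) is the extreme case: 3 of 4
  addresses marked, and one round sends all amplitude to the unmarked
  padding address 3. This is a mathematical property of Grover iteration,
  not an implementation artifact; the demonstration's published quantities
  are its schedule values (S = 3, R = 1), which the package reproduces.

* **The k = N/2 stall and the 8-base demonstration.** For the 8-base text
  ACGTACGT with motifs {GTA, TAC} under cyclic addressing, the four match
  addresses {2,3,6,7} are exactly half of the 8-state space. Whenever the
  inner loop acts as a clean ±1 phase oracle (which it does at m = 2 with
  r = 2: mark, null diffuser step, mark, −1 — an exact phase), the outer
  iteration rotates by θ = π/2 per round and the distribution stays exactly
  uniform for *every* R. The published concentration on the motif indices
  is nevertheless reachable: at r = 1 the inner loop leaves an
  address-dependent pattern-ID state (±(|0⟩−|1⟩)/√2 on matches, −|s⟩ on
  non-matches) whose interference through one outer diffuser places
  probability exactly 0.25 on each of {2,3,6,7} and 0 elsewhere. This was
  derived analytically and confirmed by exact simulation of the full
  23-qubit circuit; (R=1, r=1) is the unique schedule with that outcome,
  which is why `toy2_nested_instance()` pins it. The general-purpose
  defaults remain the formulas above.

The Enumerate-m run on the same 8-base text (linear, S = 6, k = 2 of 8,
R = 1 from the default schedule) lands in the sparse regime and puts
probability 0.5 on each of positions {2, 3} exactly.

The nested composition follows the narrated structure faithfully: the inner
amplification is *not* uncomputed before the outer diffuser. For r at which
the inner loop is not an exact phase oracle this leaves residual
entanglement between address and pattern-ID registers, and measured
behavior (e.g. padded-address leakage at m = 3) is reported as-is by the
run report rather than corrected; the package treats the circuit as the
object of study.

## Detection rule

Histograms are reported raw; for convenience the run report also flags an
address as *predicted* when its frequency reaches 1.5× the uniform baseline
shots/2^a (factor configurable). With no matching pattern the oracle is the
identity, the diffuser fixes the uniform state, and the final distribution
is exactly uniform — reported as "no amplified position".

## Resource accounting

Qubit totals follow the register inventory: ⌈log₂S⌉ index + 2L data
(+ ⌈log₂m⌉ pattern-ID + 2L pattern-data + 2L equality ancillas for the
nested variant) + a fixed overhead of 3 ancillas (phase inversion, match
indication, intermediate computation). Load cost is S·L MCX blocks counted
per (position, base); the per-data-qubit count 2·S·L is exposed alongside,
and the builders' actual emitted MCX count (one per set encoded bit, ≤
2·S·L) is cross-checked against the accounting in tests. MCX decomposition
into Toffoli/T gates, circuit depth and error-correction overhead are
deliberately not modeled. The crossover report evaluates √n·L·m (enumerate),
√n·L·√m (nested) against the classical linear bound n.

## Synthetic data

`generate_fixture(n, m, L, planted, seed)` draws m distinct uniform-random
patterns and a uniform-random background text, then overwrites `planted`
non-overlapping windows with patterns (cycled) at random positions —
planted positions are true matches by construction, and chance background
matches may exist and are not recorded. This emulates the only text
property the algorithms are sensitive to — where exact matches sit — and
none of the composition biases, repeats or homopolymer structure of real
genomes; passing tests therefore certify circuit correctness, not
robustness to genomic sequence statistics. The bundled fixtures are the two
in-study demonstration inputs verbatim (ACGT with {AC,CG,GT}; ACGTACGT with
{GTA,TAC}).

## Numerical choices and degenerate inputs

Amplitude comparisons use 1e-9 absolute tolerance (double precision leaves
~1e-15 slack on these circuit sizes). Sampled marginals are renormalized
against ~1e-16 rounding drift before the multinomial draw. Minimum register
width is 1 everywhere (S = 1 or m = 1 still allocate one qubit; the padding
machinery covers the unused state). The width-1 diffuser is the exact
operator 2|s⟩⟨s|−I = X, emitted as a single gate. Ties in frequency
ranking break toward the smaller address. Texts shorter than L, empty
patterns, mixed-length dictionaries, duplicate patterns and non-ACGT input
are rejected with specific messages.

## Known limitations

* Statevector memory bounds exact simulation to ~24–28 qubits; the nested
  variant's six registers reach 23 qubits already at n = 8, L = 3.
* The outer schedule is a convention: with unknown k no fixed formula is
  optimal, and outside the sparse regime amplification can invert or stall
  (above). Quantum counting to estimate k is not implemented.
* The classical O(n+m) matcher is, on any simulatable instance, vastly
  faster than simulating the quantum circuits; the package measures
  algorithm behavior and resource scaling, it does not accelerate matching.
* Fixed L only; multi-length dictionaries would need per-length registers.
* The simulator-reported gate totals of any particular quantum framework
  are compilation-dependent and are not reproduced; the package counts its
  own explicit constructions.
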