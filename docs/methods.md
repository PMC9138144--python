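# Methods

## Model and scope

`groverseq` simulates, with a dense complex state vector, a quantum
pipeline for finding **all exact occurrences of m patterns in a DNA text**.
The simulation is ideal-circuit: no noise channels, no density matrices,
no hardware-level memory switching (the quantum memory's load behaviour is
modelled as an abstract XOR contract, not as a bucket-brigade switch
network). Gate counts are logged per logical family {H, X, Rz, CZ(k),
CX(k)} as direct amplitude updates; no decomposition into elementary
two-qubit gates is performed, so logged counts reflect this package's own
realization and are not comparable across simulators.

Throughout, qubit 0 is the most significant bit of a register's basis
index, indices are 0-based, and valid pattern starts form the inclusive
range `[0, N_orig − M]`.

## Text encoding and quantum memory

A text of length `N_orig` is padded with `A`s to `N = 2^n`. Because every
2-bit code is a valid DNA symbol there is no spare "sentinel" code;
instead, every oracle conjoins the validity mask `i ≤ N_orig − M`, so
padded or overhanging start indices can never enter a match set. Words at
indices beyond the valid limit are defined by cyclic wrap so that the
memory's truth table is total.

Each of the `w = M·w0` data bits is synthesized in algebraic normal form
by the binary Möbius transform of its truth-table column, implemented as
the in-place XOR butterfly (`O(2^n · n)` per bit) and verified in the
tests against a naive `O(4^n)` subset-XOR implementation. Loading XORs
the addressed word into the data register — a self-inverse basis
permutation. The load raises an error when the data register holds
anything other than zeros or the already-loaded words: those are the only
two states in which the XOR contract is meaningful (and the second makes
the load its own inverse).

Two execution modes exist downstream. **Dense mode** (default for
`N ≤ 64`) physically simulates address + data + comparison registers and
derives the oracle's marked set from the comparator circuit (X-conjugated
bitwise equality, one multi-controlled X onto the comparison qubit).
**Mask mode** evaluates the memory functions classically per address and
builds the marked set directly. Both modes induce identical marked sets,
and the search loop that consumes them is shared, so runs with identical
seeds produce identical measurement sequences in either mode.

## Amplitude amplification and the search loop

For `t` marked items in a space of `N` the schedule is
`r_G = ⌊(π/4)√(N/t)⌋` with two boundary rules:

- `0 < t < N/2`: at least one round is forced (`r_G ≥ 1`).
- `t ≥ N/2`: `r_G = 0`. A bare measurement already succeeds with
  probability `t/N ≥ 1/2`, whereas a forced round overshoots once
  `θ > π/4` (at `t = 3, N = 4` the success probability after one round is
  exactly 0, which would deadlock the enumeration loop). With this rule
  the closed form `sin²((2r_G+1)θ) ≥ t/N` holds for every schedule, which
  the tests check for all `t` at several `N`.
- `t = 0`: the schedule proceeds blind with the single-solution iteration
  count; the outcome is uniform and verification rejects it.

All `t` occurrences are enumerated by repeated
prepare–amplify–measure–verify rounds. After each verified hit the index
is **excluded** from the marked set and the schedule recomputed with the
remaining count, making the expected number of successful rounds `t`
(rather than coupon-collector) and keeping total oracle applications
within `π√(N t)` plus the retry allowance. Unverified measurements count
against a retry budget of `3t + 10`; exhausting it flags an abort on the
report — aborts are reported, never silent.

## Filtering

The filter marks, for each text position holding one of the pattern's
distinct symbols, `position − first_offset(symbol)` as a candidate start,
then keeps candidates within a symbol-level Hamming distance `threshold`
of the pattern. Using the *first* offset of each distinct symbol is a
deliberate choice: using all offsets would only enlarge the candidate set
without affecting completeness (an exact occurrence always yields a
zero-distance candidate at its own start, so completeness holds for every
threshold ≥ 0 — a tested invariant). The default `threshold = ⌈M/4⌉`
keeps the filtered space small relative to `N`, which is what makes the
filtered pipeline's `O(√(t t'))` search worthwhile; it is configurable.

The location array is sorted ascending and padded to `2^tq`
(`tq = ⌈log₂ max(t,1)⌉`) with the sentinel address `2^n`, which lies
outside the text and never verifies. Padding dilutes the success
probability of the filtered search; this dilution is deliberately kept
visible (it reproduces the method's known small-`t` accuracy caveat)
rather than compensated away. When the marked fraction of the filtered
space falls in [0.4, 0.6] the report carries a `balanced_flag`, since
near-balanced spaces are the regime where amplification gains least.

The measure-and-merge collection loop is simulated (candidates drawn with
probability proportional to their marking multiplicity until the set is
complete or `max_rounds` consecutive draws add nothing, in which case a
warning is issued and the result flagged partial); the returned array is
the closed-form set whenever collection completes, and the randomness
affects only collection order.

## Quantum counting

Counting is phase estimation on the Grover operator. The operator's
action on the span of the uniform-marked / uniform-unmarked vectors is a
rotation by `2θ`, and the uniform start state splits equally between the
two conjugate eigenvectors, so the `r`-bit outcome `y` follows an
equal-weight mixture of Fejér kernels centred at `±2^r θ/π`; the estimate
is `t̂ = round(N sin²(πy/2^r))` clamped to `[0, N]`. This closed form
makes counting simulable without `2^(n+r)`-dimensional vectors; an
independent full-register reference (precision + system registers,
controlled powers by repeated application, inverse Fourier transform) is
implemented for `n + r ≤ 14` and the tests require the two distributions
to agree to 1e−9.

Exact counting uses `r = n` (or `tq` on a filtered space) and the
majority of 10 runs, ties resolved to the smaller value (an under-count
only costs retries; an over-count would schedule too few iterations per
round). **Resolution limit:** the estimate grid spacing near the true
count is `≈ 2π√(t(N−t))/N · (2^n/2^r)` counts per outcome step, so with
`r = n` the estimator can only be *exact* when that slope is below about
one count — roughly `t ≲ N/4π²` (t ≤ 3 at N = 128). Outside that regime
the majority estimate lands on a neighbouring representable count (e.g.
t = 10 at N = 128 yields 9 or 11); this is a property of fixed-precision
amplitude estimation, not of the implementation, and the counting test
fixtures therefore plant counts inside the resolvable regime. Approximate
counting (`r < n`) deviates by design and is asserted only against the
envelope of counts reachable from the phase outcomes bracketing the true
eigenphase.

## Multi-core emulation and the error protocol

Cores are independent simulator instances with disjoint registers and
per-(core, wave) random sub-streams derived from the root seed via
`SeedSequence`; the shared memory content is read-only. Parallel cost is
accounted as the per-wave maximum over cores, summed over waves.

Register accounting: the position-based layout totals
`n + M·w0 + 2 + 2` qubits (address, data, two per-symbol comparison
flags, comparison + phase ancillas); the filtered layout totals
`2n + tq` (address + auxiliary filtering registers plus the location
register).

The error protocol runs `R × I` independent single-search-and-measure
trials (defaults 10 × 100, i.e. 1,000 measurements) and classifies each
measured index as CIP (a true occurrence) or IIP (not), with IMP the
number of true indices never measured and
`Error% = 100·IIP/(CIP+IIP)` (undefined and flagged when no measurements
were made; reports format it to one decimal). Since the pre-measurement
state for a fixed schedule is deterministic, the implementation prepares
it once and draws all `R·I` outcomes from its measurement distribution —
distributionally identical to re-preparing per trial, which is also the
assumption made about the protocol itself.

## Synthetic data

The generator plants given patterns at given start indices into an i.i.d.
background (uniform over {A,T,C,G} by default) of a chosen length,
deterministically per seed, rejecting symbol-inconsistent overlaps and
verifying every plant against the brute-force matcher. Study texts are
power-of-two lengths {128, 256, 512} with small pattern sets of lengths
2–4, matching the published study conditions; the original evaluation
corpus (subsets of a SARS-CoV-2 gene with unstated accession and
windows) is not recoverable, so synthetic texts stand in for it. Several
test fixtures use patterns containing exactly one `G` planted into a
G-free background so the true occurrence count is exactly the planted
count. What the generator does **not** emulate: real genomic composition
(GC content, repeats, low-complexity regions), ambiguity codes, or
reverse-complement occurrences — so passing tests demonstrate
correctness of the search machinery, not retrieval performance on real
genomes.

## Numerical choices and problem sizes

- Norm tolerance 1e−9 after every operation; unitary round-trip 1e−10;
  closed-form vs. simulated success probabilities compared at 1e−9.
- Measurement sampling by inverse-CDF on the marginal distribution, one
  shared generator per component stream.
- Test problem sizes: exhaustive oracle checks at `N ≤ 64` plus
  randomized sweeps to `N = 512`; end-to-end matrix
  `N ∈ {16, 64, 128, 256, 512} × t ∈ {0, 1, 2, 5, 10}` (pattern length
  per cell chosen so `t` occurrences physically fit); stochastic checks
  use 4,000–10,000 draws against 3σ binomial bands. These sizes exercise
  every code path while keeping the dense state vectors small.

## Known limitations

- Qubit totals and gate counts describe this package's register layouts
  and logical gate applications; wall-clock or memory figures of other
  simulators are out of scope.
- Fixed-precision counting cannot distinguish neighbouring counts
  outside its resolution (see above); feeding an under-estimate to the
  search terminates it early by design (flagged only through the missing
  indices' absence, as the schedule was satisfied).
- Protein alphabets (|Σ| = 20) are unsupported: the encoding assumes
  |Σ| a power of two; a 5-bit code with 12 unused words would need
  sentinel handling the DNA path deliberately avoids.
- Edit-distance (indel) filtering is not implemented; the filter's error
  model is substitution-only.
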