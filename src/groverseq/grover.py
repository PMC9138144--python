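"""Exact-match oracle, Grover amplitude amplification, and the
repeat-until-all-found search loop.

The oracle marks every address whose M-symbol memory word equals the
pattern and whose start index is valid (``i <= N_orig - M``).  One Grover
round is a phase flip on the marked set followed by inversion about the
mean; after ``r`` rounds from a uniform start with ``t`` marked items the
success probability is exactly ``sin^2((2r+1) * arcsin(sqrt(t/N)))``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .sequences import EncodedText, Pattern, EncodingError
from .statevector import QuantumState, GateLog
from . import anf as anf_mod

#: Search spaces at or below this size default to the dense mode in which
#: the data register is physically simulated and the comparator runs as a
#: circuit; above it the memory functions are evaluated classically per
#: address to build the oracle mask.
DENSE_MODE_MAX_N = 64


@dataclass(frozen=True)
class IterationSchedule:
    """Grover iteration count for ``t`` marked items in ``N_search`` states."""

    N_search: int
    t: int
    theta: float
    r_G: int

    def success_probability(self) -> float:
        """Closed form sin^2((2r+1) theta); equals t/N when r = 0."""
        return float(np.sin((2 * self.r_G + 1) * self.theta) ** 2)


def grover_iterations(N_search: int, t: int) -> IterationSchedule:
    """Schedule ``r_G = floor((pi/4) sqrt(N/t))`` iterations.

    Boundary handling: ``t = 0`` searches blind with the single-solution
    count (the outcome is uniform); ``t >= N/2`` uses ``r_G = 0`` since a
    bare measurement already succeeds with probability ``t/N >= 1/2`` while
    a forced amplification round can overshoot past the target state.
    """
    if N_search <= 0 or (N_search & (N_search - 1)) != 0:
        raise ValueError(f"search space size {N_search} is not a power of two")
    if not 0 <= t <= N_search:
        raise ValueError(f"t={t} outside [0, {N_search}]")
    if t == 0:
        theta = 0.0
        r = int(np.floor(np.pi / 4 * np.sqrt(N_search)))
    else:
        theta = float(np.arcsin(np.sqrt(t / N_search)))
        if 2 * t >= N_search:
            r = 0
        else:
            r = max(1, int(np.floor(np.pi / 4 * np.sqrt(N_search / t))))
    return IterationSchedule(N_search=N_search, t=t, theta=theta, r_G=r)


def qem_match_set(
    text: EncodedText, pattern: Pattern, mode: str | None = None
) -> frozenset[int]:
    """Addresses whose M-symbol word equals the pattern (validity-masked).

    ``mode="mask"`` evaluates the memory functions classically per address;
    ``mode="dense"`` runs the comparator as a circuit on a physically
    simulated address+data+flag register set (bitwise equality via X
    conjugation, conjunction via a single multi-controlled X onto the
    comparison qubit).  Both produce the same set by construction of the
    memory; the default picks dense at small N.
    """
    if mode is None:
        mode = "dense" if text.N <= DENSE_MODE_MAX_N else "mask"
    M = pattern.M
    if M > text.n_orig:
        raise EncodingError(f"pattern length {M} exceeds text length {text.n_orig}")
    limit = text.valid_limit(M)
    if mode == "mask":
        words = text.words_int(M)
        hits = np.flatnonzero(words == pattern.bits_int)
        return frozenset(int(i) for i in hits if i <= limit)
    if mode != "dense":
        raise ValueError(f"unknown mode {mode!r}")

    w = M * text.w0
    state = QuantumState([("QA", text.n), ("QD", w), ("COMP", 1)])
    state.init_uniform("QA")
    table = anf_mod.anf_from_text(text, M)
    anf_mod.qmem_load(state, table)
    # Bitwise equality against the classically-held pattern: X where the
    # pattern bit is 0 maps "equal" to |1...1> on QD.
    qd_offset, _ = state.span("QD")
    comp_offset, _ = state.span("COMP")
    pattern_bits = pattern.bits
    for j, bit in enumerate(pattern_bits):
        if bit == "0":
            state.apply_gate("X", qd_offset + j)
    state.apply_gate("CX", comp_offset, controls=range(qd_offset, qd_offset + w))
    for j, bit in enumerate(pattern_bits):
        if bit == "0":
            state.apply_gate("X", qd_offset + j)
    addr = state.sub_indices("QA")
    comp = state.sub_indices("COMP")
    live = np.abs(state.amplitudes) > 0
    matched = frozenset(int(a) for a in np.unique(addr[live & (comp == 1)]))
    return frozenset(i for i in matched if i <= limit)


def grover_search_once(
    N_search: int,
    marked: Iterable[int],
    schedule: IterationSchedule,
    rng: np.random.Generator,
    gate_log: GateLog | None = None,
    trace: list[np.ndarray] | None = None,
) -> int:
    """One prepare-amplify-measure cycle over a uniform search register.

    Returns the measured basis index.  ``trace``, if given, collects the
    amplitude vector after every diffusion (used to check the two-value
    amplitude structure).
    """
    marked = sorted(set(marked))
    n = N_search.bit_length() - 1
    state = QuantumState([("S", n)])
    state.init_uniform("S")
    for _ in range(schedule.r_G):
        state.phase_flip_mask("S", marked)
        state.diffusion("S")
        if trace is not None:
            trace.append(state.amplitudes.copy())
    if gate_log is not None:
        gate_log.merge(state.gate_log)
    return state.measure("S", rng)


@dataclass
class MatchReport:
    """Verified occurrences of one pattern plus search accounting."""

    pattern_id: str
    found: tuple[int, ...] = ()
    t_assumed: int = 0
    grover_applications: int = 0
    retries: int = 0
    aborted: bool = False
    core: int = 0
    wave: int = 0
    balanced_flag: bool = False
    filter: object | None = None  # FilterResult for the filtered algorithm
    gate_log: GateLog | None = None
    trace_rows: list[tuple[int, int, bool]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern_id,
            "core": self.core,
            "wave": self.wave,
            "t_assumed": self.t_assumed,
            "found": list(self.found),
            "grover_applications": self.grover_applications,
            "retries": self.retries,
            "aborted": self.aborted,
            "balanced_flag": self.balanced_flag,
        }


def trace_to_tsv(report: MatchReport) -> str:
    """Measurement trace as TSV: round, measured index, verified flag."""
    header = "round\tmeasured_index\tverified"
    rows = [f"{r}\t{idx}\t{int(ok)}" for r, idx, ok in report.trace_rows]
    return "\n".join([header, *rows]) + "\n"


def retry_budget(t_assumed: int) -> int:
    """Unverified measurements allowed before a search aborts."""
    return 3 * t_assumed + 10


def search_space_loop(
    N_search: int,
    marked: frozenset[int],
    t_assumed: int,
    verify: Callable[[int], bool],
    rng: np.random.Generator,
    gate_log: GateLog | None = None,
    report: MatchReport | None = None,
) -> MatchReport:
    """Enumerate all assumed solutions by repeated amplify-measure-verify.

    After each verified hit the index is excluded from the marked set and
    the schedule recomputed for the remaining count, so the expected number
    of successful rounds is ``t`` and the total oracle cost stays within the
    O(sqrt(N t)) budget.  Unverified measurements count against the retry
    budget; exhaustion flags an abort instead of failing silently.
    """
    if report is None:
        report = MatchReport(pattern_id="")
    report.t_assumed = t_assumed
    remaining = set(marked)
    found: list[int] = []
    budget = retry_budget(t_assumed)
    rounds = 0
    while True:
        t_rem = t_assumed - len(found)
        if t_rem <= 0:
            break
        if report.retries >= budget:
            report.aborted = True
            break
        schedule = grover_iterations(N_search, t_rem)
        idx = grover_search_once(N_search, remaining, schedule, rng, gate_log)
        report.grover_applications += schedule.r_G
        ok = verify(idx) and idx in remaining
        report.trace_rows.append((rounds, idx, ok))
        if ok:
            found.append(idx)
            remaining.discard(idx)
        else:
            report.retries += 1
        rounds += 1
    report.found = tuple(sorted(found))
    return report


def search_all_occurrences(
    text: EncodedText,
    pattern: Pattern,
    t_source: int | str,
    rng: np.random.Generator,
    mode: str | None = None,
    gate_log: GateLog | None = None,
) -> MatchReport:
    """Find every occurrence of ``pattern`` over the full address space.

    ``t_source`` is either a known solution count (int) or one of
    ``"exact"`` / ``"approx"`` (quantum counting) / ``"brute"`` (classical
    fallback).
    """
    marked = qem_match_set(text, pattern, mode=mode)
    N_search = text.N
    t_assumed = resolve_t_source(t_source, N_search, marked, rng)
    report = MatchReport(pattern_id=pattern.id)
    verify = lambda i: (
        i <= text.valid_limit(pattern.M) and text.word_int(i, pattern.M) == pattern.bits_int
    )
    return search_space_loop(
        N_search, marked, t_assumed, verify, rng, gate_log, report
    )


def resolve_t_source(
    t_source: int | str,
    N_search: int,
    marked: frozenset[int],
    rng: np.random.Generator,
) -> int:
    """Turn a t-source designator into an assumed solution count.

    Precedence mirrors the count-then-search pipeline: a user-known value
    beats exact counting beats approximate counting beats the classical
    fallback.
    """
    if isinstance(t_source, (int, np.integer)):
        if t_source < 0:
            raise ValueError("known t must be non-negative")
        return int(t_source)
    from . import counting

    n = N_search.bit_length() - 1
    if t_source == "exact":
        return counting.exact_count(N_search, len(marked), rng=rng).t_hat
    if t_source == "approx":
        r = max(1, n - 2)
        return counting.approx_count(N_search, len(marked), r=r, rng=rng).t_hat
    if t_source == "brute":
        return len(marked)
    raise ValueError(f"unknown t_source {t_source!r}")
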