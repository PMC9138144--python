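"""End-to-end multiple-pattern matching, multi-core scheduling, qubit
accounting, and the CIP/IIP/IMP/Error% evaluation protocol.

Two pipelines are provided.  The position-based pipeline searches each
pattern over the full ``2^n`` address space; the filter-based pipeline
first reduces the space to the ``t`` filtered candidate starts (location
array ``LA``, addressed with ``tq = ceil(log2 t)`` qubits, the oracle
dereferencing ``LA`` before the exact-match predicate).  "Cores" are
emulated as independent simulator instances with disjoint registers and
derived random sub-streams; ``m`` patterns run on ``C`` cores in
``ceil(m/C)`` sequential waves.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequences import EncodedText, Pattern, brute_force_matches
from .statevector import GateLog, QuantumState, derive_rng
from .grover import (
    MatchReport,
    grover_iterations,
    qem_match_set,
    resolve_t_source,
    search_space_loop,
)
from .qaf import FilterResult, qaf_filter

ALGORITHMS = ("enqpbea", "enqbcea")


@dataclass(frozen=True)
class CoreAssignment:
    """Round-robin assignment of patterns to emulated quantum cores."""

    C: int
    assignment: tuple[tuple[int, ...], ...]  # core -> pattern indices, in wave order

    @property
    def waves(self) -> int:
        return max((len(pats) for pats in self.assignment), default=0)

    def placement(self, pattern_index: int) -> tuple[int, int]:
        """(core, wave) of a pattern index."""
        return pattern_index % self.C, pattern_index // self.C


def schedule_patterns(patterns: Sequence[Pattern], C: int) -> CoreAssignment:
    """Distribute m patterns round-robin over C cores (idle cores allowed).

    Reported parallel cost is the per-wave maximum over cores, summed over
    waves.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if len(patterns) < 1:
        raise ValueError("at least one pattern required")
    assignment: list[list[int]] = [[] for _ in range(C)]
    for k in range(len(patterns)):
        assignment[k % C].append(k)
    return CoreAssignment(C=C, assignment=tuple(tuple(a) for a in assignment))


def parallel_cost(reports: Sequence[MatchReport], C: int) -> int:
    """Sum over waves of the maximum per-core Grover applications."""
    waves: dict[int, list[int]] = {}
    for rep in reports:
        waves.setdefault(rep.wave, []).append(rep.grover_applications)
    return sum(max(costs) for costs in waves.values())


def qubits_required(
    algorithm: str,
    n: int,
    M: int | None = None,
    w0: int = 2,
    t: int | None = None,
) -> tuple[int, dict[str, int]]:
    """Register totals per the implementation formulas.

    Position-based pipeline: ``n + M*w0 + 2 + 2`` (address, data-vs-pattern
    comparison, per-symbol flags, comparison + phase ancillas).
    Filter-based pipeline: ``2n + ceil(log2 max(t,1))`` (address + auxiliary
    filtering registers plus the location register).
    """
    if algorithm == "enqpbea":
        if M is None:
            raise ValueError("M required for the position-based layout")
        breakdown = {
            "address": n,
            "data": M * w0,
            "symbol_flags": 2,
            "ancilla": 2,
        }
    elif algorithm == "enqbcea":
        if t is None:
            raise ValueError("t (filtered index count) required for the filtered layout")
        tq = (max(t, 1) - 1).bit_length()
        breakdown = {"address": n, "auxiliary": n, "location": tq}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return sum(breakdown.values()), breakdown


def run_enqpbea(
    text: EncodedText,
    patterns: Sequence[Pattern],
    C: int = 1,
    t_source: int | str | Sequence[int | str] = "exact",
    seed: int = 0,
    mode: str | None = None,
) -> list[MatchReport]:
    """Search every pattern over the full address space, one core each.

    Each (core, wave) slot gets its own simulator instance and derived
    random sub-stream; the shared memory content is read-only.
    """
    sched = schedule_patterns(patterns, C)
    sources = _per_pattern(t_source, len(patterns))
    reports = []
    for k, pattern in enumerate(patterns):
        core, wave = sched.placement(k)
        rng = derive_rng(seed, core, wave)
        gate_log = GateLog()
        marked = qem_match_set(text, pattern, mode=mode)
        t_assumed = resolve_t_source(sources[k], text.N, marked, rng)
        report = MatchReport(pattern_id=pattern.id, core=core, wave=wave)
        verify = _make_verifier(text, pattern)
        search_space_loop(text.N, marked, t_assumed, verify, rng, gate_log, report)
        report.gate_log = gate_log
        reports.append(report)
    return reports


def run_enqbcea(
    text: EncodedText,
    patterns: Sequence[Pattern],
    C: int = 1,
    threshold: int | None = None,
    t_source: int | str | Sequence[int | str] = "exact",
    seed: int = 0,
    mode: str | None = None,
) -> list[MatchReport]:
    """Filter-then-search: candidates from the location array only.

    The search runs over the ``tq``-qubit location register; the oracle
    dereferences ``LA`` (sentinel-padded to ``2^tq``) and conjoins the
    exact-match predicate on the original text.  A near-balanced filtered
    space (marked fraction close to 1/2) is flagged on the report.
    """
    sched = schedule_patterns(patterns, C)
    sources = _per_pattern(t_source, len(patterns))
    reports = []
    for k, pattern in enumerate(patterns):
        core, wave = sched.placement(k)
        rng = derive_rng(seed, core, wave)
        gate_log = GateLog()
        filt = qaf_filter(text, pattern, threshold=threshold, rng=rng)
        report = MatchReport(pattern_id=pattern.id, core=core, wave=wave, filter=filt)
        if filt.t == 0:
            report.found = ()
            reports.append(report)
            continue
        la = filt.padded_LA
        N_search = 1 << filt.tq
        exact = _make_verifier(text, pattern)
        marked_locs = frozenset(
            l for l, addr in enumerate(la) if addr != filt.sentinel and exact(addr)
        )
        frac = len(marked_locs) / N_search
        report.balanced_flag = 0.4 <= frac <= 0.6 and 0 < len(marked_locs) < N_search
        t_assumed = resolve_t_source(sources[k], N_search, marked_locs, rng)
        verify_loc = lambda l, la=la, s=filt.sentinel: la[l] != s and exact(la[l])
        search_space_loop(
            N_search, marked_locs, t_assumed, verify_loc, rng, gate_log, report
        )
        report.found = tuple(sorted(la[l] for l in report.found))
        report.gate_log = gate_log
        reports.append(report)
    return reports


def _per_pattern(t_source, m: int) -> list:
    if isinstance(t_source, (list, tuple)):
        if len(t_source) != m:
            raise ValueError("one t_source per pattern required")
        return list(t_source)
    return [t_source] * m


def _make_verifier(text: EncodedText, pattern: Pattern):
    limit = text.valid_limit(pattern.M)
    target = pattern.bits_int

    def verify(i: int) -> bool:
        return 0 <= i <= limit and text.word_int(i, pattern.M) == target

    return verify


# -- evaluation protocol ---------------------------------------------------


@dataclass
class ErrorStats:
    """Per-measurement tallies of the evaluation protocol.

    ``error_pct = 100 * IIP / (CIP + IIP)``; undefined (``None``) when no
    measurements were performed.  ``IMP`` counts true occurrence indices
    never measured across the whole protocol.
    """

    CIP: int
    IIP: int
    IMP: int

    @property
    def defined(self) -> bool:
        return self.CIP + self.IIP > 0

    @property
    def error_pct(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.IIP / (self.CIP + self.IIP)

    def formatted_error_pct(self) -> str:
        """Error% rounded to one decimal place, table-style."""
        return "undefined" if not self.defined else f"{self.error_pct:.1f}"

    def to_dict(self) -> dict:
        return {
            "CIP": self.CIP,
            "IIP": self.IIP,
            "IMP": self.IMP,
            "error_pct": self.error_pct,
        }


def error_stats(
    measured_indices: Iterable[int], true_indices: Iterable[int]
) -> ErrorStats:
    """Tally CIP/IIP/IMP from a stream of measured start indices."""
    true_set = set(true_indices)
    cip = iip = 0
    seen: set[int] = set()
    for idx in measured_indices:
        if idx in true_set:
            cip += 1
            seen.add(idx)
        else:
            iip += 1
    return ErrorStats(CIP=cip, IIP=iip, IMP=len(true_set - seen))


def run_experiment_protocol(
    text: EncodedText,
    pattern: Pattern,
    algorithm: str = "enqpbea",
    t_source: int | str = "exact",
    R: int = 10,
    I: int = 100,
    seed: int = 0,
    threshold: int | None = None,
    mode: str | None = None,
) -> ErrorStats:
    """R repetitions of I independent single-search-and-measure trials.

    Each trial prepares the uniform state, amplifies with the schedule
    derived from the assumed count, measures once, and classifies the
    outcome as a correctly (CIP) or incorrectly (IIP) identified pattern
    index; ``CIP + IIP = R * I``.  Defaults (10 x 100) give the 1,000-trial
    accounting of the evaluation tables.  The pre-measurement state for a
    fixed schedule is deterministic, so it is computed once and the R*I
    outcomes are drawn from its measurement distribution — exactly the law
    of full re-preparation per trial.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = derive_rng(seed, 101)
    true_set = set(brute_force_matches(text, pattern))

    if algorithm == "enqpbea":
        N_search = text.N
        marked = qem_match_set(text, pattern, mode=mode)
        index_map = None
        sentinel = None
    else:
        filt = qaf_filter(text, pattern, threshold=threshold, rng=rng)
        if filt.t == 0:
            return ErrorStats(CIP=0, IIP=0, IMP=len(true_set))
        N_search = 1 << filt.tq
        la = filt.padded_LA
        exact = _make_verifier(text, pattern)
        marked = frozenset(
            l for l, a in enumerate(la) if a != filt.sentinel and exact(a)
        )
        index_map = la
        sentinel = filt.sentinel

    t_assumed = resolve_t_source(t_source, N_search, marked, rng)
    schedule = grover_iterations(N_search, t_assumed)

    # Amplified pre-measurement distribution (deterministic for the schedule).
    n = N_search.bit_length() - 1
    state = QuantumState([("S", n)])
    state.init_uniform("S")
    for _ in range(schedule.r_G):
        state.phase_flip_mask("S", marked)
        state.diffusion("S")
    probs = state.probabilities("S")

    draws = rng.choice(N_search, size=R * I, p=probs / probs.sum())
    if index_map is not None:
        measured = [
            index_map[d] if index_map[d] != sentinel else -1 for d in draws
        ]
    else:
        measured = [int(d) for d in draws]
    return error_stats(measured, true_set)


# -- result files ----------------------------------------------------------


def reports_to_tsv(reports: Sequence[MatchReport]) -> str:
    header = "pattern\tcore\twave\tt_assumed\tfound\tgrover_applications\tretries\taborted"
    rows = [
        "\t".join(
            [
                r.pattern_id,
                str(r.core),
                str(r.wave),
                str(r.t_assumed),
                ",".join(map(str, r.found)) or "-",
                str(r.grover_applications),
                str(r.retries),
                str(int(r.aborted)),
            ]
        )
        for r in reports
    ]
    return "\n".join([header, *rows]) + "\n"


def reports_to_json(reports: Sequence[MatchReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)
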