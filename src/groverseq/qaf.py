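"""Approximate filtering of candidate pattern start positions.

Filtering marks, for every text position holding one of the pattern's
distinct symbols, the position minus that symbol's first offset within the
pattern as a candidate start; candidates within a symbol-level Hamming
distance threshold of the pattern survive into the location array ``LA``.
Completeness is unconditional: an exact occurrence produces a zero-distance
candidate at its own start, so it survives any threshold >= 0.

The quantum procedure collects ``LA`` by repeatedly re-preparing the marked
superposition, merging amplitudes, and measuring the auxiliary register;
here that collection loop is simulated (measurement order is random, the
final set is not), while the closed-form candidate set is the contract.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .sequences import EncodedText, Pattern, hamming_distance


def default_threshold(M: int) -> int:
    """Hamming-distance threshold ceil(M/4): small enough to keep the
    filtered space well below N, any value preserves completeness."""
    return math.ceil(M / 4)


@dataclass(frozen=True)
class FilterResult:
    """The location array of candidate starts produced by filtering.

    ``LA`` is sorted ascending; ``padded_LA`` extends it to length
    ``2**tq`` with a sentinel address (``2**n``, outside the text) that the
    downstream oracle never matches — the success-probability dilution this
    causes is reported, not hidden.
    """

    LA: tuple[int, ...]
    threshold: int
    SL: dict[str, int]
    sentinel: int
    partial: bool = False
    rounds_used: int = 0

    @property
    def t(self) -> int:
        return len(self.LA)

    @property
    def tq(self) -> int:
        """Location-register width ceil(log2 max(t, 1))."""
        return (max(self.t, 1) - 1).bit_length()

    @property
    def padded_LA(self) -> tuple[int, ...]:
        size = 1 << self.tq
        return self.LA + (self.sentinel,) * (size - self.t)

    def to_text(self) -> str:
        """One candidate index per line (the classically-stored array)."""
        return "\n".join(str(i) for i in self.LA) + "\n"


def distinct_symbol_offsets(pattern: Pattern) -> dict[str, int]:
    """First offset of each distinct pattern symbol (the SL array)."""
    sl: dict[str, int] = {}
    for j, s in enumerate(pattern.symbols):
        sl.setdefault(s, j)
    return sl


def candidate_starts(
    text: EncodedText, pattern: Pattern, SL: dict[str, int] | None = None
) -> frozenset[int]:
    """Start candidates ``i - j`` for every text position i holding a
    distinct pattern symbol with first offset j; out-of-range discarded."""
    if SL is None:
        SL = distinct_symbol_offsets(pattern)
    limit = text.valid_limit(pattern.M)
    out = set()
    for i in range(text.n_orig):
        j = SL.get(text.symbols[i])
        if j is None:
            continue
        c = i - j
        if 0 <= c <= limit:
            out.add(c)
    return frozenset(out)


def _candidate_weights(
    text: EncodedText, pattern: Pattern, SL: dict[str, int]
) -> dict[int, int]:
    """Marking multiplicity per candidate (the merged amplitude weight)."""
    limit = text.valid_limit(pattern.M)
    weights: dict[int, int] = {}
    for i in range(text.n_orig):
        j = SL.get(text.symbols[i])
        if j is None:
            continue
        c = i - j
        if 0 <= c <= limit:
            weights[c] = weights.get(c, 0) + 1
    return weights


def qaf_filter(
    text: EncodedText,
    pattern: Pattern,
    threshold: int | None = None,
    rng: np.random.Generator | None = None,
    max_rounds: int = 50_000,
) -> FilterResult:
    """Filter candidate starts through the Hamming-distance threshold.

    The target set is the closed form
    ``{ i in candidates : HD(text[i..i+M-1], pattern) <= threshold }``.
    When ``rng`` is given, the measure-and-collect loop is simulated:
    candidates are drawn with probability proportional to their marking
    multiplicity until either the whole set is collected or ``max_rounds``
    consecutive measurements add nothing (then a warning is issued and the
    partial flag set).  The randomness affects only collection order.
    """
    if threshold is None:
        threshold = default_threshold(pattern.M)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    M = pattern.M
    SL = distinct_symbol_offsets(pattern)
    weights = _candidate_weights(text, pattern, SL)
    passing = {
        c: w
        for c, w in weights.items()
        if hamming_distance(text.symbols[c : c + M], pattern.symbols) <= threshold
    }
    target = frozenset(passing)
    sentinel = text.N
    rounds = 0
    partial = False
    if rng is not None and target:
        cands = np.array(sorted(passing), dtype=np.int64)
        p = np.array([passing[c] for c in cands], dtype=float)
        p /= p.sum()
        collected: set[int] = set()
        stale = 0
        while collected != target and stale < max_rounds:
            batch = rng.choice(cands, size=min(max_rounds - stale, 256), p=p)
            for c in batch:
                rounds += 1
                if int(c) in collected:
                    stale += 1
                    if stale >= max_rounds:
                        break
                else:
                    collected.add(int(c))
                    stale = 0
            if collected == target:
                break
        if collected != target:
            partial = True
            warnings.warn(
                f"collection stopped after {rounds} rounds with "
                f"{len(target) - len(collected)} candidate(s) uncollected",
                stacklevel=2,
            )
            target = frozenset(collected)
    return FilterResult(
        LA=tuple(sorted(target)),
        threshold=threshold,
        SL=SL,
        sentinel=sentinel,
        partial=partial,
        rounds_used=rounds,
    )
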