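"""Shared fixtures: the published worked-example memory functions and
synthetic-text helpers."""
from __future__ import annotations

import numpy as np
import pytest

from groverseq import ANFTable, Pattern, SyntheticSpec, generate_synthetic_text

# The eight published 4-variable memory functions of the worked example
# (one per output bit of an M=4 DNA word; T0 is the most significant
# address bit; [] is the constant-1 term).
WORKED_EXAMPLE_MONOMIALS: dict[int, list[list[int]]] = {
    0: [[2], [0, 1, 2]],
    1: [[3], [2], [2, 3], [1, 2], [1, 2, 3], [0, 2], [0, 2, 3], [0, 1, 3],
        [0, 1, 2], [0, 1, 2, 3]],
    2: [[3], [2], [0, 1, 3], [0, 1, 2]],
    3: [[], [2, 3], [1, 3], [1, 2, 3], [0, 3], [0, 2, 3], [0, 1], [0, 1, 2, 3]],
    4: [[], [2], [0, 1], [0, 1, 2]],
    5: [[], [2], [2, 3], [1], [1, 3], [1, 2], [1, 2, 3], [0], [0, 3], [0, 2],
        [0, 1, 3], [0, 1, 2, 3]],
    6: [[], [3], [2], [0, 2, 3]],
    7: [[], [3], [0, 2], [0, 1], [0, 1, 3], [0, 1, 2]],
}


def worked_example_anf() -> ANFTable:
    monomials = tuple(
        frozenset(frozenset(m) for m in WORKED_EXAMPLE_MONOMIALS[b])
        for b in range(8)
    )
    return ANFTable(n_vars=4, n_funcs=8, monomials=monomials)


@pytest.fixture
def example_anf() -> ANFTable:
    return worked_example_anf()


def random_text_and_pattern(
    rng: np.random.Generator, N_orig: int, M: int
) -> tuple[str, str]:
    """A random DNA text and random pattern of the given sizes."""
    sym = np.array(list("ATCG"))
    text = "".join(sym[rng.integers(0, 4, size=N_orig)])
    pattern = "".join(sym[rng.integers(0, 4, size=M)])
    return text, pattern


# Patterns containing exactly one G, planted into a G-free background, so
# the brute-force occurrence count equals the planted count exactly.
PATTERN_BY_M = {1: "G", 2: "AG", 3: "TAG", 4: "TAGA"}
G_FREE = {"A": 1 / 3, "T": 1 / 3, "C": 1 / 3}


def spread_positions(length: int, M: int, t: int) -> list[int]:
    """t pattern starts spread through the text, spaced so that no extra
    occurrence can arise from abutting plants."""
    if t == 0:
        return []
    stride = max(M if M == 1 else M + 1, (length - M) // t)
    pos = [i * stride for i in range(t)]
    if pos[-1] + M > length:
        raise ValueError(f"cannot fit {t} x {M}-mers in length {length}")
    return pos


def exact_t_text(length: int, M: int, t: int, seed: int):
    """Synthetic text with exactly t occurrences of PATTERN_BY_M[M]."""
    pattern = PATTERN_BY_M[M]
    return (
        generate_synthetic_text(
            SyntheticSpec(
                length=length,
                planted={pattern: spread_positions(length, M, t)},
                seed=seed,
                background=G_FREE,
            )
        ),
        Pattern(pattern),
    )
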