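"""Algebraic-normal-form synthesis of the quantum-memory load unitary.

The memory holds, for each ``n``-bit address ``i``, the ``w = M*w0``-bit
substring word starting at text index ``i``.  Each output bit is a Boolean
function of the address bits, written in algebraic normal form: an XOR of
AND-monomials obtained from the truth-table column by the binary Möbius
transform.  Loading is the XOR of the addressed word into an initially-zero
data register, entangled with the address register — a self-inverse basis
permutation.

Address variable ``T0`` is the most significant address bit, matching the
``T0 = 2^(n-1)`` weighting of the address integer.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import EncodedText
from .statevector import QuantumState

Monomial = frozenset  # frozenset[int]; empty set denotes the constant-1 term


@dataclass(frozen=True)
class ANFTable:
    """Per output bit, the monomials whose XOR computes that bit.

    ``monomials[b]`` is a frozenset of monomials for output bit ``b``; each
    monomial is a frozenset of address-variable indices (``T0`` = index 0 =
    MSB), with the empty frozenset denoting the constant 1.
    """

    n_vars: int
    n_funcs: int
    monomials: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.monomials) != self.n_funcs:
            raise ValueError("one monomial set required per output bit")

    # -- evaluation --------------------------------------------------------

    def evaluate(self, address: str) -> str:
        """Output word at one address as AND-then-XOR over the monomials."""
        if len(address) != self.n_vars or set(address) - {"0", "1"}:
            raise ValueError(
                f"address must be {self.n_vars} bits, got {address!r}"
            )
        bits = [c == "1" for c in address]
        out = []
        for mons in self.monomials:
            acc = False
            for m in mons:
                acc ^= all(bits[v] for v in m)
            out.append("1" if acc else "0")
        return "".join(out)

    def truth_table(self) -> np.ndarray:
        """Evaluate at every address: the inverse of `anf_synthesize`."""
        n = self.n_vars
        table = np.zeros((1 << n, self.n_funcs), dtype=np.uint8)
        for b, mons in enumerate(self.monomials):
            col = np.zeros(1 << n, dtype=np.uint8)
            for m in mons:
                spectrum_idx = 0
                for v in m:
                    spectrum_idx |= 1 << (n - 1 - v)
                col[spectrum_idx] = 1
            table[:, b] = _mobius_transform(col)  # involution: ANF -> values
        return table

    def words_int(self) -> np.ndarray:
        """All 2^n output words as integers (leftmost output bit = MSB)."""
        table = self.truth_table()
        shifts = self.n_funcs - 1 - np.arange(self.n_funcs)
        return (table.astype(np.int64) << shifts).sum(axis=1)

    # -- plain-text serialization -------------------------------------------

    def to_text(self) -> str:
        """One line per output bit; monomials semicolon-separated, each a
        comma-separated variable list like ``T0,T2`` ('1' = constant term)."""
        lines = [f"# anf n_vars={self.n_vars} n_funcs={self.n_funcs}"]
        for b, mons in enumerate(self.monomials):
            parts = []
            for m in sorted(mons, key=lambda m: (len(m), sorted(m))):
                parts.append("1" if not m else ",".join(f"T{v}" for v in sorted(m)))
            lines.append(f"{b}: " + ("; ".join(parts) if parts else "-"))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ANFTable":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split()
        n_vars = int(header[2].split("=")[1])
        n_funcs = int(header[3].split("=")[1])
        monomials: list[frozenset] = []
        for ln in lines[1:]:
            _, _, body = ln.partition(":")
            body = body.strip()
            mons: set[frozenset] = set()
            if body != "-":
                for part in body.split(";"):
                    part = part.strip()
                    mons.add(
                        frozenset()
                        if part == "1"
                        else frozenset(int(v.lstrip("T")) for v in part.split(","))
                    )
            monomials.append(frozenset(mons))
        return cls(n_vars, n_funcs, tuple(monomials))


def _mobius_transform(column: np.ndarray) -> np.ndarray:
    """In-place-style binary Möbius transform (XOR over subsets).

    Self-inverse: maps truth-table values to ANF coefficients and back.
    O(2^n * n) butterfly.
    """
    a = column.astype(np.uint8).copy()
    size = a.size
    step = 1
    while step < size:
        blocks = a.reshape(-1, 2 * step)
        blocks[:, step:] ^= blocks[:, :step]
        step *= 2
    return a


def truth_table_from_text(text: EncodedText, M: int) -> np.ndarray:
    """The 2^n x w bit table whose row i is word(i, M) (cyclic wrap)."""
    words = text.words_int(M)
    w = M * text.w0
    shifts = w - 1 - np.arange(w)
    return ((words[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def anf_synthesize(table: np.ndarray) -> ANFTable:
    """Möbius-transform each truth-table column into its monomial set.

    Spectrum index ``s`` corresponds to the monomial over the variables
    whose address bits are set in ``s`` (T0 = MSB); ``s = 0`` is the
    constant-1 term.
    """
    table = np.asarray(table, dtype=np.uint8)
    rows, n_funcs = table.shape
    if rows == 0 or (rows & (rows - 1)) != 0:
        raise ValueError(f"row count {rows} is not a power of two")
    n = rows.bit_length() - 1
    monomials = []
    for b in range(n_funcs):
        spectrum = _mobius_transform(table[:, b])
        mons = set()
        for s in np.flatnonzero(spectrum):
            mons.add(
                frozenset(v for v in range(n) if (int(s) >> (n - 1 - v)) & 1)
            )
        monomials.append(frozenset(mons))
    return ANFTable(n_vars=n, n_funcs=n_funcs, monomials=tuple(monomials))


def anf_evaluate(anf: ANFTable, address: str) -> str:
    """Functional form of :meth:`ANFTable.evaluate`."""
    return anf.evaluate(address)


def anf_from_text(text: EncodedText, M: int) -> ANFTable:
    """Synthesize the memory functions for all M-symbol words of a text."""
    return anf_synthesize(truth_table_from_text(text, M))


def qmem_load(
    state: QuantumState, anf: ANFTable, qa: str = "QA", qd: str = "QD"
) -> QuantumState:
    """XOR the addressed memory word into the data register.

    For every address basis component ``|i>_QA``, the data register receives
    ``word(i)``; address amplitudes are untouched.  The permutation is an
    XOR, hence self-inverse: applying the load twice restores the data
    register.  Raises if the data register holds anything other than zeros
    or the already-loaded words (states where XOR-loading is meaningful).
    """
    _, n = state.span(qa)
    _, w = state.span(qd)
    if n != anf.n_vars or w != anf.n_funcs:
        raise ValueError("register widths do not match the ANF table")
    words = anf.words_int()
    addr = state.sub_indices(qa)
    data = state.sub_indices(qd)
    support = np.abs(state.amplitudes) > 0
    bad = support & (data != 0) & (data != words[addr])
    if np.any(bad):
        raise ValueError(
            "data register is neither zero nor the loaded word; "
            "XOR load would scramble it"
        )
    shift_qd, _ = state._shift_mask(qd)
    g = np.arange(state.amplitudes.size, dtype=np.int64)
    target = g ^ (words[addr] << shift_qd)
    new = np.empty_like(state.amplitudes)
    new[target] = state.amplitudes
    state.amplitudes = new
    state.gate_log.record("CX", max(n, 1), times=anf.n_funcs)
    return state
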