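"""Minimal dense state-vector engine with named registers and gate accounting.

Convention: qubit 0 is the most significant bit of the basis index, so a
register occupying a contiguous qubit span maps to a contiguous bit field of
the global index.  Gates are applied as direct amplitude updates (the logged
gate families {H, X, Rz, CZ(k), CX(k)} mirror a QASM-style taxonomy; no
Toffoli-ladder decomposition is performed).
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

NORM_TOL = 1e-9

_SQRT2INV = 1.0 / np.sqrt(2.0)


class RegisterError(ValueError):
    """Unknown register or invalid qubit addressing."""


class GateLog:
    """Monotone counter of applied gate families.

    Multi-controlled families are keyed as ``CZ(k)`` / ``CX(k)`` where ``k``
    is the number of controls.
    """

    def __init__(self) -> None:
        self.counts: Counter[str] = Counter()

    def record(self, family: str, k: int | None = None, times: int = 1) -> None:
        key = family if k is None else f"{family}({k})"
        self.counts[key] += times

    def merge(self, other: "GateLog") -> None:
        self.counts.update(other.counts)

    def dump(self) -> str:
        """Plain-text one-line-per-family summary (QASM-summary style)."""
        return "\n".join(f"{k}\t{v}" for k, v in sorted(self.counts.items()))

    def total(self) -> int:
        return sum(self.counts.values())


class QuantumState:
    """Complex amplitude vector over the basis states of named registers.

    Parameters
    ----------
    registers : sequence of (name, width)
        Declared in qubit order; spans are contiguous and disjoint.
    """

    def __init__(self, registers: Sequence[tuple[str, int]]):
        offset = 0
        self.registers: dict[str, tuple[int, int]] = {}
        for name, width in registers:
            if width < 0:
                raise RegisterError(f"negative width for register {name!r}")
            if name in self.registers:
                raise RegisterError(f"duplicate register {name!r}")
            self.registers[name] = (offset, width)
            offset += width
        self.num_qubits = offset
        self.amplitudes = np.zeros(1 << offset, dtype=np.complex128)
        self.amplitudes[0] = 1.0
        self.gate_log = GateLog()
        self._subidx_cache: dict[str, np.ndarray] = {}

    # -- register plumbing -------------------------------------------------

    def span(self, name: str) -> tuple[int, int]:
        try:
            return self.registers[name]
        except KeyError:
            raise RegisterError(f"unknown register {name!r}") from None

    def _shift_mask(self, name: str) -> tuple[int, int]:
        offset, width = self.span(name)
        shift = self.num_qubits - offset - width
        return shift, (1 << width) - 1

    def sub_indices(self, name: str) -> np.ndarray:
        """Register sub-index of every global basis state (cached)."""
        if name not in self._subidx_cache:
            shift, mask = self._shift_mask(name)
            g = np.arange(self.amplitudes.size, dtype=np.int64)
            self._subidx_cache[name] = (g >> shift) & mask
        return self._subidx_cache[name]

    def norm(self) -> float:
        return float(np.sum(np.abs(self.amplitudes) ** 2))

    def check_norm(self) -> None:
        if abs(self.norm() - 1.0) > NORM_TOL:
            raise ValueError(f"state norm {self.norm()} out of tolerance")

    def probabilities(self, name: str) -> np.ndarray:
        """Marginal measurement distribution of a register."""
        _, width = self.span(name)
        p = np.bincount(
            self.sub_indices(name),
            weights=np.abs(self.amplitudes) ** 2,
            minlength=1 << width,
        )
        return p

    # -- gates -------------------------------------------------------------

    def _view(self) -> np.ndarray:
        return self.amplitudes.reshape((2,) * self.num_qubits)

    def apply_gate(
        self,
        gate: str,
        target: int,
        controls: Iterable[int] = (),
        theta: float | None = None,
    ) -> "QuantumState":
        """Apply H, X, Rz(theta), or a (multi-)controlled X/Z.

        ``gate`` is one of ``{"H", "X", "Rz", "CX", "CZ"}``; for CX/CZ the
        control count is taken from ``controls``.
        """
        controls = tuple(controls)
        qubits = (target, *controls)
        for q in qubits:
            if not (0 <= q < self.num_qubits):
                raise RegisterError(f"qubit index {q} out of range")
        if len(set(qubits)) != len(qubits):
            raise RegisterError("overlapping control/target sets")

        if self.num_qubits == 0:
            return self
        view = self._view()
        idx0: list[object] = [slice(None)] * self.num_qubits
        for c in controls:
            idx0[c] = 1
        idx1 = list(idx0)
        idx0[target] = 0
        idx1[target] = 1
        s0, s1 = tuple(idx0), tuple(idx1)

        if gate == "H":
            if controls:
                raise RegisterError("controlled H is not in the gate set")
            a0 = view[s0].copy()
            a1 = view[s1]
            view[s0] = (a0 + a1) * _SQRT2INV
            view[s1] = (a0 - a1) * _SQRT2INV
            self.gate_log.record("H")
        elif gate == "X" or gate == "CX":
            a0 = view[s0].copy()
            view[s0] = view[s1]
            view[s1] = a0
            if controls:
                self.gate_log.record("CX", len(controls))
            else:
                self.gate_log.record("X")
        elif gate == "CZ":
            view[s1] = -view[s1]
            self.gate_log.record("CZ", len(controls))
        elif gate == "Rz":
            if theta is None:
                raise ValueError("Rz requires theta")
            if controls:
                raise RegisterError("controlled Rz is not in the gate set")
            view[s0] = view[s0] * np.exp(-0.5j * theta)
            view[s1] = view[s1] * np.exp(0.5j * theta)
            self.gate_log.record("Rz")
        else:
            raise ValueError(f"unknown gate {gate!r}")
        return self

    def init_uniform(self, name: str) -> "QuantumState":
        """Hadamard every qubit of a register.

        From a basis state this yields the equal-amplitude superposition
        1/sqrt(2^k); H is self-inverse, so a second call restores the
        basis state.
        """
        offset, width = self.span(name)
        for q in range(offset, offset + width):
            self.apply_gate("H", q)
        return self

    def phase_flip_mask(self, name: str, marked: Iterable[int]) -> "QuantumState":
        """Negate the amplitude of every basis state whose register sub-index
        is in ``marked`` (tensor-consistent across the other registers).

        Logged as a single multi-controlled-Z application.
        """
        marked = np.asarray(sorted(set(marked)), dtype=np.int64)
        _, width = self.span(name)
        if marked.size:
            if marked.min() < 0 or marked.max() >= (1 << width):
                raise RegisterError("marked index out of range")
            sel = np.isin(self.sub_indices(name), marked)
            self.amplitudes[sel] = -self.amplitudes[sel]
        self.gate_log.record("CZ", max(width - 1, 0))
        return self

    def diffusion(self, name: str) -> "QuantumState":
        """Inversion about the mean on one register: 2|psi0><psi0| - I.

        Applied as a direct amplitude update; logged as the standard
        H^k X^k CZ(k-1) X^k H^k realization.
        """
        offset, width = self.span(name)
        pre = 1 << offset
        mid = 1 << width
        post = self.amplitudes.size // (pre * mid)
        a = self.amplitudes.reshape(pre, mid, post)
        mean = a.mean(axis=1, keepdims=True)
        self.amplitudes = (2.0 * mean - a).reshape(-1)
        self.gate_log.record("H", times=2 * width)
        self.gate_log.record("X", times=2 * width)
        self.gate_log.record("CZ", max(width - 1, 0))
        return self

    def measure(self, name: str, rng: np.random.Generator, collapse: bool = True) -> int:
        """Sample a register outcome; optionally collapse the state."""
        self.check_norm()
        p = self.probabilities(name)
        u = rng.random()
        outcome = int(np.searchsorted(np.cumsum(p), u, side="right"))
        outcome = min(outcome, p.size - 1)
        if collapse:
            sel = self.sub_indices(name) == outcome
            self.amplitudes[~sel] = 0.0
            nrm = np.sqrt(np.sum(np.abs(self.amplitudes) ** 2))
            self.amplitudes /= nrm
        return outcome


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-component random stream from a root seed.

    Used to give every emulated core / pattern / repetition its own
    independent sub-stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))
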