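"""Fixed-width binary encoding of biological text, classical ground truth,
and synthetic fixture generation.

A DNA text of length ``N_orig`` is padded up to the next power of two
``N = 2**n`` so that text start positions can live in superposition over an
``n``-qubit address register.  Each symbol is encoded as a ``w0``-bit word
(``w0 = log2 |alphabet|``, 2 for DNA with A=00, T=01, C=10, G=11); the
``M``-symbol substring starting at index ``i`` is the concatenation of the
per-symbol codes, leftmost symbol first.  Indices are 0-based and valid
pattern starts live in the inclusive range ``[0, N_orig - M]``; words at
later indices are defined by cyclic wrap (so downstream truth tables are
total) but are masked out of every match set by the oracle.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class EncodingError(ValueError):
    """A symbol outside the alphabet, or structurally invalid input."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered power-of-two alphabet with a fixed binary code per symbol.

    Symbol order defines the code: symbol ``k`` encodes to ``k`` written in
    ``bits_per_symbol`` binary digits.  The default DNA alphabet is
    ``("A", "T", "C", "G")`` giving A=00, T=01, C=10, G=11.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.symbols)
        if k == 0 or (k & (k - 1)) != 0:
            raise EncodingError(f"alphabet size {k} is not a power of two")
        if len(set(self.symbols)) != k:
            raise EncodingError("alphabet symbols are not distinct")

    @property
    def bits_per_symbol(self) -> int:
        return max(1, (len(self.symbols) - 1).bit_length())

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise EncodingError(f"symbol {symbol!r} not in alphabet") from None

    def code(self, symbol: str) -> str:
        return format(self.index(symbol), f"0{self.bits_per_symbol}b")

    def decode(self, bits: str) -> str:
        if len(bits) != self.bits_per_symbol:
            raise EncodingError(f"code {bits!r} has wrong width")
        return self.symbols[int(bits, 2)]


#: Default 2-bit DNA alphabet (A=00, T=01, C=10, G=11).
DNA = Alphabet(("A", "T", "C", "G"))


@dataclass(frozen=True)
class Pattern:
    """A query pattern with its bit encoding."""

    symbols: str
    alphabet: Alphabet = DNA
    id: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise EncodingError("empty pattern")
        for pos, s in enumerate(self.symbols):
            if s not in self.alphabet.symbols:
                raise EncodingError(f"invalid symbol {s!r} at position {pos}")
        if not self.id:
            object.__setattr__(self, "id", self.symbols)

    @property
    def M(self) -> int:
        return len(self.symbols)

    @property
    def bits(self) -> str:
        return "".join(self.alphabet.code(s) for s in self.symbols)

    @property
    def bits_int(self) -> int:
        return int(self.bits, 2)


class EncodedText:
    """A power-of-two-length symbol sequence with per-index substring words.

    Attributes
    ----------
    symbols : str
        The padded text (length ``N = 2**n``); the original text is the
        prefix of length ``n_orig``.
    n_orig : int
        Length of the un-padded input text.
    """

    def __init__(self, symbols: str, n_orig: int, alphabet: Alphabet = DNA):
        self.symbols = symbols
        self.n_orig = n_orig
        self.alphabet = alphabet
        self.N = len(symbols)
        if self.N == 0 or (self.N & (self.N - 1)) != 0:
            raise EncodingError(f"text length {self.N} is not a power of two")
        self.n = self.N.bit_length() - 1
        self._codes = np.array(
            [alphabet.index(s) for s in symbols], dtype=np.int64
        )
        self._word_cache: dict[int, np.ndarray] = {}

    @property
    def w0(self) -> int:
        return self.alphabet.bits_per_symbol

    def valid_limit(self, M: int) -> int:
        """Largest valid start index for an ``M``-symbol pattern."""
        return self.n_orig - M

    def words_int(self, M: int) -> np.ndarray:
        """All ``N`` substring words of ``M`` symbols as integers (cyclic wrap)."""
        if M < 1:
            raise EncodingError("M must be >= 1")
        if M > self.n_orig:
            raise EncodingError(f"pattern length {M} exceeds text length {self.n_orig}")
        if M not in self._word_cache:
            idx = (np.arange(self.N)[:, None] + np.arange(M)[None, :]) % self.N
            sym = self._codes[idx]
            shifts = self.w0 * (M - 1 - np.arange(M))
            self._word_cache[M] = (sym << shifts).sum(axis=1)
        return self._word_cache[M]

    def word_int(self, i: int, M: int) -> int:
        return int(self.words_int(M)[i])

    def word(self, i: int, M: int) -> str:
        """Bit string of length ``M * w0`` encoding symbols[i .. i+M-1]."""
        return format(self.word_int(i, M), f"0{M * self.w0}b")

    def decode_word(self, bits: str) -> str:
        w0 = self.w0
        return "".join(
            self.alphabet.decode(bits[k : k + w0]) for k in range(0, len(bits), w0)
        )

    def __len__(self) -> int:
        return self.N

    def __repr__(self) -> str:
        return f"EncodedText(N={self.N}, n={self.n}, n_orig={self.n_orig})"


def encode_text(raw: str, alphabet: Alphabet = DNA) -> EncodedText:
    """Encode a raw symbol sequence, padding up to the next power of two.

    Padding repeats the first alphabet symbol; padded and overhanging start
    indices never appear in a match set because every oracle conjoins the
    validity mask ``i <= valid_limit(M)``.
    """
    if not raw:
        raise EncodingError("empty text")
    for pos, s in enumerate(raw):
        if s not in alphabet.symbols:
            raise EncodingError(f"invalid symbol {s!r} at position {pos}")
    n_orig = len(raw)
    N = 1 << max(0, (n_orig - 1).bit_length())
    padded = raw + alphabet.symbols[0] * (N - n_orig)
    return EncodedText(padded, n_orig, alphabet)


def brute_force_matches(text: EncodedText, pattern: Pattern) -> tuple[int, ...]:
    """Exhaustive-scan occurrence indices (the classical oracle for t).

    Returns every ``i`` in ``[0, valid_limit]`` with symbol-wise equality;
    overlapping occurrences are counted.
    """
    M = pattern.M
    if M > text.n_orig:
        raise EncodingError(f"pattern length {M} exceeds text length {text.n_orig}")
    limit = text.valid_limit(M)
    return tuple(
        i for i in range(limit + 1) if text.symbols[i : i + M] == pattern.symbols
    )


def hamming_distance(a: Sequence[str] | str, b: Sequence[str] | str) -> int:
    """Symbol-level Hamming distance (replacement at unit cost)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic text with planted pattern occurrences.

    ``planted`` maps a pattern string to the start indices at which it must
    occur; overlapping plants are allowed only when symbol-consistent.
    ``background`` is the symbol distribution for unconstrained positions
    (uniform over the alphabet by default, emulating a random DNA text).
    """

    length: int
    planted: Mapping[str, Iterable[int]] = field(default_factory=dict)
    seed: int = 0
    background: Mapping[str, float] | None = None
    alphabet: Alphabet = DNA


def generate_synthetic_text(spec: SyntheticSpec) -> EncodedText:
    """Deterministically build a text realizing every planted occurrence."""
    slots: list[str | None] = [None] * spec.length
    for pat, indices in spec.planted.items():
        for start in indices:
            if start < 0 or start + len(pat) > spec.length:
                raise ValueError(
                    f"planted {pat!r} at {start} does not fit in length {spec.length}"
                )
            for j, s in enumerate(pat):
                cur = slots[start + j]
                if cur is not None and cur != s:
                    raise ValueError(
                        f"conflicting plant at position {start + j}: "
                        f"{cur!r} vs {s!r} (pattern {pat!r} at {start})"
                    )
                slots[start + j] = s
    symbols = list(spec.alphabet.symbols)
    if spec.background is None:
        probs = np.full(len(symbols), 1.0 / len(symbols))
    else:
        probs = np.array([spec.background.get(s, 0.0) for s in symbols], float)
        probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(len(symbols), size=spec.length, p=probs)
    raw = "".join(
        slots[i] if slots[i] is not None else symbols[draws[i]]
        for i in range(spec.length)
    )
    text = encode_text(raw, spec.alphabet)
    for pat, indices in spec.planted.items():
        found = set(brute_force_matches(text, Pattern(pat, spec.alphabet)))
        missing = set(indices) - found
        if missing:  # cannot happen by construction; guards future edits
            raise AssertionError(f"plant verification failed for {pat!r}: {missing}")
    return text


def load_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA (multi-record, via Bio.SeqIO) or single-sequence plain text.

    Returns ``[(record_id, uppercased_sequence), ...]``.
    """
    with open(path) as fh:
        content = fh.read()
    stripped = content.strip()
    if not stripped:
        raise EncodingError(f"empty input file: {path}")
    if stripped.startswith(">"):
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
        if not records or any(not seq for _, seq in records):
            raise EncodingError(f"FASTA file {path} has a record with no sequence")
        return records
    seq = "".join(stripped.split()).upper()
    return [(os.path.basename(os.fspath(path)), seq)]
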