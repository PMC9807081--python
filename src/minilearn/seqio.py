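"""Sequence ingestion, integer encoding, and synthetic fixture generation.

Every downstream component operates on :class:`EncodedSequence` — an integer-coded
sequence over a finite alphabet — so the rest of the package never touches raw
strings. Fixture generators produce the three synthetic sequence classes used
throughout the test and evaluation harness: i.i.d. uniform random sequences,
tandem-repeat sequences emulating centromeric repetitiveness, and
planted-periodic sequences in which a unique sentinel k-mer occurs exactly every
w k-mer positions.

Coordinates are 0-based throughout: k-mer position ``i`` covers characters
``[i, i+k)`` and window ``t`` covers k-mer positions ``[t, t+w)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "DNA",
    "EncodedSequence",
    "SketchParams",
    "read_fasta",
    "write_fasta",
    "one_hot",
    "kmer_code",
    "kmer_codes",
    "make_random_sequence",
    "make_repeat_sequence",
    "make_planted_periodic_sequence",
]


@dataclasses.dataclass(frozen=True)
class Alphabet:
    """An ordered finite alphabet; the default is DNA (A, C, G, T)."""

    symbols: tuple[str, ...] = ("A", "C", "G", "T")

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet must contain at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("alphabet symbols must be single characters")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def encode(self, text: str) -> np.ndarray:
        """Encode a string to an integer code vector; raises on foreign characters."""
        idx = self.index
        try:
            return np.array([idx[c] for c in text.upper()], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"character {exc.args[0]!r} not in alphabet") from None

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.symbols[int(c)] for c in codes)


#: The default DNA alphabet shared across the package.
DNA = Alphabet()


@dataclasses.dataclass(frozen=True)
class EncodedSequence:
    """Integer-coded sequence: ``codes[i]`` is the alphabet index of character i."""

    codes: np.ndarray
    id: str = "seq"
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1:
            raise ValueError("codes must be a 1-D vector")
        if codes.size and (codes.min() < 0 or codes.max() >= self.alphabet.size):
            raise ValueError("codes contain invalid alphabet indices")

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def length(self) -> int:
        return len(self)

    def decode(self) -> str:
        return self.alphabet.decode(self.codes)

    def slice(self, start: int, stop: int, id: str | None = None) -> "EncodedSequence":
        """A view-like subsequence covering characters [start, stop)."""
        return EncodedSequence(
            self.codes[start:stop],
            id=id if id is not None else f"{self.id}:{start}-{stop}",
            alphabet=self.alphabet,
        )

    def num_kmers(self, k: int) -> int:
        return max(0, len(self) - k + 1)


@dataclasses.dataclass(frozen=True)
class SketchParams:
    """The (k, w) sketch configuration tied to a sequence of l k-mers.

    ``lw = l - w + 1`` is the number of (w,k)-windows; window t covers k-mer
    positions [t, t+w), i.e. w + k - 1 characters.
    """

    k: int
    w: int
    l: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.w < 2:
            raise ValueError("w must be >= 2")
        if self.l < self.w:
            raise ValueError(f"need l >= w (got l={self.l}, w={self.w})")

    @property
    def lw(self) -> int:
        return self.l - self.w + 1

    @property
    def window_chars(self) -> int:
        return self.w + self.k - 1

    @classmethod
    def for_sequence(cls, seq: EncodedSequence, k: int, w: int) -> "SketchParams":
        return cls(k=k, w=w, l=seq.num_kmers(k))


# ---------------------------------------------------------------------------
# FASTA I/O


def _segments(codes_ok: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield maximal [start, stop) runs where codes_ok is True."""
    ok = np.asarray(codes_ok, dtype=bool)
    if not ok.size:
        return
    diff = np.diff(ok.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if ok[0]:
        starts.insert(0, 0)
    if ok[-1]:
        stops.append(ok.size)
    yield from zip(starts, stops)


def read_fasta(
    path: str | Path,
    alphabet: Alphabet = DNA,
    ambiguity_policy: str = "split",
) -> list[EncodedSequence]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Lowercase characters are upcased. Characters outside the alphabet (e.g. IUPAC
    ambiguity codes) are handled per ``ambiguity_policy``:

    - ``"split"``: each maximal run of alphabet characters becomes its own record,
      suffixed ``/<start>`` with the 0-based character offset;
    - ``"error"``: raise :class:`ValueError` naming the record and offset.
    """
    if ambiguity_policy not in ("split", "error"):
        raise ValueError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    idx = alphabet.index
    out: list[EncodedSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        text = str(record.seq).upper()
        codes = np.fromiter((idx.get(c, -1) for c in text), dtype=np.int64, count=len(text))
        bad = codes < 0
        if not bad.any():
            out.append(EncodedSequence(codes, id=record.id, alphabet=alphabet))
            continue
        if ambiguity_policy == "error":
            off = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {record.id!r}: character {text[off]!r} at offset {off} "
                f"not in alphabet"
            )
        for start, stop in _segments(~bad):
            out.append(
                EncodedSequence(codes[start:stop], id=f"{record.id}/{start}", alphabet=alphabet)
            )
    return out


def write_fasta(path: str | Path, seqs: Sequence[EncodedSequence], width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            text = seq.decode()
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Encodings


def one_hot(seq: EncodedSequence, alphabet: Alphabet | None = None) -> np.ndarray:
    """One-hot encode to a (sigma, length) float32 matrix; row = alphabet index."""
    alphabet = alphabet or seq.alphabet
    mat = np.zeros((alphabet.size, len(seq)), dtype=np.float32)
    mat[seq.codes, np.arange(len(seq))] = 1.0
    return mat


def kmer_code(seq: EncodedSequence, i: int, k: int) -> int:
    """Base-sigma big-endian integer code of the k-mer at position i.

    Equal codes iff equal k-mer strings (injective for fixed k).
    """
    if not (0 <= i <= len(seq) - k):
        raise IndexError(f"k-mer position {i} out of range for length {len(seq)}, k={k}")
    sigma = seq.alphabet.size
    code = 0
    for c in seq.codes[i : i + k]:
        code = code * sigma + int(c)
    return code


def kmer_codes(seq: EncodedSequence, k: int) -> np.ndarray:
    """Vectorized :func:`kmer_code` for every position: shape (l,), dtype uint64."""
    l = seq.num_kmers(k)
    if l <= 0:
        return np.zeros(0, dtype=np.uint64)
    sigma = np.uint64(seq.alphabet.size)
    if seq.alphabet.size ** k > 2**63:
        raise ValueError(f"sigma^k overflows 64-bit codes (sigma={sigma}, k={k})")
    codes = seq.codes.astype(np.uint64)
    out = np.zeros(l, dtype=np.uint64)
    for j in range(k):
        out = out * sigma + codes[j : j + l]
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures


def make_random_sequence(
    length: int, alphabet: Alphabet = DNA, seed: int | np.random.Generator = 0, id: str = "random"
) -> EncodedSequence:
    """I.i.d. uniform random sequence; deterministic for a fixed seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, alphabet.size, size=length, dtype=np.int64)
    return EncodedSequence(codes, id=id, alphabet=alphabet)


def make_repeat_sequence(
    unit_length: int,
    copies: int,
    mutation_rate: float = 0.0,
    alphabet: Alphabet = DNA,
    seed: int | np.random.Generator = 0,
    id: str = "repeat",
) -> EncodedSequence:
    """Tandem repeat of a random unit; each position independently resampled
    with probability ``mutation_rate`` (1.0 degenerates to a random sequence)."""
    if unit_length < 1 or copies < 1:
        raise ValueError("unit_length and copies must be >= 1")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    unit = rng.integers(0, alphabet.size, size=unit_length, dtype=np.int64)
    codes = np.tile(unit, copies)
    if mutation_rate > 0:
        mask = rng.random(codes.size) < mutation_rate
        codes[mask] = rng.integers(0, alphabet.size, size=int(mask.sum()), dtype=np.int64)
    return EncodedSequence(codes, id=id, alphabet=alphabet)


def make_planted_periodic_sequence(
    k: int,
    w: int,
    n_periods: int,
    alphabet: Alphabet = DNA,
    seed: int | np.random.Generator = 0,
    id: str = "planted",
) -> EncodedSequence:
    """Sequence in which one sentinel k-mer occurs at k-mer positions
    0, w, 2w, ... and nowhere else; background is i.i.d. random with stray
    sentinel occurrences rejected and resampled.

    Requires ``k >= 8`` for the 4-letter alphabet (so a sentinel absent from a
    random background is easy to reserve) and ``w >= k`` (so planted copies
    never overlap one another).
    """
    sigma = alphabet.size
    if sigma == 4 and k < 8:
        raise ValueError("need k >= 8 for sigma=4 so the sentinel is rare in background")
    if sigma**k < 4 * w * n_periods:
        raise ValueError("sigma^k too small to reserve a sentinel for this length")
    if w < k:
        raise ValueError("need w >= k so planted sentinel copies do not overlap")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    rng = np.random.default_rng(seed)
    sentinel = rng.integers(0, sigma, size=k, dtype=np.int64)
    l = w * n_periods  # number of k-mer positions
    n_chars = l + k - 1
    codes = rng.integers(0, sigma, size=n_chars, dtype=np.int64)
    plant_positions = np.arange(0, l, w)
    for p in plant_positions:
        codes[p : p + k] = sentinel

    seq = EncodedSequence(codes, id=id, alphabet=alphabet)
    sent_code = kmer_code(EncodedSequence(sentinel, alphabet=alphabet), 0, k)
    planted = set(int(p) for p in plant_positions)
    for _ in range(1000):
        occ = np.flatnonzero(kmer_codes(seq, k) == np.uint64(sent_code))
        stray = [int(p) for p in occ if int(p) not in planted]
        if not stray:
            break
        for p in stray:
            # resample one character of the stray occurrence that lies outside
            # every planted copy (exists because plants are >= w >= k apart)
            candidates = [
                i
                for i in range(p, p + k)
                if not any(q <= i < q + k for q in planted)
            ]
            if not candidates:  # fully covered by plants: impossible since w >= k
                continue
            i = int(rng.choice(candidates))
            old = codes[i]
            new = int(rng.integers(0, sigma - 1))
            codes[i] = new if new < old else new + 1
        seq = EncodedSequence(codes, id=id, alphabet=alphabet)
    else:  # pragma: no cover - rejection loop virtually always terminates fast
        raise RuntimeError("failed to eliminate stray sentinel occurrences")
    return seq
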