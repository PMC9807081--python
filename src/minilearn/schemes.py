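"""The discrete minimizer core.

A minimizer scheme with parameters (k, w) slides a window of w consecutive
k-mers along the sequence and selects, from each window, the k-mer of lowest
priority score, breaking ties by the leftmost position. The union of selected
positions is the sketch L(S; m); its quality is the density factor

    D = |L| * (w + 1) / lw,          lw = l - w + 1 windows,

which approximates the number of k-mers selected per window. The theoretical
floor is 1 + 1/w (one pick per w windows); a random ordering yields D ~= 2.

MIN-selection is the canonical convention: low score = high priority. The
max-pool formulation used by some implementations is the mirror s -> 1 - s and
produces identical sketches (regression-tested).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import DNA, Alphabet, EncodedSequence, SketchParams, kmer_codes

__all__ = [
    "ScoreAssignment",
    "Sketch",
    "SelectionTrace",
    "DensityReport",
    "select_positions",
    "select_positions_oracle",
    "density_factor",
    "sketch_kmer_stats",
    "random_ordering_scores",
    "frequency_ordering_scores",
    "exhaustive_optimal_density",
    "export_total_order",
    "write_sketch_bed",
]

SCORE_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class ScoreAssignment:
    """Per-k-mer-position priority scores in [0, 1], one per k-mer of S."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1:
            raise ValueError("scores must be a 1-D vector")
        if scores.size and (scores.min() < -SCORE_TOL or scores.max() > 1 + SCORE_TOL):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclasses.dataclass(frozen=True)
class Sketch:
    """Strictly increasing selected k-mer positions plus the (k, w) parameters."""

    positions: np.ndarray
    params: SketchParams

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def size(self) -> int:
        return int(self.positions.size)

    def validate(self) -> None:
        """Assert the scheme invariants: window coverage and sketch-size bounds."""
        p = self.params
        if self.size < -(-p.lw // p.w) or self.size > p.lw:
            raise AssertionError("sketch size outside [ceil(lw/w), lw]")
        # every window [t, t+w) must contain a selected position
        idx = np.searchsorted(self.positions, np.arange(p.lw))
        covered = (idx < self.size) & (self.positions[np.minimum(idx, self.size - 1)] < np.arange(p.lw) + p.w)
        if not covered.all():
            raise AssertionError("window coverage violated")


@dataclasses.dataclass(frozen=True)
class SelectionTrace:
    """Per-window picks m_t and change indicators gamma_t (gamma_0 = 1)."""

    picks: np.ndarray
    changes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "picks", np.asarray(self.picks, dtype=np.int64))
        object.__setattr__(self, "changes", np.asarray(self.changes, dtype=np.int64))


@dataclasses.dataclass
class DensityReport:
    """Sketch summary: D = sketch_size * (w+1) / lw, plus unique k-mer count."""

    k: int
    w: int
    l: int
    lw: int
    sketch_size: int
    density_factor: float
    unique_kmers: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DensityReport":
        p = Path(str(text_or_path))
        text = p.read_text() if p.is_file() else str(text_or_path)
        return cls(**json.loads(text))


def _trace_from_picks(picks: np.ndarray, params: SketchParams) -> tuple[Sketch, SelectionTrace]:
    changes = np.empty(picks.size, dtype=np.int64)
    changes[0] = 1
    changes[1:] = picks[1:] != picks[:-1]
    positions = np.unique(picks)
    sketch = Sketch(positions=positions, params=params)
    return sketch, SelectionTrace(picks=picks, changes=changes)


def select_positions(
    scores: ScoreAssignment, params: SketchParams, chunk: int = 1 << 20
) -> tuple[Sketch, SelectionTrace]:
    """Leftmost-minimum selection for every window; vectorized.

    Ties are exact float equality, broken leftmost, which makes the scheme
    forward (picks never move left as the window slides).
    """
    s = scores.scores
    if len(scores) != params.l:
        raise ValueError(f"scores length {len(scores)} != l {params.l}")
    w, lw = params.w, params.lw
    picks = np.empty(lw, dtype=np.int64)
    for start in range(0, lw, chunk):
        stop = min(start + chunk, lw)
        view = sliding_window_view(s[start : stop + w - 1], w)
        picks[start:stop] = np.argmin(view, axis=1) + np.arange(start, stop)
    return _trace_from_picks(picks, params)


def select_positions_oracle(
    scores: ScoreAssignment, params: SketchParams
) -> tuple[Sketch, SelectionTrace]:
    """Naive reference: an explicit per-window O(lw*w) scan in pure Python."""
    s = [float(x) for x in scores.scores]
    if len(s) != params.l:
        raise ValueError(f"scores length {len(s)} != l {params.l}")
    w, lw = params.w, params.lw
    picks = []
    for t in range(lw):
        best = t
        for j in range(t + 1, t + w):
            if s[j] < s[best]:
                best = j
        picks.append(best)
    return _trace_from_picks(np.array(picks, dtype=np.int64), params)


def density_factor(sketch: Sketch) -> DensityReport:
    """Density factor D = |positions| * (w+1) / lw of a sketch."""
    p = sketch.params
    return DensityReport(
        k=p.k,
        w=p.w,
        l=p.l,
        lw=p.lw,
        sketch_size=sketch.size,
        density_factor=sketch.size * (p.w + 1) / p.lw,
    )


def sketch_kmer_stats(seq: EncodedSequence, sketch: Sketch, k: int | None = None) -> DensityReport:
    """Density report with the number of distinct selected k-mer strings filled in."""
    k = k if k is not None else sketch.params.k
    report = density_factor(sketch)
    codes = kmer_codes(seq, k)
    report.unique_kmers = int(np.unique(codes[sketch.positions]).size)
    return report


# ---------------------------------------------------------------------------
# Baseline orderings


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Deterministic 64-bit mixer (splitmix64 finalizer)."""
    x = x.astype(np.uint64)
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def random_ordering_scores(seq: EncodedSequence, k: int, seed: int = 0) -> ScoreAssignment:
    """A uniformly random k-mer ordering realized as a seeded hash score.

    Each distinct k-mer gets the same pseudo-random score at every occurrence
    (a consistent assignment), so this is the classical random-minimizer
    baseline with expected density factor ~= 2 on random sequences.
    """
    codes = kmer_codes(seq, k)
    salt = _splitmix64(np.array([seed], dtype=np.uint64))[0]
    h = _splitmix64(codes ^ salt)
    scores = (h >> np.uint64(11)).astype(np.float64) * 2.0**-53
    return ScoreAssignment(scores)


def frequency_ordering_scores(seq: EncodedSequence, k: int) -> ScoreAssignment:
    """Score each position by its k-mer's occurrence count in S, min-max
    normalized to [0, 1] (rare k-mers rank first under MIN-selection)."""
    codes = kmer_codes(seq, k)
    _, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
    freq = counts[inverse].astype(np.float64)
    lo, hi = freq.min(), freq.max()
    if hi == lo:
        return ScoreAssignment(np.full(freq.size, 0.5))
    return ScoreAssignment((freq - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# Exhaustive search and ordering export


def exhaustive_optimal_density(
    seq: EncodedSequence, k: int, w: int, alphabet: Alphabet | None = None
) -> tuple[float, tuple[int, ...]]:
    """Enumerate all total orders of the sigma^k k-mers and return the minimum
    density factor plus one optimal ordering (k-mer code -> rank).

    Only tractable for tiny alphabets: requires sigma^k <= 8 (at most 8! = 40320
    orderings).
    """
    alphabet = alphabet or seq.alphabet
    n_kmers = alphabet.size**k
    if n_kmers > 8:
        raise ValueError(f"sigma^k = {n_kmers} > 8: exhaustive enumeration refused")
    params = SketchParams.for_sequence(seq, k=k, w=w)
    codes = kmer_codes(seq, k).astype(np.int64)
    best_d = np.inf
    best_order: tuple[int, ...] = tuple(range(n_kmers))
    denom = max(n_kmers - 1, 1)
    for perm in itertools.permutations(range(n_kmers)):
        ranks = np.empty(n_kmers, dtype=np.float64)
        ranks[list(perm)] = np.arange(n_kmers, dtype=np.float64)
        scores = ScoreAssignment(ranks[codes] / denom)
        sketch, _ = select_positions(scores, params)
        d = sketch.size * (w + 1) / params.lw
        if d < best_d:
            best_d = d
            best_order = perm
    return float(best_d), best_order


def export_total_order(
    scores_fn: Callable[[str], float],
    k: int,
    alphabet: Alphabet = DNA,
    out: str | Path | None = None,
) -> list[tuple[str, float, int]]:
    """Materialize the total order encoded by a consistent k-mer score function.

    All sigma^k k-mers are sorted ascending by score, ties broken by
    lexicographic (alphabet) order, and returned / written as (kmer, score,
    0-based rank) rows. Guarded at sigma^k <= 4^12.
    """
    n_kmers = alphabet.size**k
    if n_kmers > 4**12:
        raise ValueError(
            f"sigma^k = {n_kmers} exceeds the enumeration guard (4^12); "
            "score k-mers on the fly instead"
        )
    kmers = ["".join(p) for p in itertools.product(alphabet.symbols, repeat=k)]
    scored = sorted((float(scores_fn(m)), m) for m in kmers)
    rows = [(m, s, rank) for rank, (s, m) in enumerate(scored)]
    if out is not None:
        with open(out, "w") as fh:
            fh.write("kmer\tscore\trank\n")
            for m, s, rank in rows:
                fh.write(f"{m}\t{s:.17g}\t{rank}\n")
    return rows


def write_sketch_bed(sketch: Sketch, seq_id: str, path: str | Path) -> None:
    """Write selected k-mer intervals as BED3 (0-based half-open)."""
    k = sketch.params.k
    with open(path, "w") as fh:
        for p in sketch.positions:
            fh.write(f"{seq_id}\t{p}\t{p + k}\n")
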