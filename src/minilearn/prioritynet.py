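"""PriorityNet: a consistency-guaranteeing convolutional k-mer scorer.

The network f maps a one-hot encoded sequence to one priority score per k-mer
position. Its first convolution has kernel size exactly k and every subsequent
layer has kernel size 1, so the score at position i is a deterministic function
of characters [i, i+k) alone. This architecture *guarantees consistency*: one
k-mer can never receive different scores at different occurrences, hence any
weight setting encodes a valid minimizer ordering. The final layer outputs a
single channel through a sigmoid, so scores lie strictly inside (0, 1).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import ConvStack
from .schemes import ScoreAssignment
from .seqio import DNA, Alphabet, EncodedSequence, kmer_codes, one_hot

__all__ = ["PriorityNetConfig", "PriorityNet", "consistency_check"]


@dataclasses.dataclass(frozen=True)
class PriorityNetConfig:
    """Architecture of the scorer.

    ``k`` is the first-layer receptive field (the k-mer length); ``channels``
    are the embedding widths of the hidden convolutions (all kernel size 1).
    """

    k: int
    channels: tuple[int, ...] = (256, 64, 16)
    alphabet_size: int = 4

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.channels or any(c < 1 for c in self.channels):
            raise ValueError("channels must be positive")

    @property
    def kernel_sizes(self) -> tuple[int, ...]:
        # first kernel k, all subsequent kernels 1: the consistency guarantee
        return (self.k,) + (1,) * len(self.channels)


class PriorityNet:
    """The scorer f(S; alpha); weights alpha live in ``stack.params``."""

    def __init__(self, config: PriorityNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        # Hidden layers use fan-in scaled init; the output head is scaled down
        # so initial scores sit in a narrow band around 1/2. The induced
        # ordering is still a non-degenerate pseudo-random total order (density
        # ~2 on random sequences, like a random minimizer), but little k-mer
        # noise has to be unlearned before the scorer can track a template.
        self.stack = ConvStack(
            c_in=config.alphabet_size,
            channels=config.channels,
            kernels=config.kernel_sizes,
            rng=rng,
            head="sigmoid",
            head_scale=0.1,
        )

    @property
    def params(self) -> list[np.ndarray]:
        return self.stack.params

    def set_params(self, flat: list[np.ndarray]) -> None:
        self.stack.set_params(flat)

    def forward(self, seq: EncodedSequence, keep_cache: bool = False):
        """Score every k-mer of ``seq``; output length l = len(seq) - k + 1.

        With ``keep_cache`` the activation cache for :meth:`backward` is also
        returned.
        """
        if len(seq) < self.config.k:
            raise ValueError(f"sequence length {len(seq)} < k = {self.config.k}")
        x = one_hot(seq)
        if x.shape[0] != self.config.alphabet_size:
            raise ValueError("alphabet size mismatch with network input channels")
        return self.stack.forward(x, keep_cache=keep_cache)

    def backward(self, cache, scores: np.ndarray, dscores: np.ndarray) -> list[np.ndarray]:
        """Gradients of sum(dscores * f) w.r.t. the weights alpha."""
        return self.stack.backward(cache, scores, dscores)

    def score_assignment(self, seq: EncodedSequence) -> ScoreAssignment:
        return ScoreAssignment(self.forward(seq).astype(np.float64))


def consistency_check(score_fn, seq: EncodedSequence, k: int) -> float:
    """Max within-group score range over groups of duplicate k-mers.

    ``score_fn`` maps an EncodedSequence to a per-position score vector. For a
    consistent scorer (equal k-mers => equal scores) the result is 0 up to
    float32 noise; values above ~1e-6 indicate a broken architecture.
    """
    scores = np.asarray(score_fn(seq), dtype=np.float64)
    codes = kmer_codes(seq, k)
    if scores.size != codes.size:
        raise ValueError("score vector length does not match the number of k-mers")
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    sorted_scores = scores[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes) != 0) + 1
    max_dev = 0.0
    for grp in np.split(sorted_scores, boundaries):
        if grp.size > 1:
            max_dev = max(max_dev, float(grp.max() - grp.min()))
    return max_dev
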