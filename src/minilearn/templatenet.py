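"""TemplateNet: low-density periodic template score assignments.

A template is a periodic function h: R -> [0, 1] with fundamental period w
whose minima, if unique per period and aligned to the integer grid, induce a
sketch with density factor 1 + 1/w + o(1) — the theoretical floor — on any
sufficiently long sequence (lw >> w^2). Two parameterizations are provided:

- the **ensemble** model: a sigmoid of an amplitude-weighted combination of w
  sines with fixed integer phase shifts, h(t) = sigmoid(sum_phi beta_phi *
  sin(2 pi (t + phi) / w)), with beta on the probability simplex (realized by
  softmax over unconstrained logits). The dominant phase phi_max = argmax beta
  controls the offset of the template minima;
- the **truncated Fourier** model: h(t) = sigmoid(beta0 + sum_{r<=R}
  [a_r sin(2 pi r t / w) + b_r cos(2 pi r t / w)]), compact for large w, but
  generic parameters may place minima between integer grid points.

Both can be augmented with a sequence-conditioned positional phase shift,
g_i = h(i + delta * xi_i(S)), where xi is a small convolutional noise network
with a tanh head (entries in [-1, 1]) mirroring PriorityNet's kernel pattern so
noise is also consistent across duplicate k-mers. With delta = 0 the model
space coincides exactly with the pure periodic template family.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import ConvStack, sigmoid
from .schemes import ScoreAssignment
from .seqio import EncodedSequence, one_hot

__all__ = [
    "EnsembleTemplateParams",
    "FourierTemplateParams",
    "PhaseShiftConfig",
    "NoiseNet",
    "ensemble_h",
    "fourier_h",
    "template_forward",
    "init_template",
]


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


@dataclasses.dataclass
class EnsembleTemplateParams:
    """Amplitude logits of length w; realized amplitudes are their softmax,
    guaranteeing beta_phi >= 0 and sum_phi beta_phi = 1."""

    logits: np.ndarray
    w: int

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.logits.shape != (self.w,):
            raise ValueError(f"need w={self.w} logits, got shape {self.logits.shape}")

    @property
    def amplitudes(self) -> np.ndarray:
        return _softmax(self.logits)

    @property
    def dominant_phase(self) -> int:
        return int(np.argmax(self.amplitudes))

    @property
    def params(self) -> list[np.ndarray]:
        return [self.logits]


@dataclasses.dataclass
class FourierTemplateParams:
    """Constant term beta0 plus R paired sine/cosine amplitudes at integer
    multiples of the fundamental frequency 1/w."""

    beta0: np.ndarray  # shape (1,)
    sin_amp: np.ndarray  # shape (R,)
    cos_amp: np.ndarray  # shape (R,)
    w: int

    def __post_init__(self) -> None:
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=np.float64))
        self.sin_amp = np.asarray(self.sin_amp, dtype=np.float64)
        self.cos_amp = np.asarray(self.cos_amp, dtype=np.float64)
        if self.sin_amp.shape != self.cos_amp.shape:
            raise ValueError("sin and cos amplitude vectors must have equal length")
        if not np.all(np.isfinite(self.beta0)) or not np.all(np.isfinite(self.sin_amp)):
            raise ValueError("amplitudes must be finite")

    @property
    def order(self) -> int:
        return int(self.sin_amp.size)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.beta0, self.sin_amp, self.cos_amp]


@dataclasses.dataclass
class PhaseShiftConfig:
    """Maximum phase perturbation delta (in k-mer position units) and the
    noise network producing per-position offsets xi in [-1, 1]."""

    delta: float = 0.0
    noise: "NoiseNet | None" = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


class NoiseNet:
    """Sequence-conditioned noise xi(S; gamma): conv stack with first kernel k,
    then 1x1 layers, tanh head. The final layer is zero-initialized so training
    starts from the exact periodic template (xi == 0)."""

    def __init__(self, k: int, channels: tuple[int, ...] = (64, 16), seed: int = 0,
                 alphabet_size: int = 4):
        self.k = k
        rng = np.random.default_rng(seed)
        self.stack = ConvStack(
            c_in=alphabet_size,
            channels=channels,
            kernels=(k,) + (1,) * len(channels),
            rng=rng,
            head="tanh",
            zero_init_last=True,
        )

    @property
    def params(self) -> list[np.ndarray]:
        return self.stack.params

    def set_params(self, flat: list[np.ndarray]) -> None:
        self.stack.set_params(flat)

    def forward(self, seq: EncodedSequence, keep_cache: bool = False):
        if len(seq) < self.k:
            raise ValueError(f"sequence length {len(seq)} < k = {self.k}")
        return self.stack.forward(one_hot(seq), keep_cache=keep_cache)


# ---------------------------------------------------------------------------
# Template evaluation


def ensemble_h(params: EnsembleTemplateParams, t: np.ndarray | float) -> np.ndarray | float:
    """h(t) = sigmoid( sum_phi beta_phi sin(2 pi (t + phi) / w) ); period w."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    beta = params.amplitudes
    phi = np.arange(params.w, dtype=np.float64)
    pre = np.sin(2.0 * np.pi * (t_arr[:, None] + phi[None, :]) / params.w) @ beta
    out = sigmoid(pre)
    return out if np.ndim(t) else float(out[0])


def fourier_h(params: FourierTemplateParams, t: np.ndarray | float) -> np.ndarray | float:
    """h(t) = sigmoid( beta0 + sum_r [a_r sin(2 pi r t/w) + b_r cos(2 pi r t/w)] )."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    pre = np.full(t_arr.shape, params.beta0[0])
    if params.order:
        r = np.arange(1, params.order + 1, dtype=np.float64)
        ang = 2.0 * np.pi * t_arr[:, None] * r[None, :] / params.w
        pre = pre + np.sin(ang) @ params.sin_amp + np.cos(ang) @ params.cos_amp
    out = sigmoid(pre)
    return out if np.ndim(t) else float(out[0])


def init_template(kind: str, w: int, seed: int = 0,
                  fourier_order: int | None = None):
    """Seeded random template parameters for either family.

    Initialization gives the template a clear dominant phase (a random
    component boosted well above the rest) so it starts inside the regime
    where its minima are unique per period. The uniform-amplitude point, where
    the sines cancel and h degenerates to the constant 1/2, is a stationary
    trap for the matching objective and is deliberately avoided.
    """
    rng = np.random.default_rng(seed)
    if kind == "ensemble":
        logits = rng.standard_normal(w) * 0.5
        logits[rng.integers(w)] += 6.0
        return EnsembleTemplateParams(logits=logits, w=w)
    if kind == "fourier":
        order = fourier_order if fourier_order is not None else min(8, w // 2)
        sin_amp = rng.standard_normal(order) * 0.2
        cos_amp = rng.standard_normal(order) * 0.2
        psi = rng.uniform(0.0, 2.0 * np.pi)  # random phase of the fundamental
        sin_amp[0] += np.cos(psi)
        cos_amp[0] += np.sin(psi)
        return FourierTemplateParams(
            beta0=rng.standard_normal(1) * 0.2,
            sin_amp=sin_amp,
            cos_amp=cos_amp,
            w=w,
        )
    raise ValueError(f"unknown template kind {kind!r}")


class _TemplateCache:
    """Intermediate values retained for the backward pass."""

    __slots__ = ("t", "g", "params", "phase", "noise_cache", "xi", "kind")

    def __init__(self, **kw):
        for name in self.__slots__:
            setattr(self, name, kw.get(name))


def template_forward(
    params: EnsembleTemplateParams | FourierTemplateParams,
    l: int | None = None,
    phase: PhaseShiftConfig | None = None,
    seq: EncodedSequence | None = None,
    offset: int = 0,
    keep_cache: bool = False,
):
    """Evaluate the template score assignment g_i = h(offset + i + delta*xi_i).

    With ``delta = 0`` (the default) this is the exact periodic model
    g_i = h(offset + i) on the 0-based grid i = 0 .. l-1. ``offset`` anchors a
    subsequence view to its absolute start coordinate in the full sequence, so
    template targets seen at a given genomic position are identical no matter
    which sampled view covers it; any global integer shift is absorbed by the
    learned phase. A positive delta requires ``seq`` so the noise network can
    condition on it.
    """
    phase = phase or PhaseShiftConfig()
    kind = "ensemble" if isinstance(params, EnsembleTemplateParams) else "fourier"
    xi = None
    noise_cache = None
    if phase.delta > 0:
        if seq is None or phase.noise is None:
            raise ValueError("delta > 0 requires a sequence and a noise network")
        xi, noise_cache = phase.noise.forward(seq, keep_cache=True)
        l = xi.size
    else:
        if l is None:
            if seq is None:
                raise ValueError("need l or seq to size the template")
            l = len(seq) - (phase.noise.k if phase.noise else 1) + 1
    if params.w > l:
        raise ValueError(f"need l >= w (got l={l}, w={params.w})")
    t = np.arange(offset, offset + l, dtype=np.float64)
    if xi is not None:
        t = t + phase.delta * xi.astype(np.float64)
    h = ensemble_h if kind == "ensemble" else fourier_h
    g = np.asarray(h(params, t))
    if keep_cache:
        return g, _TemplateCache(t=t, g=g, params=params, phase=phase,
                                 noise_cache=noise_cache, xi=xi, kind=kind)
    return g


def template_backward(cache: _TemplateCache, dg: np.ndarray):
    """Gradients of sum(dg * g) w.r.t. template params (and noise weights).

    Returns ``(param_grads, noise_grads)`` where ``param_grads`` matches
    ``params.params`` order and ``noise_grads`` is None when delta = 0.
    """
    p = cache.params
    t = cache.t
    dpre = dg * cache.g * (1.0 - cache.g)  # through the sigmoid
    w = p.w
    if cache.kind == "ensemble":
        beta = p.amplitudes
        ang = 2.0 * np.pi * (t[:, None] + np.arange(w)[None, :]) / w
        s = np.sin(ang)
        v = dpre @ s  # d loss / d beta_phi
        dlogits = beta * (v - float(beta @ v))  # softmax Jacobian
        param_grads = [dlogits]
        dpre_dt = (np.cos(ang) * (2.0 * np.pi / w)) @ beta
    else:
        r = np.arange(1, p.order + 1, dtype=np.float64)
        ang = 2.0 * np.pi * t[:, None] * r[None, :] / w
        dbeta0 = np.array([dpre.sum()])
        dsin = dpre @ np.sin(ang)
        dcos = dpre @ np.cos(ang)
        param_grads = [dbeta0, dsin, dcos]
        coef = 2.0 * np.pi * r / w
        dpre_dt = (np.cos(ang) * coef[None, :]) @ p.sin_amp \
            - (np.sin(ang) * coef[None, :]) @ p.cos_amp
    noise_grads = None
    if cache.xi is not None and cache.phase.delta > 0:
        dxi = dpre * dpre_dt * cache.phase.delta
        noise_grads = cache.phase.noise.stack.backward(
            cache.noise_cache, cache.xi, dxi.astype(np.float32)
        )
    return param_grads, noise_grads


def template_score_assignment(params, l: int, phase: PhaseShiftConfig | None = None,
                              seq: EncodedSequence | None = None) -> ScoreAssignment:
    return ScoreAssignment(np.asarray(template_forward(params, l=l, phase=phase, seq=seq)))
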