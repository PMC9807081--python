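"""Joint training of the scorer/template twin networks.

Each epoch draws N random subsequences of the target sequence, computes the
matching loss between the scorer output f and the template output g on each
(summed over positions, averaged over the batch), and takes one Adam step on
all parameters jointly — scorer weights alpha, template amplitudes beta, and
noise-network weights gamma when a positional phase shift is enabled. Every
``eval_every`` epochs the full-sequence density factor is measured by hard
MIN-selection on f, and the best-density checkpoint is retained.

Selection validity is architectural: any scorer weight setting yields a
consistent score assignment and hence a valid minimizer scheme, so every
evaluated sketch satisfies window coverage regardless of training state.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from ._nn import Adam
from .objective import (
    ObjectiveConfig,
    dm_distance,
    dm_gradient_constants,
    dm_gradient_template,
    l2_distance,
    l2_gradients,
)
from .prioritynet import PriorityNet, PriorityNetConfig
from .schemes import DensityReport, ScoreAssignment, Sketch, select_positions, sketch_kmer_stats
from .seqio import EncodedSequence, SketchParams
from .templatenet import (
    EnsembleTemplateParams,
    FourierTemplateParams,
    NoiseNet,
    PhaseShiftConfig,
    init_template,
    template_backward,
    template_forward,
)

__all__ = [
    "TrainConfig",
    "TrainResult",
    "sample_batch",
    "train",
    "evaluate_full",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "minilearn-ckpt-1"


@dataclasses.dataclass
class TrainConfig:
    """Optimization protocol.

    Defaults follow the standard recipe: 600 epochs of Adam at learning rate
    5e-3 on batches of N=10 subsequences of 500*(w+k) characters, lambda = 1,
    ensemble template with no phase shift, full-sequence evaluation every 20
    epochs.
    """

    epochs: int = 600
    batch_size: int = 10
    l_sub: int | None = None  # characters; default 500 * (w + k)
    lr: float = 5e-3
    template: str = "ensemble"
    delta: float = 0.0
    fourier_order: int | None = None
    eval_every: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.lr <= 0 or self.eval_every < 1:
            raise ValueError("invalid training configuration")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    def resolved_l_sub(self, params: SketchParams) -> int:
        l_sub = self.l_sub if self.l_sub is not None else 500 * (params.w + params.k)
        return max(l_sub, params.window_chars)


@dataclasses.dataclass
class TrainResult:
    """Traces and checkpoints of one training run."""

    loss_trace: list[float]
    eval_epochs: list[int]
    density_trace: list[float]
    best_density: float
    best_epoch: int
    best_state: dict
    final_state: dict
    initial_report: DensityReport
    best_report: DensityReport


def _sample_offsets(seq: EncodedSequence, n: int, l_sub: int,
                    rng: np.random.Generator) -> np.ndarray:
    max_start = len(seq) - l_sub
    if max_start <= 0:
        return np.zeros(n, dtype=np.int64)
    return rng.integers(0, max_start + 1, size=n)


def sample_batch(
    seq: EncodedSequence, n: int, l_sub: int, rng: np.random.Generator
) -> list[EncodedSequence]:
    """N subsequence views of ``l_sub`` characters at uniform random offsets.

    If the sequence is shorter than ``l_sub`` the whole sequence is used for
    every batch element.
    """
    if len(seq) <= l_sub:
        return [seq] * n
    offsets = _sample_offsets(seq, n, l_sub, rng)
    return [seq.slice(int(o), int(o) + l_sub) for o in offsets]


def _template_param_list(tpl) -> list[np.ndarray]:
    return tpl.params


def _state_dict(net: PriorityNet, tpl, noise: NoiseNet | None, cfg: TrainConfig,
                sketch_params: SketchParams) -> dict:
    state = {
        "version": CHECKPOINT_VERSION,
        "k": sketch_params.k,
        "w": sketch_params.w,
        "channels": list(net.config.channels),
        "alphabet_size": net.config.alphabet_size,
        "template": cfg.template,
        "delta": cfg.delta,
        "seed": cfg.seed,
        "priority_weights": [p.copy() for p in net.params],
        "template_params": [p.copy() for p in tpl.params],
        "noise_weights": [p.copy() for p in noise.params] if noise is not None else None,
    }
    if isinstance(tpl, FourierTemplateParams):
        state["fourier_order"] = tpl.order
    return state


def restore_from_state(state: dict):
    """Rebuild (PriorityNet, template params, PhaseShiftConfig) from a state dict."""
    if state.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {state.get('version')!r} != {CHECKPOINT_VERSION!r}"
        )
    net = PriorityNet(
        PriorityNetConfig(
            k=int(state["k"]),
            channels=tuple(state["channels"]),
            alphabet_size=int(state["alphabet_size"]),
        ),
        seed=int(state["seed"]),
    )
    net.set_params([np.asarray(p) for p in state["priority_weights"]])
    w = int(state["w"])
    tp = [np.asarray(p, dtype=np.float64) for p in state["template_params"]]
    if state["template"] == "ensemble":
        tpl = EnsembleTemplateParams(logits=tp[0], w=w)
    else:
        tpl = FourierTemplateParams(beta0=tp[0], sin_amp=tp[1], cos_amp=tp[2], w=w)
    noise = None
    if state.get("noise_weights") is not None:
        noise = NoiseNet(k=int(state["k"]), seed=int(state["seed"]),
                         alphabet_size=int(state["alphabet_size"]))
        noise.set_params([np.asarray(p) for p in state["noise_weights"]])
    phase = PhaseShiftConfig(delta=float(state["delta"]), noise=noise)
    return net, tpl, phase


def save_checkpoint(path: str | Path, state: dict) -> None:
    """Serialize a training state to a single .npz file with a version tag."""
    arrays: dict[str, np.ndarray] = {}
    meta = {k: v for k, v in state.items()
            if k not in ("priority_weights", "template_params", "noise_weights")}
    for group in ("priority_weights", "template_params", "noise_weights"):
        vals = state.get(group)
        meta[f"n_{group}"] = -1 if vals is None else len(vals)
        for i, arr in enumerate(vals or []):
            arrays[f"{group}_{i}"] = arr
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path) -> dict:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        state = dict(meta)
        for group in ("priority_weights", "template_params", "noise_weights"):
            n = state.pop(f"n_{group}")
            state[group] = None if n < 0 else [data[f"{group}_{i}"] for i in range(n)]
    if state.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {state.get('version')!r} != {CHECKPOINT_VERSION!r}"
        )
    return state


def evaluate_full(
    net: PriorityNet,
    seq: EncodedSequence,
    sketch_params: SketchParams,
    chunk_chars: int = 1 << 18,
    return_sketch: bool = False,
):
    """Full-sequence density by hard MIN-selection on the scorer output.

    The forward pass is chunked with chunks overlapping by k-1 characters, so
    scores are identical to the unchunked computation (scoring is k-local).
    """
    k = sketch_params.k
    scores = np.empty(seq.num_kmers(k), dtype=np.float64)
    step = max(chunk_chars - (k - 1), k)
    for start in range(0, len(seq), step):
        stop = min(start + chunk_chars, len(seq))
        if stop - start < k:
            break
        chunk_scores = net.forward(seq.slice(start, stop))
        scores[start : start + chunk_scores.size] = chunk_scores
        if stop == len(seq):
            break
    sketch, _ = select_positions(ScoreAssignment(scores), sketch_params)
    sketch.validate()
    report = sketch_kmer_stats(seq, sketch, k)
    if return_sketch:
        return report, sketch
    return report


def train(
    seq: EncodedSequence,
    sketch_params: SketchParams,
    priority_config: PriorityNetConfig | None = None,
    objective_config: ObjectiveConfig | None = None,
    train_config: TrainConfig | None = None,
    log_path: str | Path | None = None,
) -> TrainResult:
    """Run the joint optimization loop and return traces plus checkpoints."""
    cfg = train_config or TrainConfig()
    obj = objective_config or ObjectiveConfig()
    k, w = sketch_params.k, sketch_params.w
    if sketch_params.l < w:
        raise ValueError("sequence too short for the requested (k, w)")
    pcfg = priority_config or PriorityNetConfig(k=k, alphabet_size=seq.alphabet.size)
    if pcfg.k != k:
        raise ValueError("priority config k must match sketch params k")

    seeds = np.random.SeedSequence(cfg.seed).generate_state(4)
    net = PriorityNet(pcfg, seed=int(seeds[0]))
    tpl = init_template(cfg.template, w=w, seed=int(seeds[1]),
                        fourier_order=cfg.fourier_order)
    noise = None
    if cfg.delta > 0:
        noise = NoiseNet(k=k, seed=int(seeds[2]), alphabet_size=seq.alphabet.size)
    phase = PhaseShiftConfig(delta=cfg.delta, noise=noise)
    batch_rng = np.random.default_rng(int(seeds[3]))

    all_params = net.params + tpl.params + (noise.params if noise else [])
    optimizer = Adam(all_params, lr=cfg.lr)
    l_sub = cfg.resolved_l_sub(sketch_params)

    log = io.StringIO()
    log.write("epoch\tloss\tdensity_at_eval\tbest_density\n")

    initial_report = evaluate_full(net, seq, sketch_params)
    best_density = initial_report.density_factor
    best_epoch = 0
    best_report = initial_report
    best_state = _state_dict(net, tpl, noise, cfg, sketch_params)
    loss_trace: list[float] = []
    eval_epochs = [0]
    density_trace = [initial_report.density_factor]
    log.write(f"0\t\t{initial_report.density_factor:.6f}\t{best_density:.6f}\n")

    for epoch in range(1, cfg.epochs + 1):
        offsets = _sample_offsets(seq, cfg.batch_size, l_sub, batch_rng)
        # identical views contribute identical gradients: compute once, weight
        uniq, counts = np.unique(offsets, return_counts=True)

        loss = 0.0
        grads = [np.zeros_like(p) for p in all_params]
        n_pri = len(net.params)
        n_tpl = len(tpl.params)
        for off, count in zip(uniq, counts):
            weight = count / cfg.batch_size
            view = seq if len(seq) <= l_sub else seq.slice(int(off), int(off) + l_sub)
            f32, fcache = net.forward(view, keep_cache=True)
            f = f32.astype(np.float64)
            g, gcache = template_forward(tpl, l=f.size, phase=phase, seq=view,
                                         offset=int(off), keep_cache=True)
            if obj.metric == "dm":
                loss_v = dm_distance(f, g, obj.lam)
                df = dm_gradient_constants(f, g, obj.lam)
                dg = dm_gradient_template(f, g, obj.lam, detach_weight=True)
            else:
                loss_v = l2_distance(f, g)
                df, dg = l2_gradients(f, g)
            loss += weight * loss_v
            for acc, grad in zip(grads[:n_pri],
                                 net.backward(fcache, f32, (weight * df).astype(np.float32))):
                acc += grad
            tgrads, ngrads = template_backward(gcache, weight * dg)
            for acc, grad in zip(grads[n_pri : n_pri + n_tpl], tgrads):
                acc += grad
            if ngrads is not None:
                for acc, grad in zip(grads[n_pri + n_tpl :], ngrads):
                    acc += grad
        optimizer.step(grads)
        loss_trace.append(loss)

        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            report = evaluate_full(net, seq, sketch_params)
            eval_epochs.append(epoch)
            density_trace.append(report.density_factor)
            if report.density_factor < best_density:
                best_density = report.density_factor
                best_epoch = epoch
                best_report = report
                best_state = _state_dict(net, tpl, noise, cfg, sketch_params)
            log.write(f"{epoch}\t{loss:.6f}\t{report.density_factor:.6f}\t{best_density:.6f}\n")
        else:
            log.write(f"{epoch}\t{loss:.6f}\t\t{best_density:.6f}\n")

    if log_path is not None:
        Path(log_path).write_text(log.getvalue())

    return TrainResult(
        loss_trace=loss_trace,
        eval_epochs=eval_epochs,
        density_trace=density_trace,
        best_density=best_density,
        best_epoch=best_epoch,
        best_state=best_state,
        final_state=_state_dict(net, tpl, noise, cfg, sketch_params),
        initial_report=initial_report,
        best_report=best_report,
    )
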