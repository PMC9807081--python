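# minilearn — differentiable learning of sequence-specific minimizer schemes

Minimizers sample representative k-mers from biological sequences: given a
k-mer length *k*, a window size *w*, and a total ordering π over all σ^k
k-mers, every window of *w* consecutive overlapping k-mers contributes its
lowest-ranked k-mer (ties broken leftmost). The union of selected positions is
the sketch **L**(S; m), and the standard quality measure is the **density
factor**

    D = |L| · (w + 1) / l_w ,      l_w = l − w + 1 windows,

roughly the number of k-mers selected per window. A random ordering gives
D ≈ 2 on random sequences; the theoretical floor is 1 + 1/w. Read mappers,
assemblers, and k-mer counters all benefit from orderings with lower density
on *their* target sequence — but optimizing over the (σ^k)! orderings is a
hard discrete problem.

This package implements a fully differentiable surrogate for that problem,
built from two cooperating score generators:

- **PriorityNet** `f(S; α)` — a convolutional scorer whose first layer has
  kernel size exactly *k* and all later layers kernel size 1, so the score of
  a k-mer depends on its *k* characters alone. This architecturally guarantees
  *consistency* (one k-mer never gets two different scores), hence every
  weight setting encodes a valid minimizer ordering — but says nothing about
  density.
- **TemplateNet** `g(S; β)` — periodic "template" score assignments
  `g_i = h(i)` built from sinusoids with period *w* (an amplitude-weighted
  ensemble of integer-phase-shifted sines, or a truncated Fourier series,
  optionally with a sequence-conditioned positional phase shift
  `g_i = h(i + δ·ξ_i(S; γ))`). If *h* has a unique minimum per period on the
  integer grid, the induced sketch provably has density factor
  1 + 1/w + o(1) — near-optimal, but generally *not* a valid consistent
  assignment.

Training minimizes an asymmetric matching distance between the two outputs,

    Δ_DM(f, g) = Σ_i (1 − g_i)(f_i − g_i)² + λ Σ_i (f_i − 1)² ,

whose weight 1 − g_i concentrates the matching around the template minima and
whose λ-term pushes scores up elsewhere, preventing the trivial all-zero
solution (∂Δ_DM/∂f_i = 2(1 − g_i)(f_i − g_i) + 2λ(f_i − 1)). The consensus is
a *consistent* score assignment whose hard MIN-selection has low density on
the target sequence.

## Worked example

Train on a synthetic planted-periodic sequence (a unique sentinel 8-mer every
13 k-mer positions over random background — the structure an ideal minimizer
can exploit):

```
minilearn simulate --kind planted --k 8 --w 13 --periods 500 --seed 1 --out planted.fa
minilearn baseline --fasta planted.fa --k 8 --w 13 --method random --seed 0 --out base/
minilearn train    --fasta planted.fa --k 8 --w 13 --epochs 300 --seed 1 --out run/
minilearn eval     --checkpoint run/best.ckpt.npz --fasta planted.fa --out eval/
```

The `train` command prints (numbers from this exact invocation):

```
{
  "initial_density": 1.8319975339087546,
  "best_density": 1.3702219482120839,
  "best_epoch": 220
}
```

The freshly initialized scorer behaves like a random minimizer (D ≈ 1.8–2.0
depending on how the random ordering happens to rank the sentinel); after
training, the best checkpoint's density factor has dropped by ~25% toward the
1 + 1/w ≈ 1.077 floor. `eval/density.json` contains the full report
(`k`, `w`, `l`, `lw`, `sketch_size`, `density_factor`, `unique_kmers`) and
`eval/sketch.bed` the selected k-mer intervals in BED3.

The same workflow runs on any FASTA (e.g. a chromosome or contig set); IUPAC
ambiguity codes are split into unambiguous segments by default.

## Library surface

```python
import minilearn as ml

seq    = ml.read_fasta("genome.fa")[0]
params = ml.SketchParams.for_sequence(seq, k=14, w=13)

# classical baselines
scores = ml.random_ordering_scores(seq, k=14, seed=0)
sketch, trace = ml.select_positions(scores, params)
print(ml.density_factor(sketch).density_factor)      # ~2.0

# learned scheme
result = ml.train(seq, params, train_config=ml.TrainConfig(epochs=600, seed=0))
print(result.best_density)
```

`docs/methods.md` describes the model, the training procedure, parameter
defaults, and known limitations.

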