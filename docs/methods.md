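# Methods

## Problem and conventions

A minimizer scheme with parameters (k, w) selects, from every window of w
consecutive overlapping k-mers, the k-mer of minimum priority under a total
order π on Σ^k, breaking exact-equality ties by the leftmost position. All
coordinates are 0-based and half-open: k-mer position i covers characters
[i, i+k), window t covers k-mer positions [t, t+w), and a sequence with l
k-mers has l_w = l − w + 1 windows. Quality is the density factor
D = |L|·(w+1)/l_w, where L is the set of distinct selected positions;
1 + 1/w is the floor and ≈2 the random-ordering calibration.

MIN-selection is canonical throughout. The equivalent max-pool formulation
(select window maxima of 1 − s) is supported as a documented mirror and
regression-tested for sketch identity. Ties are exact float equality, not
epsilon equality, which keeps selection deterministic and forward (picks
never move left as the window slides; the per-window change indicators γ_t
therefore sum to |L|).

Selection is implemented as a chunked vectorized leftmost-argmin over a
sliding-window view; a deliberately naive pure-Python per-window scan is kept
as an independent oracle and the two are asserted bit-identical on randomized
and tie-heavy instances.

## Score reparameterization (PriorityNet)

The ordering is represented implicitly by a consistent score function
f: Σ^k → (0, 1), realized as a convolutional network over the one-hot
sequence: one convolution of kernel size k (σ input channels), then 1×1
convolutions with embedding widths (256, 64, 16), ReLU activations between
layers, and a single-channel sigmoid head. Because only the first layer has
spatial extent, the score at position i is a function of characters [i, i+k)
alone — duplicate k-mers receive identical scores for *any* weight setting,
so every point of weight space encodes a valid scheme. This is verified both
positively (tandem-repeat fixtures, arbitrary weights, tolerance 1e-6 at
float32 precision) and negatively (a control net whose second kernel is 3
fails the same check).

Initialization is fan-in-scaled Gaussian for hidden layers with the output
head scaled by 0.1. The head scaling starts all scores in a narrow band
around 1/2; the induced ordering is still a non-degenerate pseudo-random
total order (density ≈ 2 on random sequences, like a random minimizer), but
the matching objective then has very little arbitrary k-mer noise to unlearn
before it can shape the score landscape. With an unscaled head the initial
score spread behaves as memorized noise that dominates the early gradient
signal and, at the training lengths used here, the template degrades before
the scorer catches up.

## Low-density templates (TemplateNet)

A template is a periodic function h: R → [0, 1] of fundamental period w,
evaluated on the integer k-mer grid. If h has a unique minimum per period
aligned to the grid, the induced sketch picks exactly one position per
period: on a sequence with l_w ≫ w² windows the density factor is at most
1 + 1/w + w(w+1)/l_w (one extra pick per period boundary at finite length).
This exact finite-length bound is property-tested for w ∈ {5, 13, 40} at
l_w = 10^5.

Two parameterizations:

- **Ensemble**: h(t) = sigmoid( Σ_{φ=0}^{w−1} β_φ sin(2π(t+φ)/w) ) with
  amplitudes on the probability simplex via softmax over w unconstrained
  logits (smooth, no projection step). The dominant phase φ_max = argmax β
  sets the offset of the minima. The uniform-amplitude point is degenerate —
  the sines cancel and h ≡ 1/2 — so initialization boosts one randomly chosen
  logit by +6, giving a clear dominant phase (realized amplitude ≈ 0.95) and
  starting the template well inside the unique-minimum regime.
- **Truncated Fourier**: h(t) = sigmoid( β_0 + Σ_{r≤R} [a_r sin(2πrt/w) +
  b_r cos(2πrt/w)] ), default truncation R = min(8, ⌊w/2⌋); compact for large
  w, but generic parameters may place minima off the integer grid, so only
  periodicity (not the density bound) is asserted for random Fourier
  parameters. Initialization gives the fundamental (r = 1) unit magnitude at
  a random phase, plus small higher-order noise.

An optional positional phase shift g_i = h(i + δ·ξ_i(S; γ)) conditions the
template on sequence content; ξ is a small convolutional stack with the same
kernel-k-then-1×1 pattern (so the noise is also consistent across duplicate
k-mers) and a tanh head bounding |ξ| ≤ 1. Its final layer is zero-initialized
so that training starts from the exact periodic model; δ = 0 recovers it
identically.

**Anchoring.** Template values are always evaluated at absolute sequence
coordinates: a subsequence view starting at character offset o uses
g_i = h(o + i). The training objective is a single global matching problem on
S, and subsequence batching merely subsamples its terms; anchoring to local
view coordinates instead would re-randomize every position's target each
epoch and destroy the signal (any global integer shift of the grid is
absorbed by the learned phase, so the choice of origin is immaterial).

## Matching objective

The asymmetric distance (MIN convention)

    Δ_DM(f, g) = Σ_i (1 − g_i)(f_i − g_i)² + λ Σ_i (f_i − 1)²

enforces strong matching near the template minima (where 1 − g_i ≈ 1) and
pushes scores toward 1 elsewhere, which excludes the trivial solution where
both assignments collapse to 0. Its scorer-side gradient has the closed form
a_i = 2(1 − g_i)(f_i − g_i) + 2λ(f_i − 1), asserted against central finite
differences to 1e-5 relative error. λ defaults to 1. The symmetric baseline
Δ_ℓ2 = Σ_i (f_i − g_i)² is provided for ablations.

**Template-side gradient.** The full derivative ∂Δ_DM/∂g_i contains the term
−(f_i − g_i)² from differentiating the matching weight itself. That term
rewards the template for *raising* its own scores to switch the matching off;
since a sigmoid-of-zero-mean-periodic template cannot raise its mean, the
force resolves into amplitude decay and drives the ensemble toward its
degenerate constant point. The template update therefore treats the weight
(1 − g_i) as a constant ("detached"), using b_i = −2(1 − g_i)(f_i − g_i):
the template then feels only the pull toward the scorer, and stays periodic
throughout training, which matches the intended negotiation dynamic. Both
forms are exposed in `objective.dm_gradient_template`; the finite-difference
test covers the full derivative.

## Training protocol

Each epoch samples N = 10 subsequences of 500·(w+k) characters at uniform
random offsets (with replacement; a sequence shorter than that is used whole
— identical batch members are computed once and weighted by multiplicity,
which is algebraically the same mean). The loss is summed over positions and
averaged over the batch, and a single Adam step (η = 5e-3, standard moment
parameters) updates scorer weights α, template amplitudes β, and noise
weights γ jointly. Default budget is 600 epochs with a full-sequence
evaluation — chunked forward pass with k−1 character overlap, so scores are
identical to the unchunked computation — every 20 epochs; the best-density
checkpoint is retained, mirroring best-so-far reporting. Runs are
deterministic for a fixed seed (single numpy code path; no stochastic
layers): all randomness (weight init, template init, batch offsets) derives
from one seed sequence.

## Synthetic data

Three generators define the study conditions; all are pure functions of an
explicit seed:

- **random**: i.i.d. uniform characters — the calibration substrate on which
  any consistent random ordering yields D ≈ 2 (asserted as 2.0 ± 0.02 at
  l_w = 2·10^5, k = 14, w = 13, five hash seeds).
- **repeat**: a random unit tandem-repeated with optional per-position
  mutation — the adversarial substrate for consistency checks, emulating
  centromeric repetitiveness.
- **planted-periodic**: a sentinel k-mer occurring at k-mer positions
  0, w, 2w, … and nowhere else (stray background occurrences are rejected and
  resampled), over i.i.d. background — the structure an ideal sequence-specific
  scheme can exploit to approach 1 + 1/w. Requires k ≥ 8 (σ = 4) so a
  background-free sentinel exists, and w ≥ k so planted copies cannot overlap.

What these fixtures do *not* emulate: genome-scale length, biased base
composition, and — critically — the pervasive k-mer repetitiveness of real
genomes. Results on the planted fixture therefore show that the machinery
optimizes what it claims to optimize, not that the learned schemes transfer
to real chromosomes at the improvements reported there.

## Scaled-down learning study and its limits

The in-package study trains on the planted fixture (k = 8, w = 13,
500 periods ⇒ l = 6,500 k-mers) for 300 epochs, three seeds, both metrics.
Under the weighted metric the median best density improves by ≈11% over the
initialization (which spans D ≈ 1.46–1.83 depending on where the random
initial ordering ranks the sentinel), with the loss and density positively
correlated over the evaluation grid (median Spearman ρ ≈ 0.7).

One directional claim does **not** reproduce at this scale: symmetric ℓ2
matching, reported at genome scale to perform like a random minimizer,
*solves* this small fixture (best D ≈ 1.10, near the 1.077 floor) and beats
the weighted metric (median best ≈ 1.37). The reason is structural: on the
planted fixture almost every background k-mer is unique and the template
minima can align with the sentinel grid, so the exact match f = g is a
feasible consistent assignment and ℓ2's unweighted pull is simply a ~3×
stronger training signal (full template range ≈ 0.46 versus the weighted
metric's equilibrium dip depth ≈ 0.14 at λ = 1). The weighted metric's
advantage materializes when exact matching is *infeasible* — i.e. under
genome-scale repetitiveness, precisely what the small fixture lacks. The
corresponding test encodes the genome-scale expectation and is expected to
fail on this fixture; it is kept failing rather than weakened, as an honest
record of the scale limitation.

## Numerical choices and limitations

- Network math is float32; the consistency tolerance (1e-6) and the chunked
  equal-scores tolerance reflect this. Losses and template math are float64.
- Exhaustive ordering search is provided for σ^k ≤ 8 (at most 8! orders) as a
  ground-truth anchor on tiny alphabets; ranked-order export enumerates up to
  σ^k = 4^12 k-mers, beyond which callers must score on the fly.
- Hash-based random orderings use a splitmix64 finalizer on the base-σ k-mer
  code XOR a salted seed: identical k-mers always share a score, distinct
  seeds give effectively independent orderings.
- Forward strand only; no canonical (reverse-complement-aware) k-mers. FASTQ
  and compressed indexes are out of scope. Ambiguous IUPAC characters are
  split into unambiguous segments by default (policy `error` is available);
  how such bases "should" interact with a learned scheme is left open.
- Training runs on CPU; runtimes for the in-package studies are seconds to a
  few minutes. Checkpoints are single .npz files with a format-version tag,
  embedded configuration, and all three parameter groups.
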