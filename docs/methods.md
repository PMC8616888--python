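# Methods

## Model and guarantee

The package targets linear inverse problems `y = A x + η` solved by a
feed-forward ReLU network applied after a model-based inversion,
`x_rec = Φ(A†(y))`. An interval neural network (INN) replaces every weight
matrix and bias vector of the trained Φ by component-wise intervals
containing the original parameters and propagates inputs by interval
arithmetic. Two propagation cases cover the supported architectures:

* the first layer sees a *point* input, which may be signed;
* every later layer sees a *nonnegative interval* (the preceding ReLU
  guarantees nonnegativity), for which the explicit min/max case split over
  the weight-bound signs applies.

These are exactly the two closed forms implemented in
`innuq.intervals`; architectures in which a signed interval could reach a
hidden layer (any non-ReLU hidden activation) are rejected at construction
time, and the final layer may be identity so reconstructions can be signed.
Convolutions are handled by the same formulas applied to the kernel's
positive/negative parts — a 1D "same" convolution is an affine map, so the
dense-layer arithmetic transfers unchanged.

Under the box constraints `W̲ ≤ W ≤ W̄`, `b̲ ≤ b ≤ b̄` the output interval
contains the output of every parameter selection inside the intervals —in
particular the base prediction. This soundness is checked in the tests by a
vertex-enumeration oracle on small layers (the affine map is monotone in
each parameter entry, so exact extremes sit at box vertices) and by
Monte-Carlo parameter sampling on multi-layer networks.

### Floating-point rigor

Naive float interval arithmetic is *not* sound: with round-to-nearest, the
bounds and the base prediction are computed by different summation orders
and can disagree by a few ulps — visible precisely where trained interval
widths collapse to zero. Full-network propagation therefore applies
per-layer outward rounding: bounds are widened by
`1e-12 × (|W|·|z| + |b|)`, a generous bound on the accumulated rounding
error of inner products of a few hundred terms (~3.5e-14 relative). The
computed envelope is then rigorous, and the containment check passes with
no tolerance. The single-layer `propagate_*` functions expose the bare
case formulas (used by the oracle-equality tests); the slack constant is
`innuq.intervals.OUTWARD_GAMMA`.

## Interval training

With the base network frozen, the interval parameters minimize the hinge
coverage loss plus an ℓ1 width penalty weighted by the tightness β,
subject to the box constraints. Design choices where the procedure was
open:

* **Constraint handling** — unconstrained Adam steps followed by exact
  projection (clamping each bound against the frozen base parameter).
  Projection keeps the containment guarantee valid at *every* point of
  training; reparameterization via nonnegative offsets would work equally
  well but hides the guarantee inside the parameterization.
* **Initialization** — intervals start at the base parameters ± a floor
  `eps0 = 1e-6` (relative inflation `init_width` optional, default 0), so
  the starting configuration is trivially valid and width gradients are
  nonzero.
* **Optimizer** — Adam, learning rate 1e-3, batch 32; the base networks use
  the same.
* **β heuristic** — `select_beta` returns the base network's mean absolute
  prediction error (floored at 1e-8), the scale at which the width penalty
  and the hinge terms balance; the deconvolution reference configuration in
  the literature uses β of the same order (2e-3 for a near-fully-converged
  base network).
* **Precision** — the training loop runs in float32 (ample for stochastic
  gradients, ~2× faster in BLAS); parameters are cast back to float64 and
  re-projected against the float64 base afterwards, so evaluation-time
  guarantees are unaffected.

A property of the trained intervals worth knowing: for components whose
error is far below β, the width penalty drives *both* bounds onto the
prediction, and projection leaves a one-sided, near-zero-width interval.
Directionality ratios for such components are enormous (1e6+) without
carrying statistical information — the motivation for the binning rule
below.

## Uncertainty scores and metrics

* `u(z) = Φ̄(z) − Φ̲(z)` — the INN heatmap.
* **Directionality ratio (DR)** — larger over smaller interval part around
  the prediction; components whose smaller part is below `τ_DR = 1e-12`
  are reported undefined and excluded.
* **Directionality accuracy (DA)** — per DR bin, the relative frequency of
  targets in the larger part. Targets are attributed to the side of the
  prediction they fall on (this extends the definition to targets outside
  the interval, where the side still encodes the error direction); a target
  exactly at the prediction counts 0.5. Bins are log-spaced over
  `[1, dr_max]` (default `dr_max = 1e3`, 20 bins) with an **open-ended last
  bin**: ratios beyond `dr_max` describe effectively one-sided intervals
  and are pooled so every populated bin carries enough mass for a frequency
  estimate. Binning to the observed maximum instead produces tail bins of
  2–3 components whose DA is a coin flip.
* **Coverage** — fraction of components with
  `Φ̲ − λβ < x < Φ̄ + λβ`; the Markov-inequality bound `≥ 1 − 1/λ` assumes
  training reached stationarity in expectation, so the package treats it as
  a soft check (0.05 slack at λ = 2 in the acceptance test), not an
  invariant.
* **PWCC** — Pearson correlation between `|Φ(z) − x|` and `u(z)`, divided
  by the *mean* squared error of the prediction (the normalization that the
  worked 4-component example fixes: residuals (0,1,0,−1), u = (.1,.9,.1,.9)
  give correlation 1, MSE 0.5, PWCC 2). Zero-variance inputs are reported
  undefined (NaN) and excluded from averages with a logged count.
* **Heatmap-change correlation** — per sample, Pearson correlation between
  `|u(z) − u(z_pert)|` and a change map (reconstruction change for the
  adversarial protocol, the binary insertion mask for the artifact
  protocol), then averaged over the test set. Changes at the rounding level
  of the heatmaps (ptp ≤ 1e-12 × scale) count as "no change" → undefined.

## Baselines

**MCDrop** computes the component-wise sample standard deviation over T
stochastic dropout passes with the numerically safe accumulation
`((ΣΦ_t² − (ΣΦ_t)²/T)/(T−1))^{1/2}`; the deconvolution reference uses
T = 64. **ProbOut** doubles the output head into mean and log-variance
channels (variance = exp(log-variance), positive by construction) trained
from scratch with `‖(x−μ)/√v‖₂² + ‖log v‖₁`.

Two honest caveats, both consequences of printed formulas rather than
implementation choices:

* For a fixed residual r, the scalar ProbOut objective `r²/s + |log s|` is
  minimized at `s = r²` only when `|r| ≥ 1`; for sub-unity residuals the
  |log| kink moves the optimum to `s = 1`. On this benchmark (targets in
  [0,1], residuals ≪ 1) the variance head therefore pegs near 1 and the
  ProbOut heatmap is nearly flat.
* With dropout rate 0.1 at three sites, the 32-channel 1D network adapts to
  the mask noise: its deterministic forward pass has ~6× the MSE of the
  mask-averaged training regime, which in turn raises the MAE-based β.
  The rate is a config default (`dropout_rate`); smaller rates narrow the
  gap.

## Synthetic benchmark

`A = Dᵀ S D` with `D` the *orthonormalized* Type-I DCT (so `Dᵀ = D⁻¹` and
the eigenvalue identity is exact) and `s_j = ((n−j)/(n−1))^ν` for
j = 1..n — a 1-based index so that `s₁ = 1`, `s_n = 0` and the spectrum
lies in [0,1]. Reference configuration n = m = 512, ν = 8; the model-based
inversion is the identity, so network inputs are the measurements
themselves. Signals are piecewise constant with jump count uniform on
{4,…,12}, jump positions uniform without replacement, plateau heights
uniform in [0,1] (jump distribution parameters are config surface; the
generating description fixes only "random jump positions and heights").
Noise models: none, `y = Ax + η`, or `y = A(x+η₁)+η₂` with independent
`η ~ N(0, σ²Id)`. The reference dataset has 2000 pairs split 1600/200/200;
training data is generated noiseless and the noise-response sweep adds
noise at evaluation time only. The out-of-distribution artifact is a
contiguous block mask of configurable length (default 50) added with
amplitude 1 and clipped to [0,1] — a 1D stand-in for an arbitrary 2D
stencil.

What the generator does *not* emulate: real detector physics, correlated
noise, model mismatch in A, and the structured null-space of limited-angle
tomography. Passing tests therefore demonstrate the mechanics and the
claimed properties of the estimators under controlled conditions, not
clinical performance.

## Adversarial protocol

Targets are built by subtracting 1.5× the reconstruction mean inside a
random contiguous region (length 50, the 1D analog of a 50×50 square);
the attack minimizes `‖Φ(z′) − x_adv‖₂²` over the valid input box with
L-BFGS-B (gradients via backprop through the frozen network; defaults 200
iterations, gradient tolerance 1e-8). Because the forward operator is not
range-preserving, benchmark inputs can leave [0,1] slightly; the driver
widens the box to the observed input range so the clean input is always
feasible. The attack operates in input space, after the model-based
inversion; measurement-domain attacks are out of scope.

## Problem sizes and determinism

The acceptance-scale runs use the reference data configuration
(n = 512, 2000 samples) with 15 base epochs and 30 interval epochs on the
trailing five of the ten layers. Two findings drive that protocol. First,
the interval loss has near-degenerate optima whose *directional* structure
at low DR differs even when the loss values agree; slow, long training
reliably lands in well-aligned optima, so interval-training length matters
beyond the loss plateau. Second, restricting intervals to a trailing layer
subset (the standard device for very deep reconstruction networks, where
interval training is usually limited to the last layers) converges to an
equal-or-better loss at half the per-epoch cost —
leading point-interval layers keep the propagated interval degenerate and
are evaluated with a single affine pass — which is what makes 30 epochs
affordable. The library default remains intervals on *all* layers
(`interval_layers=None`). Examples run at n = 128–256 with proportionally
smaller networks. Every run is determined by
(config, seed): one seed drives data generation, initialization, batch
order, dropout masks and protocol placements, and each experiment driver
writes a manifest (config hash, seed, library versions) sufficient to
re-run it.

## Known limitations

* Interval propagation covers plain dense/1D-conv ReLU stacks; pooling,
  normalization layers, attention and signed hidden activations are out of
  scope.
* The coverage bound is asymptotic in training quality; a poorly converged
  INN can undershoot it.
* MCDrop uncertainties depend on the dropout rate, which the benchmark
  fixes by convention (0.1) rather than by calibration.
* The interval width floor `eps0` makes "exact zero width" unreachable by
  construction (trained widths can still collapse to zero after
  projection).
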