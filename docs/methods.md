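# Methods

## The model

`scorebridge` constructs a Schrödinger bridge: the diffusion process

    dX_t = μ⇀(X_t, t) dt + σ dW_t,      t ∈ [0, 1],

whose marginal laws at the two endpoints match prescribed distributions
π₀ and π₁ (given only as sample arrays), and whose path measure stays
close, in KL divergence, to a reference diffusion. The bridge is solved by
iterative proportional fitting (IPF): alternately solving *half-bridges*
that fix one boundary at a time. Each half-bridge reduces to estimating the
drift of the time-reversed process, because the reverse drift of a
diffusion with drift μ and marginal density p_t is

    μ↼(x, τ) = −μ(x, 1−τ) + σ² ∇ₓ log p_{1−τ}(x).

## Score matching with a reference drift

The score ∇log p_t is never available analytically here. Instead, the
reverse drift is characterised variationally: for points x drawn from the
reference process' marginals, the cost

    C(φ) = E[ ‖φ(x,t)‖² + 2 μ(x,t)·φ(x,t) + 2σ² Tr J_φ(x,t) ]

is minimised exactly by φ* = −μ + σ²∇log p_t, i.e. by the reverse drift.
The proof device is integration by parts: E_p[Tr J_φ] = −E_p[∇log p · φ],
which the test suite verifies empirically on standard-normal samples. The
cost involves only simulated samples, the known reference drift and the
trace of the Jacobian of the trainee — no score, no transition density, and
no dependence on the time discretisation used to generate the samples.

The empirical cost is averaged over the minibatch (not summed over the full
trajectory ensemble): per-point averaging keeps the learning rate
meaningful independently of batch size.

Three interchangeable estimators compute the trace term:

- `exact_diagonal` — D reverse-mode passes, one per one-hot output
  direction; exact, preferred for small D;
- `hutchinson` — E_z[zᵀ J z] with Rademacher probes z; unbiased, a single
  extra derivative of the scalar φ·z per probe; default one probe per point
  per step, the variance being amortised over training steps; probes are
  redrawn every step;
- `stein` — E_z[φ(x+z,t)·z]/σ_z² with Gaussian probes z ~ N(0, σ_z² I);
  derivative-free (usable with ReLU networks, which are only once
  differentiable), exact for affine φ and O(σ_z²)-biased in general.
  Default σ_z = 0.1, chosen for data standardised to unit scale; it is a
  config field.

## Drift networks

Both drifts are residual MLPs taking the state x and the normalised time t
as separate inputs. Each block computes
`h ← h + tanh(Linear([LayerNorm(h), Embed(t)]))`, where layer
normalisation is applied to the spatial features only so the time embedding
passes through unscaled; the time embedding is a learned affine map of t
(default width 16). Default sizing: width 10·D, depth max(2, ⌈D/5⌉).
Activations must be twice differentiable (tanh, GELU) when the exact or
Hutchinson estimators are used, because the parameter gradient of the trace
term is a second derivative; ReLU is admitted only with Stein.

Initialisation details that matter:

- The output layer has standard deviation `final_scale/√width`
  (final_scale = 10⁻², so the freshly built field is ≈ 0 and the
  first-iteration reference process is Wiener-dominated — the intended IPF
  starting point).
- Hidden biases are drawn uniform ±1/√fan_in rather than zero. With zero
  biases the pre-activation at x ≈ 0 is the zero vector and LayerNorm's
  variance hits its ε floor, producing a localised Jacobian spike (traces
  of order 1/√ε) that destabilises the trace term and defeats the Stein
  estimator, whose probes average over a σ_z-neighbourhood. Nonzero biases
  remove the degenerate configuration generically.

Since no automatic-differentiation framework with second-derivative support
is part of the dependency stack, the package carries a small reverse-mode
engine (`scorebridge.autodiff`) whose vector-Jacobian products are
themselves traced, giving the double backprop the loss needs. It is
verified against finite differences, including through the
gradient-of-gradient path.

## IPF driver

Each iteration performs (i) a backward half-bridge — simulate forward from
π₀ under the current forward drift, train the backward net against it — and
(ii) a forward half-bridge — simulate backward from π₁ under the freshly
trained backward net, train the forward net. Exactly two networks exist and
warm-start across iterations.

All networks are parameterised by forward-clock time; the simulator feeds
1 − τ to a net when integrating a backward grid. Training evaluates trainee
and reference at the *same* (forward-clock) time label of each sample,
which makes the trained function the reverse drift in that common
parameterisation.

Replay buffers: each half-bridge owns a FIFO buffer (capacity 512
trajectories) cleared whenever its reference drift changes, i.e. at every
IPF iteration, and refilled during training with 128 fresh trajectories
every 250 steps (four refreshes per 1000-step half-bridge). Training on
trajectories from an outdated reference would bias the cost, whose premise
is that samples come from the current reference process; intra-half-bridge
reuse is what the buffer capacity provides. Trajectory start points are
drawn from the fixed-boundary sample set, so the boundary condition is
exact by construction.

Optimisation: Adam with a cosine-annealed learning rate from 10⁻³ to 10⁻⁵
over 1000 steps per half-bridge, minibatches of 1024 (trajectory,
time-step) pairs drawn uniformly from the flattened buffer.

Divergence handling: simulation aborts (with the step index) if any state
exceeds 10⁶ in magnitude or turns non-finite — early iterations with
untrained drifts can explode, and a loud failure beats a NaN payload.
Training aborts with the step index and loss history on a non-finite loss.

## Diffusion scale

σ is a config field. The helper `sigma_heuristic` sets it so that the
Brownian spread over the horizon, σ·√(Nt·dt), equals half the largest
coordinate range of the target samples — first-iteration trajectories then
cover the target distribution, so the early score estimates see data where
it matters. For unit-scale marginals (all synthetic tasks here) σ = 1 is a
sensible configured value and is what the shipped examples use.

## Evaluation

Bridge quality is measured by the Wasserstein-1 distance between generated
and target endpoint samples, computed exactly: sorted closed form in 1-D,
optimal assignment for equal-size uniform samples, transport LP for the
weighted/unequal case; a seeded subsample cap (default 2000 points per
side) bounds LP cost on large sets. A brute-force permutation oracle and
the 1-D closed form back the solver in the tests. `mode_coverage` reports
the fraction of samples nearest each mode centre, quantifying whether a
bridge reproduces bifurcations into multimodal targets.

## Synthetic data

The generators define the study conditions:

- `gmm_pair` — π₀ a unimodal Gaussian, π₁ a balanced two-mode mixture; all
  means uniform on [−2.5, 2.5] per coordinate, all standard deviations 1.
- `manifold_pair` — π₁ concatenates independent draws of classic
  parametric manifolds (swiss roll 3-D, S-curve 3-D, two moons 2-D),
  standardised per coordinate to zero mean/unit scale plus 0.05 jitter;
  π₀ = N(0, I) in the concatenated dimension. The parametrisations are
  implemented directly from their standard forms so the tests depend on no
  external generator behaviour.
- `ou_reverse_drift` — the closed-form reverse drift of an OU process with
  Gaussian initial law; the analytic oracle for everything score-related.
  For the stationary case (init variance σ²/2θ) it reduces to −θx.
- `synthetic_embryoid_standin` — Gaussian OU marginals of a 5-D process at
  five equispaced "days", a stand-in for time-stamped single-cell
  coordinate data in the hold-out protocol. Being Gaussian with smooth
  mean/variance interpolation, it exercises the protocol's plumbing and
  interpolation accuracy but not multimodality, manifold structure, or
  batch effects of real single-cell data — passing it shows the protocol
  and training are sound, not that real data would reach the same accuracy.

## Hold-out protocol

`holdout_evaluate` trains a bridge using only the first- and last-day
samples, maps days {0..4} uniformly onto grid times {0, .25, .5, .75, 1}
(uniform spacing is the only symmetric choice), and reports W1 at every
day: day 0 from the backward endpoint, day 4 from the forward endpoint,
days 1–3 from forward-process slices at the nearest grid point. "Path"
averages the intermediate days, "Full" all five. Input files use day labels
0–4; 1-based labels are canonicalised on load and both conventions appear
in the output row.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script: 512
trajectories per reference ensemble (OU recovery), Nt = 100 and dt = 0.01
for single half-bridge studies, Nt = 50 for full 1-D bridges (10 IPF
iterations, 1000 training steps per half-bridge), four-iteration runs at
400 steps for the trajectory-count comparison, and a two-iteration, Nt = 20
bridge at D = 5 for the hold-out stand-in. Slice lookup uses the nearest
grid point with ties toward the lower index (no interpolation between
steps). LayerNorm ε = 10⁻⁵; trace computations over large evaluation
batches are chunked (8192 rows) to bound graph memory.

## Known limitations

- Single scalar σ; state- or time-dependent diffusion is out of scope.
- The reverse-drift MSE achievable from 512 trajectories is Monte-Carlo
  limited: per-time-slice empirical moments fluctuate, and the fitted drift
  inherits that noise (typical stationary-OU MSE ≈ 0.02–0.05 on |x| ≤ 2,
  occasionally higher for an unlucky draw).
- Score estimation in low-density regions remains the binding constraint;
  the trajectory count is the single most influential setting.
- Exact W1 via LP scales poorly beyond a few thousand points; the subsample
  cap trades a small bias for tractability.
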