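# Methods

## The preferred-mode analysis

A population tensor `X ∈ ℝ^{N×C×T}` (neurons × conditions × times) has two
matrix unfoldings whose rows run along the first two modes:

```
X₍₁₎ = [X(1) X(2) … X(T)] ∈ ℝ^{N×CT}      (rows = neurons)
X₍₂₎ = [X(1)ᵀ X(2)ᵀ … X(T)ᵀ] ∈ ℝ^{C×NT}   (rows = conditions)
```

where `X(t)` is the N×C slice at time `t`. Truncated SVD of `X₍₁₎` yields
*basis-neurons* — its top-k right singular vectors reshaped to C×T
matrices — and each neuron's slice is approximated as a weighted sum of
them; `X₍₂₎` yields *basis-conditions* (N×T) symmetrically. Reconstruction
error is the normalized squared error `‖X − X̂‖²_F / ‖X‖²_F`, which by the
Eckart–Young theorem equals `1 − Σ_{i≤k} s_i² / Σ_i s_i²` for the mode's
singular values `s_i`; the implementation computes both and they must agree
to 1e-10. The *preferred mode* is the mode whose k-element basis leaves
the smaller error.

Rationale: under a static tuning model `x(t,c) = B u(t,c)` with `M`
inputs, `X₍₁₎ = B U₍₁₎` has rank ≤ M at every timespan while the rank of
`X₍₂₎` grows with the timespan (inputs are unconstrained across
conditions) — neuron-preferred. Under autonomous linear dynamics
`x(t+1,c) = A x(t,c)`, `X₍₂₎ = X(1)ᵀ A₍₂₎` has rank equal to
`rank(X(1))` at every timespan while the rank of `X₍₁₎` grows toward
`rank(A)` — condition-preferred. The identification requires the low-rank
preconditions `N > M`, `C > M` (tuning) and `rank(X(1)) < rank(A)`
(dynamics); the simulator configuration enforces them for the pure cases.
The dynamics argument survives time-varying `A(t)` as long as the dynamics
are shared across conditions, and the implementation verifies this.

### Procedure

1. **k-selection.** At the central timepoint `t_half` (1-based
   `round(T/2)`, half-up), the N×C slice is a matrix, so row rank equals
   column rank and neither mode is preferred. `select_k` returns the
   smallest k whose rank-k error on that slice is within the threshold
   (default 5%). The comparison is `error ≤ threshold` (with a 1e-12 float
   guard): with equal singular values the residual hits the threshold
   exactly and that k is accepted.
2. **Timespan sweep.** With k fixed for both modes, windows expand one
   step per side per iteration around `t_half`, clamping at the array
   boundaries and continuing on the open side until the full range is
   covered (lengths 1, 3, 5, …, T for odd T). Per-condition errors are
   tracked throughout; error bars are standard errors across conditions
   (deliberately conservative relative to pooling neurons and conditions).
3. **Basis-count sweep.** At the full timespan, the difference
   (condition-mode error − neuron-mode error) is computed for every
   k = 1…k_max (default 20, clamped at min(N, C) with a warning) and
   normalized by the smaller of the two full-timespan errors at the
   reference k (the `select_k` choice, per dataset). Positive values
   indicate neuron-preferred structure; the difference is identically zero
   at k = N = C.
4. **Verdict.** A paired two-sided test across conditions on the
   full-timespan per-condition error differences: two-sided Wilcoxon
   signed-rank by default (robust to skewed error distributions; a paired
   t-test is available via `test="ttest"`). The sign of the mean
   difference sets the label when p < α (default 0.05), otherwise `none`;
   mean differences below 1e-12 are exact ties and give `none` regardless
   of p. Fewer than 5 conditions is refused. The reported `effect` is
   (condition error − neuron error) divided by the smaller of the two.

### Per-condition error normalization

Each condition's squared residual is divided by that condition's own sum
of squares (default), so a weakly driven condition is not swamped by
strong ones. The alternative — dividing by the global sum of squares over
C, so per-condition errors average exactly to the total — is available via
`per_slice_norm=False`.

## Preprocessing

Order (enforced and recorded): count equalization → soft normalization →
cross-condition mean removal. Normalization must precede mean removal;
swapping the two changes the result.

- **Smoothing.** Spikes are binned at 1 ms, convolved with a Gaussian
  kernel (default SD 20 ms) truncated at ±4 SD, renormalized by the
  kernel's in-window mass near the edges (avoiding the edge dip of plain
  convolution), converted to spikes/s, averaged across trials, and sampled
  every 10 ms by linear interpolation between bin centers. Smoothing is
  linear, so averaging smoothed trials equals smoothing the pooled
  estimate.
- **Soft normalization.** Each neuron is divided by
  (constant + range), where the range is max − min of its rate over all
  conditions and times and the constant defaults to 5 spikes/s. A
  100 spikes/s neuron maps to a range near 1, a 5 spikes/s neuron to 0.5;
  squared-error analyses are then not dominated by high-rate neurons,
  while low-rate (noise-dominated) neurons are not blown up.
- **Mean removal.** The condition-averaged N×T matrix is subtracted from
  every condition, removing structure identical across conditions
  (idempotent; requires C ≥ 2).
- **Equalization.** Excess neurons are dropped by signal-to-noise score —
  response variance over conditions and times divided by a per-neuron
  noise variance when one is supplied, otherwise the response range as a
  proxy — and excess conditions by response standard deviation across
  neurons and times. Ties break by original index; kept labels are
  recorded in the tensor's metadata. The exact SNR definition is a
  documented choice of this package, not asserted to match any particular
  prior pipeline.

## The synthetic-data generator

`simulate_lds` iterates `x(t+1,c) = a·A x(t,c) + b·B u(t+1,c)` with
N = C = 20, T = 300, M = 10 inputs by default:

- **A** is orthogonal with eigenvalues on the unit circle: block-diagonal
  2×2 rotations with angles drawn uniformly on (0, `max_rotation_angle`],
  conjugated by a random orthogonal matrix. The default maximum angle
  2π·6/300 ≈ 0.126 rad/step admits at most 6 (mean ≈ 3) oscillation cycles
  over the default T, comparable to cortical population data. Orthogonality
  is load-bearing: it keeps trajectories bounded, and it makes the
  condition-mode error of a pure-dynamics run *exactly* flat across
  timespans at any k (the windowed Gram of `X₍₂₎` is `T_i · X(1)ᵀX(1)`, so
  spectra are proportional across windows).
- **B** has orthonormal columns (first M columns of a random orthogonal
  matrix).
- **Inputs** `u_m(·,c)` are randomly weighted sums of 20 sinusoids whose
  angular frequencies are drawn by the same sampler as A's rotation angles
  (inputs and dynamics share frequency content); frequencies and phases
  are per (channel, sinusoid), weights are independent across conditions
  (the "unconstrained inputs" premise), and each channel × condition trace
  is normalized to unit temporal RMS.
- **Initial states** are Gaussian, projected onto a random
  `init_state_rank`-dimensional subspace (default 10 < N), columns scaled
  to unit per-neuron RMS (`init_state_scale=1`, column norm √N).
- **Pure tuning (a = 0)** is emitted as the static readout
  `x(t) = b·B u(t)` at every time; a lingering random initial state would
  otherwise contaminate the rank-M bound that defines this model class.
  With the recursion form, inputs are applied at the target step, so
  **pure dynamics (b = 0)** satisfies `x(t) = A^{t−1} x(1)` exactly.
- **Presets** `fig8a`–`fig8d` pin (a, b) to (0, 1), (0.98, 0.05),
  (0.99, 0.03), (1, 0) with seed 0. All randomness flows from the single
  config seed through a fixed splitting scheme (A, B, inputs, initial
  states, in that order).

Scale convention and its consequences: the source model class fixes
neither the input amplitude nor the initial-state norm, yet the two mixed
presets are expected to fall on opposite sides of the tuning/dynamics
boundary ((0.98, 0.05) neuron-preferred, (0.99, 0.03)
condition-preferred). Under the unit-RMS conventions above this holds at
the pinned preset seed; the boundary between the two mixed regimes is
genuinely narrow, and for other seeds a mixed preset can return `none`.
The pure presets are robust across seeds.

Partial observation (`apply_observation`) zeroes all but the first
`observed_dims` state coordinates (diagonal 0/1 observation matrix),
bounding the neuron-mode rank accordingly; observing all dimensions is the
identity. The control manipulation (`make_control_dataset`) extracts the
top basis elements along one mode, sums random equal-size groups, and
projects every row of that mode's unfolding onto the collapsed span
(equivalent to per-slice least-squares refitting), capping that mode's
rank at the group count. Condition subsampling uses greedy farthest-point
sampling on Frobenius distances between condition slices from a random
start — a documented stand-in for "random but sufficiently different".
`simulate_spikes` emits inhomogeneous Poisson trains by thinning a
homogeneous stream at each slice's peak rate, with linear interpolation of
the rate between samples.

What the generator does *not* emulate: trial-to-trial rate fluctuations
beyond Poisson emission, non-Poisson spiking statistics, nonlinearities in
the rate model, non-stationary task epochs (target/go/move locking), and
realistic receptive-field or kinematic tuning structure. Passing tests on
these synthetics therefore validate the algebra and the qualitative
tuning-vs-dynamics dissociation, not performance on any particular
empirical dataset.

## Numerical choices

- **Numerical rank**: number of singular values above 1e-8 × the largest
  (measured unfoldings of noisy data are always full rank in the exact
  sense). The threshold is a package choice with double-precision headroom
  above accumulation error, exposed as a parameter; a zero matrix has
  rank 0.
- **Unfolding column order**: time-major blocks, conditions (mode 1) or
  neurons (mode 2) within a block. Singular values and errors are
  invariant to column order; a fixed order keeps coefficient matrices
  reproducible.
- **SVD sign indeterminacy**: basis elements are defined up to sign (and
  up to rotation within degenerate singular subspaces); all public
  guarantees are on errors and spans, never on element entries.
- **Degenerate inputs**: all-zero tensors, zero central slices, and
  `a = b = 0` configurations raise explicit errors rather than returning
  NaN.
- **Flat stable-mode curves**: the 1e-9 flatness of the stable mode's
  error holds at any k for orthogonal-dynamics runs (spectral
  proportionality, above) and at k ≥ M for tuning runs (error identically
  zero); at smaller k the tuning neuron-mode error varies mildly with the
  window because input spectra are only asymptotically stationary.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the generator's native sizes (N = C = 20, T = 300 for the canonical
presets; C = 72 for the subsampling study; 10 seeds for rank sweeps;
1000 white-noise replicates of size 20×20×50 for the null study; 50
Poisson trials per condition — the trial count of typical sensory-cortex
recordings — for the end-to-end spike pipeline).

## Known limitations

- **The verdict is conservative under a global null.** On i.i.d. noise
  tensors the per-condition error differences between modes are negatively
  dependent (each mode's per-condition errors are near-exchangeable
  deviations around nearly equal totals, so deviations cancel: their mean
  has ≈ 2% of the variance predicted under independence). Any paired
  location test that assumes independent pairs therefore rejects far less
  often than α — the measured false-positive rate on 1000 white-noise
  replicates is 0. Type-I error is controlled, but p-values near the null
  are not calibrated; the verdict should be read as evidence *for* a
  preferred mode, not as a calibrated test of exchangeability.
- The mixed-regime boundary is sensitive to the relative scale of inputs
  and initial states (see above); mixed-preset outcomes are guaranteed
  only under the pinned preset seed.
- Analysis windows are taken as given; the package does not splice
  multi-epoch recordings.
- Only the Frobenius norm is supported; no Tucker/CP decompositions.
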